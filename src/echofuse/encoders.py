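"""Video, audio and text branch encoders.

All branches emit the same embedding dimension ``embed_dim`` so they can be
fused.  The default backbone is a small 4-block strided convolutional net
(channel widths 16/32/64/embed_dim, overall spatial stride 8) sized for CPU
training; a paper-scale preset builds a ResNeXt-style topology with
squeeze-and-excitation blocks and a dilated final stage, available untrained
for architecture experiments.

The video branch represents a clip by 2 uniformly sampled frames stacked as
channels.  The audio branch consumes 256x256 log-spectrograms and shares
architecture hyper-parameters (never weights) with the video branch.  The
text branch looks words up in a fixed random embedding table (a stand-in
with the same interface as pretrained word vectors) and projects them
through two trainable fully-connected layers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .audio import Spectrogram, SPECTROGRAM_SIZE

__all__ = [
    "VideoEncoder",
    "AudioEncoder",
    "TextEmbedder",
    "TextEmbeddingSequence",
    "encode_video",
    "encode_audio",
    "embed_text",
    "sample_clip_frames",
    "preprocess_frames",
    "DEFAULT_EMBED_DIM",
    "N_CLIP_FRAMES",
]

DEFAULT_EMBED_DIM = 128
#: number of frames sampled to represent a clip
N_CLIP_FRAMES = 2


# ---------------------------------------------------------------------------
# visual preprocessing
# ---------------------------------------------------------------------------


def preprocess_frames(frames: np.ndarray, preset: str = "desk") -> np.ndarray:
    """Visual preprocessing.

    ``paper`` preset: scale each frame to 256x256 then centre-crop to
    224x224.  ``desk`` preset: identity (the generator already emits frames
    at model resolution).
    """
    frames = np.asarray(frames, dtype=np.float32)
    if preset == "desk":
        return frames
    if preset != "paper":
        raise ValueError(f"unknown preprocessing preset {preset!r}")
    from scipy.ndimage import zoom

    single = frames.ndim == 2
    if single:
        frames = frames[None]
    out = []
    for f in frames:
        zf = (256 / f.shape[0], 256 / f.shape[1])
        scaled = zoom(f, zf, order=1)[:256, :256]
        lo = (256 - 224) // 2
        out.append(scaled[lo : lo + 224, lo : lo + 224])
    out = np.stack(out)
    return out[0] if single else out


def sample_clip_frames(n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of the 2 frames representing a clip, sampled uniformly
    without replacement (sorted, so frame order within the clip is kept)."""
    if n_frames < N_CLIP_FRAMES:
        raise ValueError(f"clip has {n_frames} frames; need >= {N_CLIP_FRAMES}")
    return np.sort(rng.choice(n_frames, size=N_CLIP_FRAMES, replace=False))


# ---------------------------------------------------------------------------
# convolutional backbones
# ---------------------------------------------------------------------------


class _TinyBackbone(nn.Module):
    """conv(s2,16) - conv(s2,32) - conv(s1,64) - dilated conv(s1,64) -
    conv1x1(embed_dim); the map before global pooling is the spatial
    feature (stride 4, so a 64-pixel frame yields a 16x16 map).

    The dilated block widens the receptive field without further
    downsampling, so cells centred on a structure integrate evidence from
    its whole extent — the property that makes the response map usable for
    localisation."""

    stride = 4

    def __init__(self, in_channels: int, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = nn.Conv2d(in_channels, 16, 3, rng, stride=2)
        self.n1 = nn.InstanceNorm2d(16)
        self.c2 = nn.Conv2d(16, 32, 3, rng, stride=2)
        self.n2 = nn.InstanceNorm2d(32)
        self.c3 = nn.Conv2d(32, 64, 3, rng, stride=1)
        self.n3 = nn.InstanceNorm2d(64)
        self.c3d = nn.Conv2d(64, 64, 3, rng, stride=1, dilation=2)
        self.n3d = nn.InstanceNorm2d(64)
        self.c4 = nn.Conv2d(64, embed_dim, 1, rng, stride=1, pad=0)

    def spatial_map(self, x):
        x = self.n1(self.c1(x)).relu()
        x = self.n2(self.c2(x)).relu()
        x = self.n3(self.c3(x)).relu()
        x = self.n3d(self.c3d(x)).relu()
        return self.c4(x).relu()

    def forward(self, x):
        return F.global_avg_pool(self.spatial_map(x))


class _ResNeXtBlock(nn.Module):
    def __init__(self, c_in, c_out, rng, cardinality=8, stride=1, dilation=1):
        super().__init__()
        mid = c_out // 2
        self.reduce = nn.Conv2d(c_in, mid, 1, rng, pad=0)
        self.grouped = nn.Conv2d(
            mid, mid, 3, rng, stride=stride, groups=cardinality, dilation=dilation
        )
        self.expand = nn.Conv2d(mid, c_out, 1, rng, pad=0)
        self.se = nn.SEBlock(c_out, rng)
        self.shortcut = (
            nn.Conv2d(c_in, c_out, 1, rng, stride=stride, pad=0)
            if (c_in != c_out or stride != 1)
            else None
        )

    def forward(self, x):
        y = self.reduce(x).relu()
        y = self.grouped(y).relu()
        y = self.se(self.expand(y))
        sc = self.shortcut(x) if self.shortcut is not None else x
        return (y + sc).relu()


class _PaperBackbone(nn.Module):
    """ResNeXt-style grouped-convolution backbone with squeeze-and-excitation
    and a dilated (stride-free) final stage; spatial stride 8."""

    stride = 8

    def __init__(self, in_channels: int, embed_dim: int, rng: np.random.Generator,
                 widths=(32, 64, 128), blocks_per_stage=2, cardinality=8):
        super().__init__()
        self.stem = nn.Conv2d(in_channels, widths[0], 3, rng, stride=2)
        stages = []
        c_prev = widths[0]
        for si, c in enumerate(widths):
            for bi in range(blocks_per_stage):
                last_stage = si == len(widths) - 1
                stride = 2 if (bi == 0 and si > 0 and not last_stage) else 1
                dilation = 2 if last_stage else 1
                stages.append(
                    _ResNeXtBlock(c_prev, c, rng, cardinality, stride, dilation)
                )
                c_prev = c
        self.stages = nn.Sequential(*stages)
        self.head = nn.Conv2d(c_prev, embed_dim, 1, rng, pad=0)

    def spatial_map(self, x):
        x = self.stem(x).relu()
        x = self.stages(x)
        return self.head(x).relu()

    def forward(self, x):
        return F.global_avg_pool(self.spatial_map(x))


def _build_backbone(preset: str, in_channels: int, embed_dim: int, rng):
    if preset == "tiny":
        return _TinyBackbone(in_channels, embed_dim, rng)
    if preset == "paper":
        return _PaperBackbone(in_channels, embed_dim, rng)
    raise ValueError(f"unknown backbone preset {preset!r}")


# ---------------------------------------------------------------------------
# branch encoders
# ---------------------------------------------------------------------------


class VideoEncoder(nn.Module):
    def __init__(self, embed_dim: int = DEFAULT_EMBED_DIM, backbone: str = "tiny",
                 seed: int = 0):
        super().__init__()
        self.embed_dim = embed_dim
        rng = np.random.default_rng(seed)
        self.net = _build_backbone(backbone, N_CLIP_FRAMES, embed_dim, rng)

    @property
    def stride(self) -> int:
        return self.net.stride

    def forward(self, clips, spatial: bool = False):
        """``clips``: (B, 2, H, W) array or Tensor of stacked sampled frames.

        Pooled mode returns (B, D); spatial mode returns the (B, D, H', W')
        feature map taken before the final pooling.
        """
        x = nn.astensor(np.asarray(clips, dtype=np.float32) if not isinstance(clips, nn.Tensor) else clips)
        fmap = self.net.spatial_map(x)
        return fmap if spatial else F.global_avg_pool(fmap)


class AudioEncoder(nn.Module):
    """Same architecture family as the video branch, disjoint weights.

    256x256 spectrograms are average-pooled 4x at the input so the audio
    branch runs at the same spatial budget as the video branch.
    """

    def __init__(self, embed_dim: int = DEFAULT_EMBED_DIM, backbone: str = "tiny",
                 seed: int = 0, input_pool: int = 4):
        super().__init__()
        self.embed_dim = embed_dim
        self.input_pool = input_pool
        rng = np.random.default_rng(seed)
        self.net = _build_backbone(backbone, 1, embed_dim, rng)

    def forward(self, specs):
        """``specs``: (B, 256, 256) or (B, 1, 256, 256) array -> (B, D)."""
        x = np.asarray(specs, dtype=np.float32) if not isinstance(specs, nn.Tensor) else specs
        x = nn.astensor(x)
        if x.ndim == 3:
            b, h, w = x.shape
            x = x.reshape(b, 1, h, w)
        if x.shape[2] != SPECTROGRAM_SIZE or x.shape[3] != SPECTROGRAM_SIZE:
            raise ValueError(f"audio branch expects 256x256 input, got {x.shape}")
        if self.input_pool > 1:
            x = F.avg_pool2d(x, self.input_pool)
        return self.net(x)


# ---------------------------------------------------------------------------
# text branch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TextEmbeddingSequence:
    """Per-token fixed embeddings (L, E) with an out-of-vocabulary mask."""

    embeddings: np.ndarray
    unk_mask: np.ndarray
    tokens: tuple

    def __post_init__(self):
        if len(self.embeddings) == 0:
            raise ValueError("empty token sequence")
        object.__setattr__(self, "unk_mask", np.asarray(self.unk_mask, dtype=bool))
        object.__setattr__(self, "tokens", tuple(self.tokens))


class TextEmbedder(nn.Module):
    """Fixed random word-embedding table + two trainable projection layers.

    The table is seeded from a hash of the vocabulary so the same vocabulary
    always yields the same embeddings; unknown tokens share one reserved
    <unk> row and are flagged in the mask.
    """

    def __init__(self, vocab, embed_width: int = 64,
                 embed_dim: int = DEFAULT_EMBED_DIM, seed: int = 0):
        super().__init__()
        self.vocab = tuple(vocab)
        if not self.vocab:
            raise ValueError("vocabulary is empty")
        self.embed_width = embed_width
        self.embed_dim = embed_dim
        self._index = {tok: i for i, tok in enumerate(self.vocab)}
        digest = hashlib.sha256(("\n".join(self.vocab)).encode()).digest()
        table_seed = (int.from_bytes(digest[:4], "big") ^ seed) % (2**31)
        trng = np.random.default_rng(table_seed)
        self.table = trng.normal(0.0, 1.0, size=(len(self.vocab) + 1, embed_width)).astype(np.float32)
        self.unk_row = len(self.vocab)
        prng = np.random.default_rng(seed + 1)
        self.fc1 = nn.Linear(embed_width, embed_width, prng)
        self.fc2 = nn.Linear(embed_width, embed_dim, prng)

    @classmethod
    def from_file(cls, path, **kwargs) -> "TextEmbedder":
        """Vocabulary file: UTF-8, one token per line; line order is
        embedding row order."""
        with open(path, encoding="utf-8") as fh:
            vocab = [line.strip() for line in fh if line.strip()]
        return cls(vocab, **kwargs)

    def lookup(self, tokens) -> TextEmbeddingSequence:
        tokens = tuple(tokens)
        if not tokens:
            raise ValueError("empty token list")
        rows = [self._index.get(t.lower(), self.unk_row) for t in tokens]
        unk = np.array([r == self.unk_row for r in rows])
        return TextEmbeddingSequence(self.table[rows], unk, tokens)

    def project(self, seq: TextEmbeddingSequence) -> nn.Tensor:
        """(L, E) fixed embeddings -> (L, D) trainable projection."""
        x = nn.Tensor(seq.embeddings)
        return self.fc2(self.fc1(x).relu())

    def forward(self, tokens):
        seq = self.lookup(tokens)
        return self.project(seq), seq


# ---------------------------------------------------------------------------
# thin functional wrappers (one call per spec operation)
# ---------------------------------------------------------------------------


def encode_video(encoder: VideoEncoder, clip: np.ndarray, rng: np.random.Generator,
                 spatial: bool = False):
    """Encode one clip (T, H, W): sample 2 frames, stack channel-wise, run
    the video branch.  Deterministic given ``rng``."""
    clip = np.asarray(clip, dtype=np.float32)
    idx = sample_clip_frames(len(clip), rng)
    stacked = clip[idx][None]  # (1, 2, H, W)
    out = encoder(stacked, spatial=spatial)
    return out


def encode_audio(encoder: AudioEncoder, spec: Spectrogram) -> nn.Tensor:
    return encoder(spec.values[None])


def embed_text(embedder: TextEmbedder, tokens) -> TextEmbeddingSequence:
    return embedder.lookup(tokens)
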