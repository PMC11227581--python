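"""Downstream transfer tasks: standard plane detection, eye-gaze saliency
prediction, and audio-guided anatomy localisation.

The first two are fine-tuning estimators that can initialise their visual
encoder from a pretrained correspondence model (or from scratch, the
ablation control).  Localisation needs no fine-tuning at all: the spatial
fusion response map learned during pretraining is upsampled to image
resolution and read directly.  Localisation is text-free at inference —
only the audio and video branches are consulted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .nn import functional as F
from .audio import AUDIO_WINDOW_S, AUDIO_RATE, Waveform, log_spectrogram, resample
from .encoders import VideoEncoder, sample_clip_frames, N_CLIP_FRAMES
from .labels import BACKGROUND_CLASS, N_PLANE_CLASSES
from .pretrain import MultiModalPretrainer

__all__ = [
    "PlaneLabel",
    "SaliencyMap",
    "LocalisationMap",
    "PlaneClassifier",
    "SaliencyPredictor",
    "AudioVisualLocalizer",
    "finetune_spd",
    "finetune_saliency",
    "localise_from_audio",
    "labelled_frames",
    "scan_folds",
]


@dataclass(frozen=True)
class PlaneLabel:
    """Index into the 14-category standard-plane set."""

    index: int

    def __post_init__(self):
        if not 0 <= self.index < N_PLANE_CLASSES:
            raise ValueError(f"plane label {self.index} outside [0, {N_PLANE_CLASSES - 1}]")


@dataclass
class SaliencyMap:
    """Non-negative spatial attention map; sums to 1 when normalised."""

    values: np.ndarray
    normalized: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0:
            raise ValueError("saliency map has negative values")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-6:
            raise ValueError("normalised saliency map must sum to 1")


@dataclass
class LocalisationMap:
    """Audio-guided response map upsampled to frame size, in [0, 1]."""

    values: np.ndarray
    source_audio: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("localisation map has non-finite values")

    @property
    def argmax(self) -> tuple:
        return np.unravel_index(int(self.values.argmax()), self.values.shape)


# ---------------------------------------------------------------------------
# labelled data extraction (synthetic ground truth)
# ---------------------------------------------------------------------------


def labelled_frames(scans, max_background_per_scan: int = 6,
                    frames_per_event: int = 3):
    """Per-frame supervised data: up to ``frames_per_event`` frames spread
    over each event plus a few background frames per scan.  Returns
    (frames, labels, gaze maps, scan indices)."""
    X, y, g, sid = [], [], [], []
    for si, scan in enumerate(scans):
        fps = scan.config.fps
        for ev in scan.events:
            span = ev.t_end - ev.t_start
            offsets = (np.arange(frames_per_event) + 0.5) / frames_per_event
            idx = {
                min(int((ev.t_start + o * span) * fps), len(scan.frames) - 1)
                for o in offsets
            }
            for i in sorted(idx):
                X.append(scan.frames[i])
                y.append(ev.anatomy_id)
                g.append(scan.gaze_maps[i])
                sid.append(si)
        bg = np.flatnonzero(scan.plane_labels == BACKGROUND_CLASS)
        for i in bg[:: max(len(bg) // max_background_per_scan, 1)][:max_background_per_scan]:
            X.append(scan.frames[i])
            y.append(BACKGROUND_CLASS)
            g.append(scan.gaze_maps[i])
            sid.append(si)
    return np.stack(X), np.array(y), np.stack(g), np.array(sid)


def scan_folds(n_scans: int, n_folds: int = 3, seed: int = 0):
    """Cross-validation fold index per scan (folds never split a scan)."""
    rng = np.random.default_rng(seed)
    folds = np.arange(n_scans) % n_folds
    rng.shuffle(folds)
    return folds


def _frames_to_clips(frames: np.ndarray) -> np.ndarray:
    """Single frames duplicated through the 2-frame clip sampler."""
    frames = np.asarray(frames, dtype=np.float32)
    return np.repeat(frames[:, None], N_CLIP_FRAMES, axis=1)


def _init_encoder(pretrained, embed_dim, backbone, seed):
    if pretrained is not None:
        enc = VideoEncoder(pretrained.embed_dim, pretrained.backbone, seed=seed)
        enc.load_state_dict(pretrained.video_encoder_.state_dict())
        return enc
    return VideoEncoder(embed_dim, backbone, seed=seed)


# ---------------------------------------------------------------------------
# standard plane detection
# ---------------------------------------------------------------------------


def _l2_normalise(feats, d):
    """Scale pooled features to O(1) norm so the classification head sees
    comparable gradients whatever the encoder's output scale (contrastive
    pretraining leaves much smaller feature norms than random init)."""
    norm = (feats * feats).sum(axis=1, keepdims=True) ** 0.5 + 1e-8
    return feats / norm * float(np.sqrt(d))


class PlaneClassifier(BaseEstimator, ClassifierMixin):
    """14-way standard-plane classifier fine-tuned from a pretrained
    (or random) visual encoder.  All weights are fine-tuned; the pooled
    feature is L2-normalised before the linear head."""

    def __init__(self, pretrained: MultiModalPretrainer | None = None,
                 embed_dim: int = 128, backbone: str = "tiny", epochs: int = 12,
                 batch_size: int = 40, lr: float = 0.01, momentum: float = 0.9,
                 seed: int = 0):
        self.pretrained = pretrained
        self.embed_dim = embed_dim
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.seed = seed

    def fit(self, frames, labels):
        labels = np.asarray(labels)
        if labels.min() < 0 or labels.max() >= N_PLANE_CLASSES:
            raise ValueError(f"labels outside [0, {N_PLANE_CLASSES - 1}]")
        rng = np.random.default_rng(self.seed)
        self.encoder_ = _init_encoder(self.pretrained, self.embed_dim,
                                      self.backbone, self.seed)
        d = self.encoder_.embed_dim
        self.head_ = nn.Linear(d, N_PLANE_CLASSES, rng)
        self.classes_ = np.arange(N_PLANE_CLASSES)
        clips = _frames_to_clips(frames)
        opt = nn.SGD(
            list(self.encoder_.parameters()) + list(self.head_.parameters()),
            lr=self.lr, momentum=self.momentum,
        )
        n = len(clips)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for i in range(0, n, self.batch_size):
                idx = order[i : i + self.batch_size]
                feats = _l2_normalise(self.encoder_(clips[idx]), self.encoder_.embed_dim)
                logits = self.head_(feats)
                logp = F.log_softmax(logits, axis=1)
                loss = -logp[np.arange(len(idx)), labels[idx]].mean()
                if not np.isfinite(loss.item()):
                    raise RuntimeError("fine-tuning diverged: non-finite loss")
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict_proba(self, frames):
        clips = _frames_to_clips(frames)
        out = []
        with nn.no_grad():
            for i in range(0, len(clips), self.batch_size):
                feats = _l2_normalise(
                    self.encoder_(clips[i : i + self.batch_size]),
                    self.encoder_.embed_dim,
                )
                out.append(F.softmax(self.head_(feats), axis=1).data)
        return np.concatenate(out)

    def predict(self, frames):
        return self.predict_proba(frames).argmax(axis=1)


def linear_probe_spd(pretrained, frames, labels, train_mask, seed: int = 0,
                     embed_dim: int = 128, backbone: str = "tiny"):
    """Linear evaluation of representation quality for plane detection.

    Freezes the (pretrained or random) visual encoder, standardises the
    pooled features and fits a multinomial logistic-regression head on the
    training split.  This is the standard protocol for comparing
    self-supervised representations when full fine-tuning saturates a
    small labelled set.  Returns (predicted labels on the held-out split,
    true labels on that split).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    labels = np.asarray(labels)
    train_mask = np.asarray(train_mask, dtype=bool)
    if pretrained is not None:
        encoder = pretrained.video_encoder_
    else:
        encoder = VideoEncoder(embed_dim, backbone, seed=seed)
    clips = _frames_to_clips(frames)
    feats = []
    with nn.no_grad():
        for i in range(0, len(clips), 40):
            feats.append(encoder(clips[i : i + 40]).data)
    feats = np.concatenate(feats)
    scaler = StandardScaler().fit(feats[train_mask])
    fs = scaler.transform(feats)
    head = LogisticRegression(max_iter=3000, C=10.0).fit(
        fs[train_mask], labels[train_mask]
    )
    return head.predict(fs[~train_mask]), labels[~train_mask]


def finetune_spd(pretrained, frames, labels, **params) -> PlaneClassifier:
    """Fine-tune a 14-way plane classifier from a pretraining checkpoint
    (``pretrained=None`` gives the random-initialisation control arm)."""
    return PlaneClassifier(pretrained=pretrained, **params).fit(frames, labels)


# ---------------------------------------------------------------------------
# eye-gaze saliency prediction
# ---------------------------------------------------------------------------


class SaliencyPredictor(BaseEstimator):
    """Spatial saliency regressor: encoder features are upsampled by two
    transposed-convolution blocks to image resolution; the output is a
    softmax over pixels trained with a KL objective against normalised
    gaze maps."""

    def __init__(self, pretrained: MultiModalPretrainer | None = None,
                 embed_dim: int = 128, backbone: str = "tiny", epochs: int = 15,
                 batch_size: int = 40, lr: float = 0.01, momentum: float = 0.9,
                 seed: int = 0):
        self.pretrained = pretrained
        self.embed_dim = embed_dim
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.seed = seed

    def _logits(self, clips_t):
        fmap = self.norm_(self.encoder_(clips_t, spatial=True))
        up = self.dec1_(fmap).relu()
        return self.dec2_(up)  # (B, 1, H, W)

    def fit(self, frames, gaze_maps):
        gaze_maps = np.asarray(gaze_maps, dtype=np.float64)
        sums = gaze_maps.sum(axis=(1, 2))
        if np.any(np.abs(sums - 1.0) > 1e-5):
            raise ValueError("gaze targets must be normalised to sum to 1")
        rng = np.random.default_rng(self.seed)
        self.encoder_ = _init_encoder(self.pretrained, self.embed_dim,
                                      self.backbone, self.seed)
        d = self.encoder_.embed_dim
        # feature-map normalisation decouples the decoder from the
        # encoder's output scale; two transposed-conv blocks then factor
        # the encoder stride
        self.norm_ = nn.InstanceNorm2d(d)
        stride = self.encoder_.stride
        s1 = stride // 2
        if s1 >= 4:
            self.dec1_ = nn.ConvTranspose2d(d, 16, s1, rng, stride=s1, pad=0)
        else:
            self.dec1_ = nn.ConvTranspose2d(d, 16, 4, rng, stride=s1, pad=1)
        self.dec2_ = nn.ConvTranspose2d(16, 1, 4, rng, stride=2, pad=1)
        clips = _frames_to_clips(frames)
        params = (
            list(self.encoder_.parameters())
            + list(self.norm_.parameters())
            + list(self.dec1_.parameters())
            + list(self.dec2_.parameters())
        )
        opt = nn.SGD(params, lr=self.lr, momentum=self.momentum)
        n, hw = len(clips), frames.shape[1] * frames.shape[2]
        targets = gaze_maps.reshape(n, hw).astype(np.float32)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for i in range(0, n, self.batch_size):
                idx = order[i : i + self.batch_size]
                logits = self._logits(clips[idx]).reshape(len(idx), hw)
                logp = F.log_softmax(logits, axis=1)
                # KL(gt || pred) up to the constant entropy of gt
                loss = -(nn.Tensor(targets[idx]) * logp).sum(axis=1).mean()
                if not np.isfinite(loss.item()):
                    raise RuntimeError("fine-tuning diverged: non-finite loss")
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict(self, frames):
        """Per-frame saliency maps, each a distribution summing to 1."""
        clips = _frames_to_clips(frames)
        h, w = frames.shape[1], frames.shape[2]
        out = []
        with nn.no_grad():
            for i in range(0, len(clips), self.batch_size):
                logits = self._logits(clips[i : i + self.batch_size])
                b = logits.shape[0]
                p = F.softmax(logits.reshape(b, h * w), axis=1)
                out.append(p.data.reshape(b, h, w))
        return np.concatenate(out)


def finetune_saliency(pretrained, frames, gaze_maps, **params) -> SaliencyPredictor:
    return SaliencyPredictor(pretrained=pretrained, **params).fit(frames, gaze_maps)


# ---------------------------------------------------------------------------
# audio-guided localisation
# ---------------------------------------------------------------------------


def _bilinear_upsample(m: np.ndarray, out_size: int) -> np.ndarray:
    """Centre-aligned bilinear upsampling: output pixel k samples the map at
    (k + 0.5) / scale - 0.5, so each coarse cell stays centred on the image
    region it was computed from."""
    from scipy.ndimage import map_coordinates

    sy = out_size / m.shape[0]
    sx = out_size / m.shape[1]
    ys = (np.arange(out_size) + 0.5) / sy - 0.5
    xs = (np.arange(out_size) + 0.5) / sx - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return map_coordinates(m, [yy, xx], order=1, mode="nearest")


def localise_from_audio(model: MultiModalPretrainer, clip: np.ndarray,
                        audio_window: Waveform,
                        rng: np.random.Generator | None = None,
                        flip_average: bool = True) -> LocalisationMap:
    """Audio-guided anatomy localisation from a pretrained spatial model.

    Computes the spatial fusion response map between the clip's visual
    feature map and the audio embedding of the 0.6 s window, bilinearly
    upsamples it to frame size and min-max normalises to [0, 1].  No text
    is consumed.  With ``flip_average`` (default) the response is averaged
    over the four axis flips of the clip, cancelling directional biases in
    the learned detectors.
    """
    if not model._uses_spatial:
        raise ValueError(
            f"variant {model.variant!r} was pretrained without spatial fusion; "
            "no response map is available"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    clip = np.asarray(clip, dtype=np.float32)
    spec = log_spectrogram(resample(audio_window, AUDIO_RATE)).values
    with nn.no_grad():
        idx = sample_clip_frames(len(clip), rng)
        stacked = clip[idx]
        a = model.audio_encoder_(spec[None])
        maps = []
        for flip in range(4 if flip_average else 1):
            x = stacked
            if flip & 1:
                x = x[:, ::-1, :]
            if flip & 2:
                x = x[:, :, ::-1]
            vmap = model.video_encoder_(np.ascontiguousarray(x)[None], spatial=True)
            r = model.va_head_.response_map(vmap, a).data[0]
            if flip & 1:
                r = r[::-1, :]
            if flip & 2:
                r = r[:, ::-1]
            maps.append(r)
        resp = np.mean(maps, axis=0)
    up = _bilinear_upsample(resp, clip.shape[1])
    lo, hi = up.min(), up.max()
    if hi - lo < 1e-12:
        up = np.zeros_like(up)
    else:
        up = (up - lo) / (hi - lo)
    return LocalisationMap(up, source_audio=spec)


def localisation_hit_rate(model: MultiModalPretrainer, scans, n: int = 50,
                          seed: int = 0) -> float:
    """Fraction of anatomy-audio clips whose localisation argmax falls
    inside the true anatomy region mask.

    Clips are sampled at anatomy-keyword utterances with their matched
    audio window (the setting where the narration names what is on
    screen).
    """
    from .pretrain import sample_pairs

    rng = np.random.default_rng(seed)
    examples = sample_pairs(list(scans), n, p_negative=0.0, rng=rng)
    hits = 0
    for ex in examples:
        scan = scans[ex.scan_idx]
        ev = next(
            (e for e in scan.events if e.t_start - 0.3 <= ex.t < e.t_end + 0.3), None
        )
        if ev is None:
            continue
        w = scan.waveform.slice_time(ex.t - AUDIO_WINDOW_S / 2,
                                     ex.t + AUDIO_WINDOW_S / 2)
        m = localise_from_audio(model, ex.clip, w, rng)
        hits += bool(ev.region_mask[m.argmax])
    return hits / len(examples)


class AudioVisualLocalizer(BaseEstimator):
    """Transform-shaped wrapper around audio-guided localisation."""

    def __init__(self, model: MultiModalPretrainer, seed: int = 0):
        self.model = model
        self.seed = seed

    def transform(self, clip_audio_pairs):
        rng = np.random.default_rng(self.seed)
        return [
            localise_from_audio(self.model, clip, audio, rng)
            for clip, audio in clip_audio_pairs
        ]
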