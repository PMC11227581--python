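"""Pair construction and the self-supervised pretraining loop.

Training examples are anchored at anatomy-keyword utterances (the output of
the audio-cleaning chain): for a video clip at time t, the matched audio
and text are taken from the 0.6 s window [t - 0.3 s, t + 0.3 s).  Negatives
substitute the window of a different scan, or of the same scan shifted by
at least 5 s, and carry label c = 0.

``MultiModalPretrainer`` is a scikit-learn style estimator: configure in
``__init__``, call ``fit(scans)``, read fitted attributes (trailing
underscore) afterwards.  Variants select the architecture/objective of the
framework's ablation ladder:

===============  ============================  ============================
variant          fusion                        loss terms (equal weights)
===============  ============================  ============================
``base``         concatenation                 correspondence
``contrastive``  concatenation                 correspondence + contrastive
``spatial``      spatial response map          correspondence + contrastive
``text``         spatial + text (SIG filter)   all four
``full``         spatial + text (SIG keyword)  all four
===============  ============================  ============================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .audio import AUDIO_WINDOW_S, AUDIO_RATE, resample, log_spectrogram
from .encoders import (
    AudioEncoder,
    TextEmbedder,
    VideoEncoder,
    sample_clip_frames,
    N_CLIP_FRAMES,
)
from .gating import KeywordDictionary, SIGModule
from .objectives import (
    ConcatFusionHead,
    CorrespondenceBatch,
    ObjectiveWeights,
    SpatialFusionHead,
    joint_loss,
)
from .synthetic import FILLER_WORDS, ScanRecord

__all__ = [
    "TrainingExample",
    "TrainState",
    "sample_pairs",
    "MultiModalPretrainer",
    "pretrain",
    "VARIANTS",
    "MIN_NEGATIVE_SHIFT_S",
    "CLIP_HALF_WIDTH_S",
]

VARIANTS = ("base", "contrastive", "spatial", "text", "full")
#: same-scan negatives must be shifted by at least this much
MIN_NEGATIVE_SHIFT_S = 5.0
#: video clips span t +- this width
CLIP_HALF_WIDTH_S = 0.5


@dataclass
class TrainingExample:
    """One (clip, audio window, text window, label) tuple."""

    scan_idx: int
    t: float
    clip: np.ndarray            # (T, H, W) frames around t
    spectrogram: np.ndarray     # (256, 256) of the 0.6 s audio window
    tokens: tuple               # transcript tokens overlapping the window
    label: int                  # 1 matched, 0 substituted
    source_scan_idx: int        # where audio/text came from
    source_t: float


@dataclass
class TrainState:
    """Mutable optimisation state logged per epoch."""

    step: int = 0
    epoch: int = 0
    lr_init: float = 1e-3
    lr_decay_every: int = 20
    batch_size: int = 40
    seed: int = 0
    running_loss: list = field(default_factory=list)

    @property
    def lr(self) -> float:
        from .nn.optim import step_decay_lr

        return step_decay_lr(self.lr_init, self.epoch, self.lr_decay_every)


def _anchor_times(scan: ScanRecord) -> list:
    """Midpoints of anatomy-keyword utterances (the cleaned-audio anchors)."""
    return [s.midpoint_s for s in scan.segments if s.is_anatomy]


def _clip_at(scan: ScanRecord, t: float) -> np.ndarray:
    fps = scan.config.fps
    i0 = max(int(np.floor((t - CLIP_HALF_WIDTH_S) * fps)), 0)
    i1 = min(int(np.ceil((t + CLIP_HALF_WIDTH_S) * fps)), len(scan.frames))
    if i1 - i0 < N_CLIP_FRAMES:
        i1 = min(i0 + N_CLIP_FRAMES, len(scan.frames))
        i0 = max(i1 - N_CLIP_FRAMES, 0)
    return scan.frames[i0:i1]


def _window_tokens(scan: ScanRecord, t: float) -> tuple:
    lo, hi = t - AUDIO_WINDOW_S / 2, t + AUDIO_WINDOW_S / 2
    toks = []
    for s in scan.segments:
        if s.start_s < hi and s.end_s > lo:
            toks.extend(s.text)
    return tuple(toks)


def _window_spectrogram(scan: ScanRecord, t: float) -> np.ndarray:
    w = scan.waveform.slice_time(t - AUDIO_WINDOW_S / 2, t + AUDIO_WINDOW_S / 2)
    return log_spectrogram(resample(w, AUDIO_RATE)).values


def sample_pairs(
    scans, n: int, p_negative: float, rng: np.random.Generator
) -> list:
    """Draw ``n`` training examples from keyword-anchored windows.

    Positives pair a clip with its own co-timed audio/text window;
    negatives substitute the window of another scan, or of the same scan at
    a shift of at least 5 s, and are labelled 0.
    """
    scans = list(scans)
    anchors = [(si, t) for si, scan in enumerate(scans) for t in _anchor_times(scan)]
    if not anchors:
        raise ValueError("no anatomy-keyword segments to anchor pairs at")
    if p_negative > 0 and len(scans) < 2:
        si0 = anchors[0][0]
        ts = [t for _, t in anchors]
        if max(ts) - min(ts) < MIN_NEGATIVE_SHIFT_S:
            raise ValueError(
                "cannot build negatives: a single scan needs anchors at least "
                f"{MIN_NEGATIVE_SHIFT_S} s apart"
            )
    examples = []
    for _ in range(n):
        si, t_anchor = anchors[int(rng.integers(len(anchors)))]
        t = float(np.clip(
            t_anchor + rng.uniform(-0.1, 0.1),
            CLIP_HALF_WIDTH_S,
            scans[si].duration_s - CLIP_HALF_WIDTH_S,
        ))
        clip = _clip_at(scans[si], t)
        negative = bool(rng.random() < p_negative)
        if negative:
            candidates = [
                (sj, tj)
                for sj, tj in anchors
                if sj != si or abs(tj - t) >= MIN_NEGATIVE_SHIFT_S
            ]
            sj, tj = candidates[int(rng.integers(len(candidates)))]
            src_si, src_t = sj, float(tj)
        else:
            src_si, src_t = si, t
        examples.append(
            TrainingExample(
                scan_idx=si,
                t=t,
                clip=clip,
                spectrogram=_window_spectrogram(scans[src_si], src_t),
                tokens=_window_tokens(scans[src_si], src_t),
                label=0 if negative else 1,
                source_scan_idx=src_si,
                source_t=src_t,
            )
        )
    return examples


def _spread_batches(examples: list, batch_size: int) -> list:
    """Greedy reorder so no two matched items in a batch come from the same
    scan within 5 s of each other (avoids false contrastive negatives)."""
    pending = list(examples)
    out = []
    while pending:
        batch, rest = [], []
        for ex in pending:
            clash = any(
                ex.label == 1
                and b.label == 1
                and b.scan_idx == ex.scan_idx
                and abs(b.t - ex.t) < MIN_NEGATIVE_SHIFT_S
                for b in batch
            )
            if clash or len(batch) >= batch_size:
                rest.append(ex)
            else:
                batch.append(ex)
        out.append(batch)
        pending = rest
    return out


_VARIANT_WEIGHTS = {
    "base": ObjectiveWeights(1.0, 0.0, 0.0, 0.0),
    "contrastive": ObjectiveWeights(0.5, 0.0, 0.5, 0.0),
    "spatial": ObjectiveWeights(0.5, 0.0, 0.5, 0.0),
    "text": ObjectiveWeights(0.25, 0.25, 0.25, 0.25),
    "full": ObjectiveWeights(0.25, 0.25, 0.25, 0.25),
}


class MultiModalPretrainer(BaseEstimator):
    """Self-supervised audio-visual(-text) correspondence pretrainer.

    Parameters follow the framework's printed training configuration:
    SGD, learning rate 1e-3 decayed by 10 every 20 epochs, batch size 40,
    equal loss weights.  ``n_examples`` examples are (re)drawn each epoch
    from the epoch-indexed random stream; a held-out set of
    ``heldout_fraction`` is drawn once and never trained on.
    """

    def __init__(
        self,
        variant: str = "full",
        embed_dim: int = 128,
        backbone: str = "tiny",
        epochs: int = 10,
        batch_size: int = 40,
        lr: float = 1e-3,
        lr_decay_every: int = 20,
        momentum: float = 0.9,
        tau: float = 0.1,
        contrastive_mode: str = "infonce",
        n_examples: int = 400,
        p_negative: float = 0.5,
        heldout_fraction: float = 0.2,
        sig_lambda: float = 0.0,
        spatial_pool: str = "mean",
        augment_flips: bool = False,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.variant = variant
        self.embed_dim = embed_dim
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay_every = lr_decay_every
        self.momentum = momentum
        self.tau = tau
        self.contrastive_mode = contrastive_mode
        self.n_examples = n_examples
        self.p_negative = p_negative
        self.heldout_fraction = heldout_fraction
        self.sig_lambda = sig_lambda
        self.spatial_pool = spatial_pool
        self.augment_flips = augment_flips
        self.seed = seed
        self.verbose = verbose

    # -- helpers ------------------------------------------------------------
    @property
    def _uses_text(self) -> bool:
        return self.variant in ("text", "full")

    @property
    def _uses_spatial(self) -> bool:
        return self.variant in ("spatial", "text", "full")

    def _encode_batch(self, batch, rng, spatial, augment=False):
        clips = np.stack(
            [ex.clip[sample_clip_frames(len(ex.clip), rng)] for ex in batch]
        )
        if augment and self.augment_flips:
            # random horizontal/vertical flips; correspondence and alignment
            # are flip-invariant, and symmetric detectors localise better
            for i in range(len(clips)):
                if rng.random() < 0.5:
                    clips[i] = clips[i, :, ::-1, :]
                if rng.random() < 0.5:
                    clips[i] = clips[i, :, :, ::-1]
        specs = np.stack([ex.spectrogram for ex in batch])
        v = self.video_encoder_(clips, spatial=spatial)
        a = self.audio_encoder_(specs)
        text, empty = None, None
        if self._uses_text:
            feats, empties = [], []
            for ex in batch:
                if not ex.tokens:
                    feats.append(nn.Tensor(np.zeros(self.embed_dim, dtype=np.float32)))
                    empties.append(True)
                    continue
                seq = self.text_embedder_.lookup(ex.tokens)
                g = self.sig_(
                    self.text_embedder_.project(seq),
                    seq,
                    dictionary=self.keyword_dictionary_ if self.variant == "full" else None,
                    lam=self.sig_lambda,
                )
                feats.append(g.vector)
                empties.append(g.empty)
            text = nn.stack(feats)
            empty = np.array(empties)
        c = np.array([ex.label for ex in batch])
        return CorrespondenceBatch(v, a, c, text, empty)

    def _batch_loss(self, cbatch):
        return joint_loss(
            cbatch,
            self.weights_,
            va_head=self.va_head_,
            vt_head=self.vt_head_,
            tau=self.tau,
            mode=self.contrastive_mode,
            spatial_pool=self.spatial_pool,
        )

    def _predict_p(self, cbatch):
        with nn.no_grad():
            if self._uses_spatial:
                _, p = self.va_head_(cbatch.video, cbatch.audio)
            else:
                p = self.va_head_(cbatch.video, cbatch.audio)
        return p.data

    # -- estimator API -------------------------------------------------------
    def fit(self, scans, y=None):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; use one of {VARIANTS}")
        scans = list(scans)
        ss = np.random.SeedSequence(self.seed)
        s_init, s_data, s_sampler = ss.spawn(3)
        init_seeds = s_init.generate_state(4)

        cfg = scans[0].config
        vocab = tuple(cfg.anatomy_vocab) + FILLER_WORDS + tuple(cfg.distractor_vocab)
        self.vocab_ = vocab
        self.keyword_dictionary_ = KeywordDictionary(frozenset(cfg.anatomy_vocab))
        self.video_encoder_ = VideoEncoder(self.embed_dim, self.backbone,
                                           seed=int(init_seeds[0]))
        self.audio_encoder_ = AudioEncoder(self.embed_dim, self.backbone,
                                           seed=int(init_seeds[1]))
        self.text_embedder_ = TextEmbedder(vocab, embed_dim=self.embed_dim,
                                           seed=int(init_seeds[2]))
        self.sig_ = SIGModule(self.embed_dim, seed=int(init_seeds[3]))
        if self._uses_spatial:
            self.va_head_ = SpatialFusionHead(self.embed_dim, seed=int(init_seeds[0]) + 1)
            self.vt_head_ = SpatialFusionHead(self.embed_dim, seed=int(init_seeds[1]) + 1)
        else:
            self.va_head_ = ConcatFusionHead(self.embed_dim, seed=int(init_seeds[0]) + 1)
            self.vt_head_ = ConcatFusionHead(self.embed_dim, seed=int(init_seeds[1]) + 1)
        self.weights_ = _VARIANT_WEIGHTS[self.variant]

        params = list(self.video_encoder_.parameters())
        params += list(self.audio_encoder_.parameters())
        params += [self.text_embedder_.fc1.weight, self.text_embedder_.fc1.bias,
                   self.text_embedder_.fc2.weight, self.text_embedder_.fc2.bias]
        params += list(self.sig_.parameters())
        params += list(self.va_head_.parameters()) + list(self.vt_head_.parameters())
        # dedupe (text projection listed once) while keeping order
        seen, uniq = set(), []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                uniq.append(p)
        opt = nn.SGD(uniq, lr=self.lr, momentum=self.momentum)

        data_rng = np.random.default_rng(s_data)
        n_heldout = max(int(self.n_examples * self.heldout_fraction), 2)
        heldout = sample_pairs(scans, n_heldout, self.p_negative, data_rng)

        state = TrainState(lr_init=self.lr, lr_decay_every=self.lr_decay_every,
                           batch_size=self.batch_size, seed=self.seed)
        self.history_ = []
        epoch_streams = s_sampler.spawn(self.epochs)
        for epoch in range(self.epochs):
            state.epoch = epoch
            opt.lr = state.lr
            erng = np.random.default_rng(epoch_streams[epoch])
            examples = sample_pairs(scans, self.n_examples, self.p_negative, erng)
            order = erng.permutation(len(examples))
            examples = [examples[i] for i in order]
            losses = []
            for batch in _spread_batches(examples, self.batch_size):
                if len(batch) < 2:
                    continue
                cbatch = self._encode_batch(batch, erng, self._uses_spatial, augment=True)
                loss = self._batch_loss(cbatch)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at step {state.step}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                state.step += 1
            acc = self.score_examples(heldout, np.random.default_rng(self.seed))
            rec = {
                "epoch": epoch,
                "step": state.step,
                "lr": state.lr,
                "train_loss": float(np.mean(losses)),
                "heldout_acc": float(acc),
            }
            state.running_loss.append(rec["train_loss"])
            self.history_.append(rec)
            if self.verbose:
                print(json.dumps(rec))
        self.state_ = state
        self.heldout_examples_ = heldout
        self.heldout_accuracy_ = self.history_[-1]["heldout_acc"]
        return self

    def score_examples(self, examples, rng=None) -> float:
        """Correspondence accuracy (p > 0.5 vs label) on given examples."""
        rng = rng or np.random.default_rng(self.seed)
        correct = 0
        for i in range(0, len(examples), self.batch_size):
            chunk = examples[i : i + self.batch_size]
            cbatch = self._encode_batch(chunk, rng, self._uses_spatial)
            p = self._predict_p(cbatch)
            correct += int(((p > 0.5).astype(int) == cbatch.labels).sum())
        return correct / len(examples)

    def score(self, scans, y=None) -> float:
        """Correspondence accuracy on freshly sampled pairs from ``scans``."""
        rng = np.random.default_rng(self.seed + 1)
        examples = sample_pairs(list(scans), 100, self.p_negative, rng)
        return self.score_examples(examples, rng)

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        """Single-archive checkpoint: named weight arrays + config hash."""
        import hashlib

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cfg = json.dumps(self.get_params(), sort_keys=True)
        arrays = {}
        for mod_name in ("video_encoder_", "audio_encoder_", "sig_",
                         "va_head_", "vt_head_"):
            for k, v in getattr(self, mod_name).state_dict().items():
                arrays[f"{mod_name}{k}"] = v
        arrays["text_table"] = self.text_embedder_.table
        for k, v in self.text_embedder_.state_dict().items():
            arrays[f"text_embedder_{k}"] = v
        arrays["config_json"] = np.frombuffer(cfg.encode(), dtype=np.uint8)
        arrays["config_hash"] = np.frombuffer(
            hashlib.sha256(cfg.encode()).digest(), dtype=np.uint8
        )
        arrays["vocab"] = np.array("\n".join(self.vocab_))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MultiModalPretrainer":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(bytes(data["config_json"]).decode())
        est = cls(**cfg)
        vocab = tuple(str(data["vocab"]).split("\n"))
        ss = np.random.SeedSequence(est.seed)
        init_seeds = ss.spawn(3)[0].generate_state(4)
        est.vocab_ = vocab
        est.video_encoder_ = VideoEncoder(est.embed_dim, est.backbone,
                                          seed=int(init_seeds[0]))
        est.audio_encoder_ = AudioEncoder(est.embed_dim, est.backbone,
                                          seed=int(init_seeds[1]))
        est.text_embedder_ = TextEmbedder(vocab, embed_dim=est.embed_dim,
                                          seed=int(init_seeds[2]))
        est.sig_ = SIGModule(est.embed_dim, seed=int(init_seeds[3]))
        if est._uses_spatial:
            est.va_head_ = SpatialFusionHead(est.embed_dim)
            est.vt_head_ = SpatialFusionHead(est.embed_dim)
        else:
            est.va_head_ = ConcatFusionHead(est.embed_dim)
            est.vt_head_ = ConcatFusionHead(est.embed_dim)
        for mod_name in ("video_encoder_", "audio_encoder_", "sig_",
                         "va_head_", "vt_head_"):
            mod = getattr(est, mod_name)
            state = {
                k[len(mod_name):]: data[k]
                for k in data.files
                if k.startswith(mod_name)
            }
            mod.load_state_dict(state)
        est.text_embedder_.table = data["text_table"]
        est.text_embedder_.load_state_dict(
            {k[len("text_embedder_"):]: data[k] for k in data.files
             if k.startswith("text_embedder_") and not k.endswith("table")}
        )
        est.weights_ = _VARIANT_WEIGHTS[est.variant]
        est.keyword_dictionary_ = None
        return est


def pretrain(scans, **params) -> MultiModalPretrainer:
    """Functional wrapper: configure, fit and return a pretrainer."""
    return MultiModalPretrainer(**params).fit(scans)
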