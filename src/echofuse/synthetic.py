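"""Synthetic multi-modal scan generator.

Real clinical scan recordings pair a long ultrasound video with sparse,
noisy concurrent narration: the sonographer names an anatomy while it is on
screen, other speech is off-topic small talk, and automatic transcription
corrupts some words.  Since that data is private, this module generates
"scans" with the same statistical structure plus full ground truth:

* the timeline is a sequence of anatomy events separated by background gaps;
* each event renders a class-specific phantom shape over a speckle
  background, labels its frames with the matching plane class, and attaches
  a Gaussian gaze map at the shape centroid;
* with probability ``1 - p_offtopic`` the concurrent utterance names the
  anatomy (its keyword plus filler words) and the waveform carries the
  class's acoustic signature — a two-tone mixture amplitude-modulated at
  4 Hz to mimic a speech envelope; otherwise the utterance is off-topic
  small talk over a neutral low-frequency signature;
* each transcript token is independently corrupted to an out-of-vocabulary
  string with probability ``p_invalid_token`` (emulating ASR errors).

Everything is deterministic given ``ScanConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
from PIL import Image

from .audio import TranscriptSegment, Waveform, write_wav, read_wav, write_transcript, read_transcript
from .labels import BACKGROUND_CLASS, N_ANATOMY_CLASSES

__all__ = [
    "ScanConfig",
    "AnatomyEvent",
    "ScanRecord",
    "generate_scan",
    "render_frame",
    "make_gaze_map",
    "anatomy_signature",
    "write_scan",
    "read_scan",
    "DEFAULT_ANATOMY_VOCAB",
    "DEFAULT_DISTRACTOR_VOCAB",
    "FILLER_WORDS",
]

#: One spoken keyword per anatomy class, in class-index order.
DEFAULT_ANATOMY_VOCAB = (
    "tracheal", "chambers", "outflow", "ventricle", "brain", "cerebellum",
    "abdomen", "femur", "kidneys", "lips", "profile", "spine", "sacrum",
)

#: Off-topic small talk drawn when an utterance is unrelated to the screen.
DEFAULT_DISTRACTOR_VOCAB = (
    "how", "are", "you", "today", "weather", "lovely", "thanks", "okay",
    "room", "door", "coffee", "appointment", "weekend", "traffic",
)

#: In-vocabulary connective words emitted around keywords.
FILLER_WORDS = ("this", "is", "the", "looking", "at", "we", "can", "see", "here", "now")

_TEMPLATES = (
    ("this", "is", "the"),
    ("looking", "at", "the"),
    ("we", "can", "see", "the"),
    ("here", "is", "the"),
)

_NEUTRAL_TONES = (250.0, 330.0)


@dataclass(frozen=True)
class ScanConfig:
    duration_s: float = 60.0
    fps: float = 4.0
    image_size: int = 64
    sample_rate: int = 24_000
    n_anatomy_classes: int = N_ANATOMY_CLASSES
    anatomy_vocab: tuple = DEFAULT_ANATOMY_VOCAB
    distractor_vocab: tuple = DEFAULT_DISTRACTOR_VOCAB
    p_offtopic: float = 0.3
    p_invalid_token: float = 0.1
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if not (0 <= self.p_offtopic <= 1 and 0 <= self.p_invalid_token <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.anatomy_vocab) < self.n_anatomy_classes:
            raise ValueError(
                f"anatomy_vocab has {len(self.anatomy_vocab)} terms but "
                f"{self.n_anatomy_classes} classes are requested"
            )
        object.__setattr__(self, "anatomy_vocab", tuple(self.anatomy_vocab))
        object.__setattr__(self, "distractor_vocab", tuple(self.distractor_vocab))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))


@dataclass(frozen=True)
class AnatomyEvent:
    """A rendered anatomy visible over [t_start, t_end)."""

    anatomy_id: int
    t_start: float
    t_end: float
    centroid: tuple
    region_mask: np.ndarray
    keyword: str

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("event needs t_start < t_end")
        mask = np.asarray(self.region_mask, dtype=bool)
        if not mask.any():
            raise ValueError("event region mask is empty")
        object.__setattr__(self, "region_mask", mask)


@dataclass
class ScanRecord:
    config: ScanConfig
    frames: np.ndarray          # (n_frames, H, W) float32 in [0, 1]
    waveform: Waveform
    segments: list              # TranscriptSegment
    events: list                # AnatomyEvent
    plane_labels: np.ndarray    # (n_frames,) int
    gaze_maps: np.ndarray       # (n_frames, H, W) float32, each sums to 1

    def frame_time(self, i: int) -> float:
        """Midpoint time of frame i (frame i spans [i/fps, (i+1)/fps))."""
        return (i + 0.5) / self.config.fps

    @property
    def duration_s(self) -> float:
        return self.config.duration_s


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def _shape_mask(anatomy_id: int, centroid, image_size: int) -> np.ndarray:
    """Distinct geometry per class: ellipses, rings, crosses, bars, ..."""
    r0, c0 = centroid
    rr, cc = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    dr, dc = rr - r0, cc - c0
    s = image_size / 10.0  # base length scale
    k = anatomy_id % 13
    if k == 0:      # wide ellipse
        return (dr / (0.8 * s)) ** 2 + (dc / (1.6 * s)) ** 2 <= 1
    if k == 1:      # tall ellipse
        return (dr / (1.6 * s)) ** 2 + (dc / (0.8 * s)) ** 2 <= 1
    if k == 2:      # ring
        d2 = dr**2 + dc**2
        return (d2 <= (1.6 * s) ** 2) & (d2 >= (0.9 * s) ** 2)
    if k == 3:      # plus / cross
        return ((np.abs(dr) <= 0.45 * s) & (np.abs(dc) <= 1.7 * s)) | (
            (np.abs(dc) <= 0.45 * s) & (np.abs(dr) <= 1.7 * s)
        )
    if k == 4:      # square
        return (np.abs(dr) <= 1.1 * s) & (np.abs(dc) <= 1.1 * s)
    if k == 5:      # diamond
        return np.abs(dr) + np.abs(dc) <= 1.6 * s
    if k == 6:      # disc
        return dr**2 + dc**2 <= (1.3 * s) ** 2
    if k == 7:      # horizontal bar
        return (np.abs(dr) <= 0.5 * s) & (np.abs(dc) <= 2.0 * s)
    if k == 8:      # two blobs
        d2a = (dr - 0.9 * s) ** 2 + (dc - 0.9 * s) ** 2
        d2b = (dr + 0.9 * s) ** 2 + (dc + 0.9 * s) ** 2
        return (d2a <= (0.8 * s) ** 2) | (d2b <= (0.8 * s) ** 2)
    if k == 9:      # vertical bar
        return (np.abs(dc) <= 0.5 * s) & (np.abs(dr) <= 2.0 * s)
    if k == 10:     # X shape
        return (np.abs(dr - dc) <= 0.6 * s) & (np.abs(dr + dc) <= 2.2 * s) | (
            np.abs(dr + dc) <= 0.6 * s
        ) & (np.abs(dr - dc) <= 2.2 * s)
    if k == 11:     # triangle (lower half-plane wedge)
        return (dr >= -1.2 * s) & (dr <= 1.2 * s) & (np.abs(dc) <= 0.2 * s + 0.7 * (dr + 1.2 * s))
    # k == 12: L shape
    return ((np.abs(dc + 0.8 * s) <= 0.5 * s) & (np.abs(dr) <= 1.6 * s)) | (
        (np.abs(dr - 1.1 * s) <= 0.5 * s) & (np.abs(dc) <= 1.6 * s)
    )


def render_frame(
    anatomy_id: int,
    centroid,
    image_size: int,
    noise_sigma: float,
    rng: np.random.Generator,
):
    """Render one frame: class-specific bright shape over speckle background.

    Returns ``(image, region_mask)`` with pixel values in [0, 1]; with
    ``noise_sigma == 0`` the background outside the mask is exactly 0.
    """
    r0, c0 = centroid
    if not (0 <= r0 < image_size and 0 <= c0 < image_size):
        raise ValueError(f"centroid {centroid} outside {image_size}x{image_size} image")
    mask = _shape_mask(anatomy_id, centroid, image_size)
    img = np.abs(rng.normal(0.0, noise_sigma, size=(image_size, image_size)))
    base = 0.75 + 0.1 * np.cos(anatomy_id + np.linspace(0, np.pi, image_size))[None, :]
    inside = base + rng.normal(0.0, noise_sigma, size=(image_size, image_size))
    img[mask] = inside[mask]
    return np.clip(img, 0.0, 1.0).astype(np.float32), mask


def make_gaze_map(region_mask: np.ndarray, sigma_px: float) -> np.ndarray:
    """Isotropic Gaussian at the mask centroid, normalised to sum to 1."""
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    rows, cols = np.nonzero(mask)
    r0, c0 = int(round(rows.mean())), int(round(cols.mean()))
    h, w = mask.shape
    rr, cc = np.mgrid[0:h, 0:w]
    g = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2))
    return (g / g.sum()).astype(np.float64)


def anatomy_signature(anatomy_id: int | None, sample_rate: int) -> tuple:
    """The two tone frequencies carried by class ``anatomy_id`` (None: the
    neutral off-topic signature).  All frequencies sit below Nyquist for
    rates >= 24 kHz."""
    if anatomy_id is None:
        return _NEUTRAL_TONES
    f1 = 500.0 + 400.0 * anatomy_id
    f2 = 6000.0 + 450.0 * anatomy_id
    nyq = sample_rate / 2.0
    if f2 >= nyq:
        raise ValueError(f"signature tone {f2} Hz above Nyquist ({nyq} Hz)")
    return (f1, f2)


def _tone_burst(f1: float, f2: float, t0: float, n: int, rate: int) -> np.ndarray:
    """AM two-tone mixture: 4 Hz envelope mimicking a speech rhythm."""
    t = t0 + np.arange(n) / rate
    env = 0.55 + 0.45 * np.sin(2 * np.pi * 4.0 * t)
    return 0.4 * env * 0.5 * (np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t))


def _corrupt_token(rng: np.random.Generator) -> str:
    consonants = "bcdfghjklmnpqrstvwxz"
    return "".join(rng.choice(list(consonants), size=5))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_scan(config: ScanConfig) -> ScanRecord:
    """Generate one deterministic multi-modal scan record."""
    rng = np.random.default_rng(config.seed)
    n_frames, size = config.n_frames, config.image_size

    # -- event timeline -----------------------------------------------------
    events, utterances = [], []
    t = float(rng.uniform(0.3, 1.0))
    margin = size // 5  # keep shapes fully inside the frame
    while True:
        ev_len = float(rng.uniform(2.0, 4.0))
        if t + ev_len > config.duration_s - 0.3:
            break
        anatomy_id = int(rng.integers(config.n_anatomy_classes))
        centroid = (
            int(rng.integers(margin, size - margin)),
            int(rng.integers(margin, size - margin)),
        )
        mask = _shape_mask(anatomy_id, centroid, size)
        keyword = config.anatomy_vocab[anatomy_id]
        events.append(
            AnatomyEvent(anatomy_id, t, t + ev_len, centroid, mask, keyword)
        )
        offtopic = bool(rng.random() < config.p_offtopic)
        # utterance interval inside the event so its midpoint is within the
        # event (hence within +-0.3 s of the event interval)
        seg_len = float(rng.uniform(1.0, min(2.0, ev_len - 0.4)))
        seg_start = t + float(rng.uniform(0.1, ev_len - seg_len - 0.1))
        utterances.append((seg_start, seg_start + seg_len, offtopic, events[-1]))
        t += ev_len + float(rng.uniform(0.8, 2.0))

    # -- frames, labels, gaze ------------------------------------------------
    frames = np.empty((n_frames, size, size), dtype=np.float32)
    plane_labels = np.full(n_frames, BACKGROUND_CLASS, dtype=np.int64)
    gaze = np.empty((n_frames, size, size), dtype=np.float32)
    bg_gaze = make_gaze_map(
        np.ones((size, size), dtype=bool), sigma_px=size / 2.0
    ).astype(np.float32)
    ev_idx = 0
    for i in range(n_frames):
        tm = (i + 0.5) / config.fps
        ev = next(
            (e for e in events if e.t_start <= tm < e.t_end), None
        )
        if ev is None:
            frames[i] = np.clip(
                np.abs(rng.normal(0.0, config.noise_sigma, size=(size, size))), 0, 1
            ).astype(np.float32)
            gaze[i] = bg_gaze
        else:
            img, mask = render_frame(
                ev.anatomy_id, ev.centroid, size, config.noise_sigma, rng
            )
            frames[i] = img
            plane_labels[i] = ev.anatomy_id
            gaze[i] = make_gaze_map(mask, sigma_px=size / 12.0).astype(np.float32)
            s = gaze[i].sum()
            gaze[i] /= s

    # -- waveform + transcript ----------------------------------------------
    wav = rng.normal(0.0, config.noise_sigma * 0.2, size=config.n_samples)
    segments = []
    anatomy_terms = set(config.anatomy_vocab)
    for seg_start, seg_end, offtopic, ev in utterances:
        i0 = int(round(seg_start * config.sample_rate))
        i1 = min(int(round(seg_end * config.sample_rate)), config.n_samples)
        if offtopic:
            f1, f2 = anatomy_signature(None, config.sample_rate)
            n_tok = int(rng.integers(3, 6))
            tokens = list(rng.choice(config.distractor_vocab, size=n_tok))
        else:
            f1, f2 = anatomy_signature(ev.anatomy_id, config.sample_rate)
            template = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
            tokens = list(template) + [ev.keyword]
        wav[i0:i1] += _tone_burst(f1, f2, seg_start, i1 - i0, config.sample_rate)
        tokens = [
            _corrupt_token(rng) if rng.random() < config.p_invalid_token else tok
            for tok in tokens
        ]
        segments.append(
            TranscriptSegment(
                start_s=round(seg_start, 4),
                end_s=round(seg_end, 4),
                speaker="sonographer",
                text=tuple(tokens),
                is_anatomy=any(tok in anatomy_terms for tok in tokens),
            )
        )
    waveform = Waveform(np.clip(wav, -1.0, 1.0), config.sample_rate)

    return ScanRecord(
        config=config,
        frames=frames,
        waveform=waveform,
        segments=segments,
        events=events,
        plane_labels=plane_labels,
        gaze_maps=gaze,
    )


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_scan(record: ScanRecord, out_dir, write_png: bool = True):
    """Write one scan directory: frames/ (PNG) + frames.npy, audio.wav,
    transcript.jsonl, events.json (+ event_masks.npy), gaze/gaze.npy,
    manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "frames.npy", record.frames)
    if write_png:
        fdir = out / "frames"
        fdir.mkdir(exist_ok=True)
        for i, frame in enumerate(record.frames):
            Image.fromarray((frame * 255).astype(np.uint8), mode="L").save(
                fdir / f"{i:05d}.png"
            )
    write_wav(out / "audio.wav", record.waveform)
    write_transcript(out / "transcript.jsonl", record.segments)
    (out / "gaze").mkdir(exist_ok=True)
    np.save(out / "gaze" / "gaze.npy", record.gaze_maps)
    np.save(out / "plane_labels.npy", record.plane_labels)
    np.save(
        out / "event_masks.npy",
        np.stack([e.region_mask for e in record.events])
        if record.events
        else np.zeros((0,) + record.frames.shape[1:], dtype=bool),
    )
    with open(out / "events.json", "w", encoding="utf-8") as fh:
        json.dump(
            [
                {
                    "anatomy_id": e.anatomy_id,
                    "t_start": e.t_start,
                    "t_end": e.t_end,
                    "centroid": list(e.centroid),
                    "keyword": e.keyword,
                }
                for e in record.events
            ],
            fh,
            indent=1,
        )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "frames": "frames.npy",
                "frames_png": "frames/",
                "audio": "audio.wav",
                "transcript": "transcript.jsonl",
                "events": "events.json",
                "gaze": "gaze/gaze.npy",
                "plane_labels": "plane_labels.npy",
                "fps": record.config.fps,
                "sample_rate": record.config.sample_rate,
                "seed": record.config.seed,
                "config": asdict(record.config),
            },
            fh,
            indent=1,
        )


def read_scan(scan_dir) -> ScanRecord:
    root = Path(scan_dir)
    with open(root / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    cfg_d = manifest["config"]
    cfg_d["anatomy_vocab"] = tuple(cfg_d["anatomy_vocab"])
    cfg_d["distractor_vocab"] = tuple(cfg_d["distractor_vocab"])
    config = ScanConfig(**cfg_d)
    frames = np.load(root / manifest["frames"])
    waveform = read_wav(root / manifest["audio"])
    segments = read_transcript(root / manifest["transcript"])
    gaze = np.load(root / manifest["gaze"])
    plane_labels = np.load(root / manifest["plane_labels"])
    masks = np.load(root / "event_masks.npy")
    with open(root / manifest["events"], encoding="utf-8") as fh:
        ev_meta = json.load(fh)
    events = [
        AnatomyEvent(
            anatomy_id=m["anatomy_id"],
            t_start=m["t_start"],
            t_end=m["t_end"],
            centroid=tuple(m["centroid"]),
            region_mask=masks[i],
            keyword=m["keyword"],
        )
        for i, m in enumerate(ev_meta)
    ]
    return ScanRecord(config, frames, waveform, segments, events, plane_labels, gaze)
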