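"""Audio cleaning chain and log-spectrogram front end.

The cleaning chain mirrors what a clinical audio pipeline does before any
learning happens: denoise, find speech, keep the dominant speaker (the
sonographer narrates far more than anyone else in the room), transcribe, and
keep the segments that mention anatomy keywords.  The neural denoiser, VAD,
diarizer and ASR that a production system would use are external pretrained
models; here each stage is a simple, well-defined stand-in behind the same
interface (an energy VAD, speaker labels carried on the transcript, ground
truth text with injected corruption), so real models can be dropped in.

The front end for the audio encoder is a 256x256 log-magnitude spectrogram
of a 0.6 s speech window: STFT with a 10 ms window, 5 ms hop and 256 linear
frequency bands, log(1+x) compressed, with the time axis linearly
interpolated to 256 columns.
"""

from __future__ import annotations

import json
from fractions import Fraction
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.signal
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "TranscriptSegment",
    "Spectrogram",
    "resample",
    "detect_voice_segments",
    "select_sonographer",
    "log_spectrogram",
    "select_keyword_segments",
    "load_keyword_dictionary",
    "read_wav",
    "write_wav",
    "read_transcript",
    "write_transcript",
    "SPECTROGRAM_SIZE",
    "STFT_WINDOW_S",
    "STFT_HOP_S",
    "AUDIO_RATE",
    "AUDIO_WINDOW_S",
]

#: STFT configuration: 10 ms window, 5 ms hop, 256 frequency bands,
#: 0.6 s windows resampled to 24 kHz.
SPECTROGRAM_SIZE = 256
STFT_WINDOW_S = 0.010
STFT_HOP_S = 0.005
AUDIO_RATE = 24_000
AUDIO_WINDOW_S = 0.6


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples in [-1, 1] at a fixed sample rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def slice_time(self, start_s: float, end_s: float) -> "Waveform":
        """Half-open time slice [start_s, end_s), zero-padded at the edges."""
        i0 = int(round(start_s * self.rate))
        i1 = int(round(end_s * self.rate))
        n = i1 - i0
        out = np.zeros(n, dtype=self.samples.dtype)
        lo, hi = max(i0, 0), min(i1, len(self.samples))
        if hi > lo:
            out[lo - i0 : hi - i0] = self.samples[lo:hi]
        return Waveform(out, self.rate)


@dataclass(frozen=True)
class TranscriptSegment:
    """One utterance: [start_s, end_s), speaker id, tokenised text."""

    start_s: float
    end_s: float
    speaker: str
    text: tuple = ()
    is_anatomy: bool = False

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError(
                f"segment needs start < end, got [{self.start_s}, {self.end_s})"
            )
        object.__setattr__(self, "text", tuple(self.text))

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Spectrogram:
    """256x256 log-magnitude time-frequency image of a 0.6 s window."""

    values: np.ndarray
    freq_range: tuple
    hop_s: float = STFT_HOP_S
    window_s: float = STFT_WINDOW_S

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float32)
        if v.shape != (SPECTROGRAM_SIZE, SPECTROGRAM_SIZE):
            raise ValueError(f"spectrogram must be 256x256, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrogram contains non-finite values")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# cleaning chain
# ---------------------------------------------------------------------------


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Polyphase resampling to ``target_rate`` (duration preserved)."""
    if target_rate <= 0:
        raise ValueError(f"target rate must be positive, got {target_rate}")
    if target_rate == w.rate:
        return w
    frac = Fraction(target_rate, w.rate)
    out = scipy.signal.resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(out, target_rate)


def denoise_identity(w: Waveform) -> Waveform:
    """Plug-in point for a speech-enhancement model; the default is identity."""
    return w


def detect_voice_segments(
    w: Waveform, frame_s: float = 0.05, energy_quantile: float = 0.5
) -> list:
    """Energy-based voice activity detection.

    Frames of ``frame_s`` whose RMS energy strictly exceeds the given
    quantile of all frame energies are voice; maximal voiced runs are
    returned as disjoint sorted half-open ``(start_s, end_s)`` intervals.
    Invariant to global amplitude scaling (the threshold scales with the
    energies).
    """
    if frame_s <= 0:
        raise ValueError("frame_s must be positive")
    if len(w.samples) == 0:
        raise ValueError("empty waveform")
    n = int(round(frame_s * w.rate))
    n_frames = max(len(w.samples) // n, 1)
    frames = w.samples[: n_frames * n].reshape(n_frames, n)
    rms = np.sqrt((frames**2).mean(axis=1))
    thr = np.quantile(rms, energy_quantile)
    voiced = rms > thr
    out = []
    i = 0
    while i < n_frames:
        if voiced[i]:
            j = i
            while j < n_frames and voiced[j]:
                j += 1
            out.append((i * n / w.rate, j * n / w.rate))
            i = j
        else:
            i += 1
    return out


def select_sonographer(segments: Sequence[TranscriptSegment]) -> str:
    """Dominant-speaker rule: the speaker with the most speech segments is
    taken to be the sonographer (ties broken by total speech duration, then
    lexicographically smallest speaker id)."""
    if not segments:
        raise ValueError("no segments to select a speaker from")
    counts: dict = {}
    durations: dict = {}
    for s in segments:
        counts[s.speaker] = counts.get(s.speaker, 0) + 1
        durations[s.speaker] = durations.get(s.speaker, 0.0) + s.duration_s
    return min(counts, key=lambda sp: (-counts[sp], -durations[sp], sp))


def select_keyword_segments(
    segments: Iterable[TranscriptSegment], dictionary: Iterable[str]
) -> list:
    """Flag segments whose text contains at least one dictionary keyword
    (exact token match after case-folding).  Idempotent."""
    terms = {t.lower() for t in dictionary}
    if not terms:
        raise ValueError("keyword dictionary is empty")
    return [
        replace(s, is_anatomy=any(tok.lower() in terms for tok in s.text))
        for s in segments
    ]


# ---------------------------------------------------------------------------
# spectrogram front end
# ---------------------------------------------------------------------------


def log_spectrogram(w: Waveform) -> Spectrogram:
    """256x256 log(1+|STFT|) image of a ~0.6 s window at 24 kHz.

    nfft = 512 gives 257 linear bins; the Nyquist bin is dropped to leave
    exactly 256 frequency bands, so band k spans frequencies around
    ``k * rate / 512``.  A 0.6 s window at a 5 ms hop yields ~121 STFT
    frames; the time axis is linearly interpolated to 256 columns.
    """
    nperseg = int(round(STFT_WINDOW_S * w.rate))
    if len(w.samples) < nperseg:
        raise ValueError(
            f"waveform of {len(w.samples)} samples shorter than one "
            f"{nperseg}-sample window"
        )
    hop = int(round(STFT_HOP_S * w.rate))
    nfft = 2 * SPECTROGRAM_SIZE
    _, _, z = scipy.signal.stft(
        w.samples,
        fs=w.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        nfft=nfft,
        boundary=None,
        padded=False,
    )
    mag = np.log1p(np.abs(z[:SPECTROGRAM_SIZE]))  # drop the Nyquist bin
    n_t = mag.shape[1]
    if n_t != SPECTROGRAM_SIZE:
        src = np.linspace(0.0, 1.0, n_t)
        dst = np.linspace(0.0, 1.0, SPECTROGRAM_SIZE)
        mag = np.stack([np.interp(dst, src, row) for row in mag])
    return Spectrogram(mag.astype(np.float32), freq_range=(0.0, w.rate / 2))


def spectrogram_for_window(w: Waveform, t: float) -> Spectrogram:
    """Spectrogram of the 0.6 s window centred at ``t`` (resampled to 24 kHz)."""
    win = w.slice_time(t - AUDIO_WINDOW_S / 2, t + AUDIO_WINDOW_S / 2)
    return log_spectrogram(resample(win, AUDIO_RATE))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Waveform(data, int(rate))


def write_wav(path, w: Waveform):
    pcm = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.rate, (pcm * 32767).astype(np.int16))


def read_transcript(path) -> list:
    segments = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            segments.append(
                TranscriptSegment(
                    start_s=obj["start_s"],
                    end_s=obj["end_s"],
                    speaker=obj["speaker"],
                    text=tuple(obj["text"].split()),
                    is_anatomy=obj.get("is_anatomy", False),
                )
            )
    return segments


def write_transcript(path, segments: Iterable[TranscriptSegment]):
    with open(path, "w", encoding="utf-8") as fh:
        for s in segments:
            fh.write(
                json.dumps(
                    {
                        "start_s": s.start_s,
                        "end_s": s.end_s,
                        "speaker": s.speaker,
                        "text": " ".join(s.text),
                        "is_anatomy": s.is_anatomy,
                    }
                )
                + "\n"
            )


def load_keyword_dictionary(path) -> set:
    """Keyword file: UTF-8, one lowercase term per line."""
    with open(path, encoding="utf-8") as fh:
        terms = {line.strip().lower() for line in fh if line.strip()}
    if not terms:
        raise ValueError(f"keyword dictionary {path} is empty")
    return terms
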