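"""Audio cleaning chain and the log-spectrogram front end."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echofuse.audio import (
    AUDIO_RATE,
    TranscriptSegment,
    Waveform,
    detect_voice_segments,
    load_keyword_dictionary,
    log_spectrogram,
    resample,
    select_keyword_segments,
    select_sonographer,
)


def tone(freq, duration_s, rate, amp=0.5):
    t = np.arange(int(duration_s * rate)) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq * t), rate)


class TestResample:
    def test_sample_count_arithmetic(self):
        w = tone(440, 0.6, 48_000)
        out = resample(w, 24_000)
        assert out.rate == 24_000
        assert len(out.samples) == 14_400

    def test_identity_at_same_rate(self):
        w = tone(440, 0.2, 24_000)
        assert resample(w, 24_000) is w

    def test_spectral_peak_preserved(self):
        out = resample(tone(1000, 0.5, 48_000), 24_000)
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out.samples), 1 / out.rate)
        assert abs(freqs[spec.argmax()] - 1000) < 10

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            resample(tone(440, 0.1, 24_000), 0)


class TestVoiceActivityDetection:
    def test_silence_gives_no_segments(self):
        w = Waveform(np.zeros(24_000), 24_000)
        assert detect_voice_segments(w) == []

    def test_single_tone_interval_recovered(self):
        rate, frame_s = 24_000, 0.05
        x = np.zeros(3 * rate)
        t = np.arange(rate) / rate
        x[rate : 2 * rate] = 0.5 * np.sin(2 * np.pi * 500 * t)
        segs = detect_voice_segments(Waveform(x, rate), frame_s, 0.5)
        assert len(segs) == 1
        s, e = segs[0]
        assert abs(s - 1.0) <= frame_s and abs(e - 2.0) <= frame_s

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 24_000) * (rng.random(24_000) > 0.5)
        w1 = Waveform(np.clip(x, -1, 1), 24_000)
        w2 = Waveform(np.clip(0.1 * x, -1, 1), 24_000)
        assert detect_voice_segments(w1) == detect_voice_segments(w2)

    def test_intervals_disjoint_sorted(self):
        rng = np.random.default_rng(1)
        w = Waveform(rng.normal(0, 0.2, 48_000), 24_000)
        segs = detect_voice_segments(w)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            assert s1 < e1 <= s2 < e2

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            detect_voice_segments(Waveform(np.array([]), 24_000))


def seg(start, end, speaker="A", text=()):
    return TranscriptSegment(start, end, speaker, tuple(text))


class TestSelectSonographer:
    def test_majority_speaker_wins(self):
        segs = [seg(0, 1), seg(2, 3), seg(4, 5), seg(6, 7, "B")]
        assert select_sonographer(segs) == "A"

    def test_single_speaker(self):
        assert select_sonographer([seg(0, 1, "Z")]) == "Z"

    def test_duration_tie_break(self):
        segs = [seg(0, 3, "A"), seg(4, 6, "A"), seg(10, 11, "B"), seg(12, 14, "B")]
        # both have 2 segments; A speaks 5 s vs B 3 s
        assert select_sonographer(segs) == "A"

    def test_lexicographic_final_tie_break(self):
        segs = [seg(0, 1, "B"), seg(2, 3, "A")]
        assert select_sonographer(segs) == "A"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_sonographer([])


class TestLogSpectrogram:
    def test_output_shape_256(self):
        assert log_spectrogram(tone(440, 0.6, AUDIO_RATE)).values.shape == (256, 256)

    def test_silence_maps_to_zero(self):
        w = Waveform(np.zeros(int(0.6 * AUDIO_RATE)), AUDIO_RATE)
        np.testing.assert_allclose(log_spectrogram(w).values, 0.0, atol=1e-12)

    def test_6khz_tone_hits_band_128(self):
        spec = log_spectrogram(tone(6000, 0.6, AUDIO_RATE)).values
        band = np.unravel_index(spec.argmax(), spec.shape)[0]
        assert band == 128  # 6 kHz over a 12 kHz Nyquist, 256 linear bands

    @pytest.mark.parametrize("duration", [0.55, 0.58, 0.6, 0.62, 0.65])
    def test_shape_invariant_to_duration_jitter(self, duration):
        assert log_spectrogram(tone(500, duration, AUDIO_RATE)).values.shape == (256, 256)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            log_spectrogram(Waveform(np.zeros(100), AUDIO_RATE))


class TestKeywordSelection:
    DICT = {"heart", "femur", "kidneys"}

    def test_anatomy_segment_flagged(self):
        out = select_keyword_segments([seg(0, 1, text=("this", "is", "the", "heart"))],
                                      self.DICT)
        assert out[0].is_anatomy

    def test_smalltalk_not_flagged(self):
        out = select_keyword_segments([seg(0, 1, text=("how", "are", "you"))], self.DICT)
        assert not out[0].is_anatomy

    def test_case_folding(self):
        out = select_keyword_segments([seg(0, 1, text=("HEART",))], self.DICT)
        assert out[0].is_anatomy

    def test_empty_inputs(self):
        assert select_keyword_segments([], self.DICT) == []
        with pytest.raises(ValueError):
            select_keyword_segments([seg(0, 1)], set())

    def test_idempotent(self):
        segs = [seg(0, 1, text=("femur",)), seg(2, 3, text=("hello",))]
        once = select_keyword_segments(segs, self.DICT)
        twice = select_keyword_segments(once, self.DICT)
        assert once == twice


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_vad_partition_covers_duration(seed):
    """Detected intervals and their complement tile [0, duration)."""
    rng = np.random.default_rng(seed)
    samples = np.clip(rng.normal(0, 0.3, 2400) * (rng.random(2400) > 0.3), -1, 1)
    w = Waveform(samples, 24_000)
    segs = detect_voice_segments(w, frame_s=0.01)
    n_frames = len(samples) // 240
    covered = sum(round((e - s) / 0.01) for s, e in segs)
    voiced_bounds_ok = all(0 <= s < e <= n_frames * 0.01 + 1e-9 for s, e in segs)
    assert voiced_bounds_ok and 0 <= covered <= n_frames


def test_keyword_dictionary_file_roundtrip(tmp_path):
    p = tmp_path / "dict.txt"
    p.write_text("heart\nfemur\n\nkidneys\n", encoding="utf-8")
    assert load_keyword_dictionary(p) == {"heart", "femur", "kidneys"}
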