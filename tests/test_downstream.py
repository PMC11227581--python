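"""Downstream transfer tasks: SPD head, saliency distributions, localisation."""

import numpy as np
import pytest

from echofuse import nn
from echofuse.audio import Waveform
from echofuse.downstream import (
    AudioVisualLocalizer,
    LocalisationMap,
    PlaneClassifier,
    SaliencyMap,
    SaliencyPredictor,
    labelled_frames,
    localisation_hit_rate,
    localise_from_audio,
    scan_folds,
)
from echofuse.labels import N_PLANE_CLASSES
from echofuse.metrics import saliency_metrics
from echofuse.pretrain import MultiModalPretrainer, sample_pairs


@pytest.fixture(scope="module")
def labelled(tiny_scans):
    return labelled_frames(tiny_scans)


class TestPlaneClassifier:
    def test_head_has_14_outputs(self, labelled):
        X, y, _, _ = labelled
        clf = PlaneClassifier(embed_dim=8, epochs=1, seed=0).fit(X[:12], y[:12])
        proba = clf.predict_proba(X[:4])
        assert proba.shape == (4, N_PLANE_CLASSES)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_label_out_of_range_rejected(self, labelled):
        X, y, _, _ = labelled
        bad = y.copy()
        bad[0] = N_PLANE_CLASSES
        with pytest.raises(ValueError, match="labels"):
            PlaneClassifier(embed_dim=8, epochs=1).fit(X, bad)

    def test_random_init_control_trains_under_same_schedule(self, labelled):
        X, y, _, _ = labelled
        clf = PlaneClassifier(pretrained=None, embed_dim=8, epochs=1, seed=0)
        clf.fit(X[:12], y[:12])
        assert clf.predict(X[:3]).shape == (3,)

    def test_pretrained_init_loads_encoder_weights(self, labelled, mini_model):
        X, y, _, _ = labelled
        clf = PlaneClassifier(pretrained=mini_model, epochs=0 + 1, seed=0)
        clf.fit(X[:12], y[:12])
        assert clf.encoder_.embed_dim == mini_model.embed_dim


class TestSaliencyPredictor:
    def test_predictions_are_distributions(self, labelled):
        X, _, G, _ = labelled
        model = SaliencyPredictor(embed_dim=8, epochs=1, seed=0).fit(X[:10], G[:10])
        preds = model.predict(X[:4])
        assert preds.shape == (4, X.shape[1], X.shape[2])
        np.testing.assert_allclose(preds.sum(axis=(1, 2)), 1.0, atol=1e-5)
        assert np.all(preds >= 0)

    def test_unnormalised_targets_rejected(self, labelled):
        X, _, G, _ = labelled
        with pytest.raises(ValueError, match="normalis"):
            SaliencyPredictor(embed_dim=8, epochs=1).fit(X[:4], 2.0 * G[:4])

    def test_trained_model_beats_mean_map_on_heldout(self, labelled):
        X, _, G, sid = labelled
        train, test = sid == 0, sid == 1
        model = SaliencyPredictor(embed_dim=16, epochs=12, lr=0.02, seed=0)
        model.fit(X[train], G[train])
        preds = model.predict(X[test])
        mean_map = G[train].mean(axis=0)
        mean_map /= mean_map.sum()
        kl_model, kl_mean = [], []
        for p, g in zip(preds, G[test]):
            fix = [np.unravel_index(g.argmax(), g.shape)]
            kl_model.append(saliency_metrics(p, g, fix).KL)
            kl_mean.append(saliency_metrics(mean_map, g, fix).KL)
        assert np.mean(kl_model) < np.mean(kl_mean)


class TestLocalisation:
    def _window(self, scan, t):
        return scan.waveform.slice_time(t - 0.3, t + 0.3)

    def test_map_properties(self, mini_model, tiny_scans):
        ex = sample_pairs(tiny_scans, 3, 0.0, np.random.default_rng(0))[0]
        w = self._window(tiny_scans[ex.scan_idx], ex.t)
        m = localise_from_audio(mini_model, ex.clip, w, np.random.default_rng(1))
        assert m.values.shape == ex.clip.shape[1:]
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_inference_is_text_free(self, mini_model, tiny_scans):
        """Deleting the text branch weights does not change the output."""
        ex = sample_pairs(tiny_scans, 3, 0.0, np.random.default_rng(0))[0]
        w = self._window(tiny_scans[ex.scan_idx], ex.t)
        before = localise_from_audio(mini_model, ex.clip, w, np.random.default_rng(2))
        saved = mini_model.text_embedder_.state_dict()
        try:
            mini_model.text_embedder_.load_state_dict(
                {k: np.zeros_like(v) for k, v in saved.items()}
            )
            for p in mini_model.sig_.parameters():
                p.data = np.zeros_like(p.data)
            after = localise_from_audio(mini_model, ex.clip, w, np.random.default_rng(2))
        finally:
            mini_model.text_embedder_.load_state_dict(saved)
        np.testing.assert_array_equal(before.values, after.values)

    def test_nonspatial_model_rejected(self, tiny_scans):
        est = MultiModalPretrainer(
            variant="base", embed_dim=8, epochs=1, n_examples=20, seed=0
        ).fit(tiny_scans)
        ex = sample_pairs(tiny_scans, 1, 0.0, np.random.default_rng(0))[0]
        w = self._window(tiny_scans[ex.scan_idx], ex.t)
        with pytest.raises(ValueError, match="spatial"):
            localise_from_audio(est, ex.clip, w)

    def test_zeroed_audio_branch_gives_flat_guarded_map(self, mini_model, tiny_scans):
        ex = sample_pairs(tiny_scans, 1, 0.0, np.random.default_rng(0))[0]
        w = self._window(tiny_scans[ex.scan_idx], ex.t)

        class _ZeroAudio:
            def __call__(self, spec):
                return nn.Tensor(np.zeros((1, mini_model.embed_dim), np.float32))

        real = mini_model.audio_encoder_
        try:
            mini_model.audio_encoder_ = _ZeroAudio()
            m = localise_from_audio(mini_model, ex.clip, w, np.random.default_rng(1))
        finally:
            mini_model.audio_encoder_ = real
        assert np.all(np.isfinite(m.values))
        np.testing.assert_array_equal(m.values, 0.0)

    def test_offtopic_audio_still_finite(self, mini_model, tiny_scans):
        rng = np.random.default_rng(0)
        ex = sample_pairs(tiny_scans, 1, 0.0, rng)[0]
        neutral = Waveform(
            0.3 * np.sin(2 * np.pi * 250 * np.arange(14_400) / 24_000), 24_000
        )
        m = localise_from_audio(mini_model, ex.clip, neutral, rng)
        assert np.all(np.isfinite(m.values))

    def test_hit_rate_in_unit_interval(self, mini_model, tiny_scans):
        rate = localisation_hit_rate(mini_model, tiny_scans, n=10, seed=0)
        assert 0.0 <= rate <= 1.0

    def test_transform_wrapper(self, mini_model, tiny_scans):
        ex = sample_pairs(tiny_scans, 2, 0.0, np.random.default_rng(0))
        pairs = [
            (e.clip, self._window(tiny_scans[e.scan_idx], e.t)) for e in ex
        ]
        maps = AudioVisualLocalizer(mini_model, seed=0).transform(pairs)
        assert len(maps) == 2 and all(isinstance(m, LocalisationMap) for m in maps)


class TestDataHelpers:
    def test_labelled_frames_match_events(self, tiny_scans, labelled):
        X, y, G, sid = labelled
        n_events = sum(len(s.events) for s in tiny_scans)
        assert len(X) >= n_events
        assert set(np.unique(sid)) == {0, 1}
        np.testing.assert_allclose(G.sum(axis=(1, 2)), 1.0, atol=1e-5)

    def test_scan_folds_partition_scans(self):
        folds = scan_folds(9, n_folds=3, seed=0)
        assert len(folds) == 9
        assert set(folds) == {0, 1, 2}

    def test_saliency_map_type_validates(self):
        with pytest.raises(ValueError):
            SaliencyMap(np.ones((4, 4)), normalized=True)
        SaliencyMap(np.ones((4, 4)) / 16, normalized=True)
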