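"""Classification, saliency and compactness metrics against counting oracles."""

import numpy as np
import pytest

from echofuse.metrics import classification_report, comp_metric, saliency_metrics


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1, 0])
        rep = classification_report(y, y, 3)
        np.testing.assert_array_equal(rep["precision"], 1.0)
        np.testing.assert_array_equal(rep["recall"], 1.0)
        assert rep["macro_f1"] == 1.0

    def test_hand_counted_case(self):
        rep = classification_report([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert rep["precision"][1] == pytest.approx(1.0)
        assert rep["recall"][1] == pytest.approx(2 / 3)
        assert rep["f1"][1] == pytest.approx(0.8)

    def test_confusion_matrix_conserves_counts(self, rng):
        pred = rng.integers(0, 5, 200)
        true = rng.integers(0, 5, 200)
        rep = classification_report(pred, true, 5)
        assert rep["confusion_matrix"].sum() == 200
        np.testing.assert_array_equal(
            rep["confusion_matrix"].sum(axis=1), np.bincount(true, minlength=5)
        )

    def test_agrees_with_brute_force_counting_oracle(self, rng):
        pred = rng.integers(0, 7, 1000)
        true = rng.integers(0, 7, 1000)
        rep = classification_report(pred, true, 7)
        for k in range(7):
            tp = int(((pred == k) & (true == k)).sum())
            fp = int(((pred == k) & (true != k)).sum())
            fn = int(((pred != k) & (true == k)).sum())
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert rep["precision"][k] == pytest.approx(prec)
            assert rep["recall"][k] == pytest.approx(rec)

    def test_macro_ignores_unsupported_classes(self):
        rep = classification_report([0, 0], [0, 0], 3)
        assert rep["macro_f1"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_report([0], [0, 1], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            classification_report([0, 5], [0, 1], 2)


class TestSaliencyMetrics:
    def test_identity_cases(self):
        rng = np.random.default_rng(0)
        g = rng.random((16, 16))
        g /= g.sum()
        m = saliency_metrics(g, g, [(3, 3)])
        assert m.KL == pytest.approx(0.0, abs=1e-6)
        assert m.CC == pytest.approx(1.0, abs=1e-6)
        assert m.SIM == pytest.approx(1.0, abs=1e-6)

    def test_constant_prediction_degenerates_gracefully(self):
        pred = np.full((8, 8), 1 / 64)
        gt = np.zeros((8, 8))
        gt[2, 2] = 1.0
        m = saliency_metrics(pred, gt, [(2, 2)])
        assert m.NSS == 0.0
        assert m.AUC == pytest.approx(0.5)

    def test_sim_hand_example(self):
        gt = np.array([[0.7, 0.1], [0.1, 0.1]])
        pred = np.array([[0.4, 0.2], [0.2, 0.2]])
        m = saliency_metrics(pred, gt, [(0, 0)])
        assert m.SIM == pytest.approx(0.7, abs=1e-9)

    def test_nss_rewards_mass_at_fixations(self):
        peaked = np.zeros((8, 8))
        peaked[4, 4] = 1.0
        m = saliency_metrics(peaked, peaked, [(4, 4)])
        assert m.NSS > 1.0
        assert m.AUC > 0.9

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="normalis"):
            saliency_metrics(np.ones((4, 4)), np.ones((4, 4)) / 16, [(0, 0)])

    def test_empty_fixations_rejected(self):
        g = np.ones((4, 4)) / 16
        with pytest.raises(ValueError, match="fixation"):
            saliency_metrics(g, g, [])


class TestCompMetric:
    def _hand_map(self):
        pred = np.zeros((4, 4))
        pred[0, 0] = pred[0, 1] = 1.0
        pred[0, 2] = pred[0, 3] = 0.4
        return pred

    def test_hand_worked_example(self):
        pred = self._hand_map()
        ref = (pred > 0).astype(float)
        r = comp_metric(pred, ref, thres=0.5)
        assert r.alpha_S == pytest.approx(0.25)
        assert r.alpha_H == pytest.approx(0.125)
        assert r.eta_H == pytest.approx(0.5)
        assert r.iou == pytest.approx(1.0)
        assert r.comp == pytest.approx(2.0)

    def test_disjoint_supports_give_zero(self):
        pred = np.zeros((4, 4))
        pred[0, 0] = 1.0
        ref = np.zeros((4, 4))
        ref[3, 3] = 1.0
        assert comp_metric(pred, ref).comp == 0.0

    def test_compactness_increases_as_support_shrinks(self):
        ref = np.zeros((8, 8))
        ref[:2, :2] = 1.0
        wide = np.zeros((8, 8))
        wide[:4, :4] = 1.0
        tight = np.zeros((8, 8))
        tight[:2, :2] = 1.0
        assert comp_metric(tight, ref).comp > comp_metric(wide, ref).comp

    def test_resolution_invariance_under_nearest_upsampling(self):
        pred = self._hand_map()
        ref = (pred > 0).astype(float)
        small = comp_metric(pred, ref)
        big = comp_metric(np.kron(pred, np.ones((4, 4))), np.kron(ref, np.ones((4, 4))))
        assert big.comp == pytest.approx(small.comp)
        assert big.alpha_S == pytest.approx(small.alpha_S)

    def test_raw_counts_option(self):
        pred = self._hand_map()
        r = comp_metric(pred, (pred > 0).astype(float), raw_counts=True)
        assert r.alpha_S == 4 and r.alpha_H == 2
        assert r.eta_H == pytest.approx(0.5)

    def test_all_zero_prediction_flagged_invalid(self):
        r = comp_metric(np.zeros((4, 4)), np.ones((4, 4)))
        assert not r.valid
        assert np.isnan(r.comp)

    def test_invariants_on_random_maps(self, rng):
        for _ in range(20):
            pred = rng.random((8, 8)) * (rng.random((8, 8)) > 0.5)
            if pred.max() > 0:
                pred = pred / pred.max()
            ref = (rng.random((8, 8)) > 0.7).astype(float)
            r = comp_metric(pred, ref)
            if r.valid:
                assert 0 <= r.alpha_H <= r.alpha_S <= 1
                assert 0 <= r.eta_H <= 1
                assert 0 <= r.iou <= 1
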