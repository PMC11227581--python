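"""Fusion heads and training objectives against hand-computed oracles."""

import numpy as np
import pytest

from echofuse import nn
from echofuse.objectives import (
    ConcatFusionHead,
    CorrespondenceBatch,
    ObjectiveWeights,
    SimilarityMatrix,
    SpatialFusionHead,
    joint_loss,
    loss_base,
    loss_contrastive,
    similarity_matrix,
    spatial_objective,
)


class TestObjectiveWeights:
    def test_default_equal_weights_sum_to_one(self):
        w = ObjectiveWeights()
        assert w.alpha == w.beta == w.gamma == w.delta == 0.25

    def test_degenerate_single_term_allowed(self):
        ObjectiveWeights(1.0, 0.0, 0.0, 0.0)

    def test_rejects_bad_sum(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ObjectiveWeights(0.5, 0.5, 0.5, 0.5)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ObjectiveWeights(1.5, -0.5, 0.0, 0.0)


class TestLossBase:
    def test_maximum_entropy_is_ln2(self):
        p = np.full(8, 0.5)
        c = np.tile([0, 1], 4)
        assert loss_base(p, c).item() == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_prediction_tends_to_zero(self):
        p = np.array([1.0, 0.0, 1.0])
        c = np.array([1, 0, 1])
        assert loss_base(p, c).item() < 1e-5

    def test_hand_computed_two_pair_case(self):
        # c=(1,0), p=(0.8,0.3): -(ln 0.8 + ln 0.7)/2
        val = loss_base(np.array([0.8, 0.3]), np.array([1, 0])).item()
        assert val == pytest.approx(0.2899092, abs=1e-6)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, size=10)
            c = rng.integers(0, 2, size=10)
            assert loss_base(p, c).item() >= 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            loss_base(np.array([1.2]), np.array([1]))


class TestLossContrastive:
    def test_literal_two_pair_hand_case(self):
        # raw scores s11=1, s21=0 -> anchor 1 literal loss = -log(e/1) = -1
        S = SimilarityMatrix(nn.Tensor(np.exp(np.array([[1.0, 0.2], [0.0, 0.7]]))), 1.0)
        per = loss_contrastive(S, "literal", per_anchor=True)
        assert per.data[0] == pytest.approx(-1.0, abs=1e-6)

    def test_infonce_two_pair_hand_case(self):
        S = SimilarityMatrix(nn.Tensor(np.exp(np.array([[1.0, 0.2], [0.0, 0.7]]))), 1.0)
        per = loss_contrastive(S, "infonce", per_anchor=True)
        assert per.data[0] == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-6)

    def test_uniform_similarities_give_ln_n(self):
        for n in (2, 5, 9):
            S = SimilarityMatrix(nn.Tensor(np.full((n, n), 3.7)), 0.1)
            assert loss_contrastive(S).item() == pytest.approx(np.log(n), abs=1e-9)

    def test_strictly_decreasing_in_positive_similarity(self):
        base = np.exp(np.random.default_rng(0).normal(size=(4, 4)))
        losses = []
        for bump in (0.0, 0.5, 1.0):
            m = base.copy()
            m[np.arange(4), np.arange(4)] += bump
            losses.append(loss_contrastive(SimilarityMatrix(nn.Tensor(m), 1.0)).item())
        assert losses[0] > losses[1] > losses[2]

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            loss_contrastive(SimilarityMatrix(nn.Tensor(np.ones((1, 1))), 1.0))


class TestFusion:
    def test_concat_probability_in_open_interval(self, rng):
        head = ConcatFusionHead(8, seed=0)
        p = head(rng.normal(size=(5, 8)), rng.normal(size=(5, 8))).data
        assert np.all((p > 0) & (p < 1))

    def test_concat_zero_weights_give_exactly_half(self, rng):
        head = ConcatFusionHead(8, seed=0)
        for par in head.parameters():
            par.data = np.zeros_like(par.data)
        p = head(rng.normal(size=(3, 8)), rng.normal(size=(3, 8))).data
        np.testing.assert_array_equal(p, 0.5)

    def test_concat_dimension_mismatch_rejected(self, rng):
        head = ConcatFusionHead(8, seed=0)
        with pytest.raises(ValueError):
            head(rng.normal(size=(3, 8)), rng.normal(size=(3, 4)))

    def test_spatial_response_hand_example(self):
        head = SpatialFusionHead(2, seed=0)
        v_map = np.array([[[[1.0, 0.0], [2.0, 0.0]], [[0.0, 1.0], [0.0, 3.0]]]])
        a = np.array([[1.0, 0.0]])
        r = head.response_map(nn.Tensor(v_map), nn.Tensor(a)).data
        np.testing.assert_allclose(r[0], [[1.0, 0.0], [2.0, 0.0]])

    def test_spatial_zero_audio_gives_zero_response(self, rng):
        head = SpatialFusionHead(6, seed=0)
        v_map = nn.Tensor(rng.normal(size=(2, 6, 3, 3)))
        r = head.response_map(v_map, nn.Tensor(np.zeros((2, 6)))).data
        np.testing.assert_array_equal(r, 0.0)

    def test_spatial_response_matches_explicit_loop_oracle(self, rng):
        head = SpatialFusionHead(5, seed=0)
        v_map = rng.normal(size=(3, 5, 4, 4))
        a = rng.normal(size=(3, 5))
        r = head.response_map(nn.Tensor(v_map), nn.Tensor(a)).data
        oracle = np.zeros((3, 4, 4))
        for b in range(3):
            for h in range(4):
                for w in range(4):
                    oracle[b, h, w] = float(np.dot(v_map[b, :, h, w], a[b]))
        assert np.abs(r - oracle).max() < 1e-6


class TestSpatialObjective:
    def test_decomposes_into_base_plus_contrastive(self, rng):
        head = SpatialFusionHead(4, seed=2)
        v = nn.Tensor(rng.normal(size=(4, 4, 2, 2)).astype(np.float64))
        a = nn.Tensor(rng.normal(size=(4, 4)))
        c = np.array([1, 1, 0, 1])
        total = spatial_objective(head, v, a, c, tau=0.5).item()
        _, p = head(v, a)
        base = loss_base(p.detach(), c).item()
        pooled = v.data.mean(axis=(2, 3))
        raw = pooled @ a.data.T
        contra = loss_contrastive(
            SimilarityMatrix(nn.Tensor(np.exp(raw / 0.5)), 0.5)
        ).item()
        assert total == pytest.approx(base + contra, abs=1e-9)

    def test_zero_audio_contrastive_term_is_ln_n(self, rng):
        head = SpatialFusionHead(4, seed=2)
        v = nn.Tensor(rng.normal(size=(5, 4, 2, 2)))
        a = nn.Tensor(np.zeros((5, 4)))
        c = np.ones(5, dtype=int)
        total = spatial_objective(head, v, a, c).item()
        _, p = head(v, a)
        base = loss_base(p.detach(), c).item()
        assert total == pytest.approx(base + np.log(5), abs=1e-9)

    def test_gradient_reaches_every_spatial_cell(self, rng):
        head = SpatialFusionHead(4, seed=2)
        v = nn.Tensor(rng.normal(size=(3, 4, 2, 2)))
        v.requires_grad = True
        a = nn.Tensor(rng.normal(size=(3, 4)))
        spatial_objective(head, v, a, np.array([1, 0, 1])).backward()
        assert np.all(v.grad != 0)


class TestJointLoss:
    def _batch(self, rng, n=6, with_text=True, spatial=False):
        shape = (n, 8, 3, 3) if spatial else (n, 8)
        return CorrespondenceBatch(
            video=nn.Tensor(rng.normal(size=shape)),
            audio=nn.Tensor(rng.normal(size=(n, 8))),
            labels=np.tile([1, 0], n // 2),
            text=nn.Tensor(rng.normal(size=(n, 8))) if with_text else None,
            text_empty=np.zeros(n, dtype=bool) if with_text else None,
        )

    def test_degenerate_weights_equal_base_alone(self, rng):
        batch = self._batch(rng, with_text=False)
        head = ConcatFusionHead(8, seed=0)
        w = ObjectiveWeights(1.0, 0.0, 0.0, 0.0)
        total = joint_loss(batch, w, va_head=head).item()
        base = loss_base(head(batch.video, batch.audio).detach(), batch.labels).item()
        assert total == pytest.approx(base, abs=1e-12)

    def test_decomposition_against_separately_computed_terms(self, rng):
        batch = self._batch(rng)
        va, vt = ConcatFusionHead(8, seed=0), ConcatFusionHead(8, seed=1)
        w = ObjectiveWeights()
        total = joint_loss(batch, w, va_head=va, vt_head=vt, tau=0.2).item()
        pos = batch.labels == 1
        base_va = loss_base(va(batch.video, batch.audio).detach(), batch.labels).item()
        base_vt = loss_base(vt(batch.video, batch.text).detach(), batch.labels).item()
        contra_va = loss_contrastive(
            similarity_matrix(batch.video[pos].detach(), batch.audio[pos].detach(), 0.2)
        ).item()
        contra_vt = loss_contrastive(
            similarity_matrix(batch.video[pos].detach(), batch.text[pos].detach(), 0.2)
        ).item()
        expected = 0.25 * (base_va + base_vt + contra_va + contra_vt)
        assert total == pytest.approx(expected, abs=1e-9)

    def test_all_text_empty_drops_text_terms(self, rng):
        batch = self._batch(rng)
        batch.text_empty = np.ones(batch.n, dtype=bool)
        va, vt = ConcatFusionHead(8, seed=0), ConcatFusionHead(8, seed=1)
        w = ObjectiveWeights()
        total = joint_loss(batch, w, va_head=va, vt_head=vt).item()
        pos = batch.labels == 1
        base_va = loss_base(va(batch.video, batch.audio).detach(), batch.labels).item()
        contra_va = loss_contrastive(
            similarity_matrix(batch.video[pos].detach(), batch.audio[pos].detach())
        ).item()
        assert total == pytest.approx(0.25 * (base_va + contra_va), abs=1e-9)

    def test_linear_in_component_losses(self, rng):
        batch = self._batch(rng, with_text=False)
        head = ConcatFusionHead(8, seed=0)
        l_base = joint_loss(batch, ObjectiveWeights(1, 0, 0, 0), head).item()
        l_contra = joint_loss(batch, ObjectiveWeights(0, 0, 1, 0), head).item()
        l_mix = joint_loss(batch, ObjectiveWeights(0.3, 0, 0.7, 0), head).item()
        assert l_mix == pytest.approx(0.3 * l_base + 0.7 * l_contra, abs=1e-9)

    def test_spatial_softmax_pool_is_finite(self, rng):
        batch = self._batch(rng, spatial=True)
        va, vt = SpatialFusionHead(8, seed=0), SpatialFusionHead(8, seed=1)
        total = joint_loss(batch, ObjectiveWeights(), va, vt, spatial_pool="softmax")
        assert np.isfinite(total.item())


def test_similarity_matrix_entries_positive(rng):
    v, a = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
    S = similarity_matrix(nn.Tensor(v), nn.Tensor(a), tau=0.1)
    assert np.all(S.values.data > 0)
    # entry (j, i) is exp(cos(v_j, a_i)/tau)
    cos = (v[2] / np.linalg.norm(v[2])) @ (a[1] / np.linalg.norm(a[1]))
    assert S.values.data[2, 1] == pytest.approx(np.exp(cos / 0.1), rel=1e-6)
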