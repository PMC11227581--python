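"""Fusion strategies and training objectives.

The framework trains on four composable terms over a batch of (video,
audio, text) triples with correspondence labels c in {0, 1}:

* correspondence loss ``L_base`` — binary cross-entropy on the fused
  probability that a pair was recorded together,
* cross-modal contrastive loss ``L_contra`` — per matched anchor i,
  ``-log( sim(V_i, A_i) / sum_j sim(V_j, A_i) )`` with in-batch negatives,
  where ``sim(x, y) = exp(cos(x, y) / tau)``; ``mode="literal"`` drops the
  j = i term from the denominator (as the formula is sometimes printed,
  allowing negative values), ``mode="infonce"`` (default) keeps it,
* the spatial objective — ``L_base + L_contra`` evaluated on spatial video
  features through the element-wise dot-product fusion,
* the joint loss — ``alpha*L_base(V,A) + beta*L_base(V,T) +
  gamma*L_contra(V,A) + delta*L_contra(V,T)`` with the four weights summing
  to 1 (equal by default).  Pairs whose gated text feature is empty are
  excluded from the two text terms, with the denominators renormalised over
  the remaining pairs.

Two fusion strategies produce the correspondence probability: concatenation
(pooled features -> fully-connected head -> sigmoid) and spatial-aware
fusion (dot product between the audio vector and every cell of the visual
feature map; the response map is exposed for localisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "ObjectiveWeights",
    "CorrespondenceBatch",
    "SimilarityMatrix",
    "ConcatFusionHead",
    "SpatialFusionHead",
    "fuse_concat",
    "fuse_spatial",
    "loss_base",
    "loss_contrastive",
    "similarity_matrix",
    "spatial_objective",
    "joint_loss",
    "DEFAULT_TAU",
]

DEFAULT_TAU = 0.1
_EPS = 1e-7


@dataclass(frozen=True)
class ObjectiveWeights:
    """Convex weights (alpha, beta, gamma, delta) of the four loss terms."""

    alpha: float = 0.25
    beta: float = 0.25
    gamma: float = 0.25
    delta: float = 0.25

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.gamma, self.delta)
        if any(v < 0 for v in vals):
            raise ValueError(f"loss weights must be non-negative, got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"loss weights must sum to 1, got {sum(vals)!r}")


@dataclass
class CorrespondenceBatch:
    """Aligned per-pair features and labels for one training batch."""

    video: object                      # (N, D) pooled or (N, D, H', W') spatial
    audio: object                      # (N, D)
    labels: np.ndarray                 # (N,) in {0, 1}
    text: object = None                # (N, D) gated pooled text, optional
    text_empty: np.ndarray = None      # (N,) bool, True where SIG flagged empty

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("correspondence labels must be 0 or 1")
        if self.text is not None and self.text_empty is None:
            self.text_empty = np.zeros(len(self.labels), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class SimilarityMatrix:
    """values[j, i] = exp(score(V_j, A_i) / tau), strictly positive."""

    values: object  # (N, N) Tensor
    tau: float = DEFAULT_TAU


# ---------------------------------------------------------------------------
# fusion heads
# ---------------------------------------------------------------------------


class ConcatFusionHead(nn.Module):
    """[v; a] -> FC -> ReLU -> FC -> sigmoid probability."""

    def __init__(self, embed_dim: int, hidden: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(2 * embed_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def forward(self, v, a):
        v, a = nn.astensor(v), nn.astensor(a)
        if v.shape[-1] != a.shape[-1]:
            raise ValueError(f"embedding dims differ: {v.shape} vs {a.shape}")
        x = nn.concat([v, a], axis=-1)
        return self.fc2(self.fc1(x).relu()).sigmoid().reshape(-1)


class SpatialFusionHead(nn.Module):
    """Response map fusion: r[h,w] = <v_map[:,h,w], a>; the map is globally
    average-pooled (both directly and as an attention weight over the visual
    cells) and a fully-connected layer turns the aggregate into the
    correspondence probability."""

    def __init__(self, embed_dim: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc = nn.Linear(embed_dim + 1, 1, rng)

    def response_map(self, v_map, a):
        v_map, a = nn.astensor(v_map), nn.astensor(a)
        b, d = a.shape
        if v_map.shape[1] != d:
            raise ValueError(
                f"embedding dims differ: map {v_map.shape} vs audio {a.shape}"
            )
        return (v_map * a.reshape(b, d, 1, 1)).sum(axis=1)  # (B, H', W')

    def forward(self, v_map, a):
        r = self.response_map(v_map, a)
        b = r.shape[0]
        # normalise the aggregated features to cosine scale so the sigmoid
        # head sees O(1) inputs regardless of feature magnitudes
        v_bar = v_map.mean(axis=(2, 3))              # (B, D)
        norms = (
            ((v_bar * v_bar).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
            * ((a * a).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
            + 1e-8
        )
        weighted = v_map * r.reshape(b, 1, r.shape[1], r.shape[2])
        pooled = weighted.mean(axis=(2, 3)) / norms  # (B, D)
        r_mean = r.mean(axis=(1, 2)).reshape(b, 1) / norms
        p = self.fc(nn.concat([pooled, r_mean], axis=1)).sigmoid().reshape(-1)
        return r, p


def fuse_concat(head: ConcatFusionHead, v, a):
    return head(v, a)


def fuse_spatial(head: SpatialFusionHead, v_map, a):
    return head(v_map, a)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def loss_base(p, c) -> nn.Tensor:
    """Mean binary cross-entropy between probabilities and 0/1 labels."""
    p = nn.astensor(p)
    c = np.asarray(c, dtype=p.data.dtype)
    if p.shape != c.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs c {c.shape}")
    if np.any(p.data <= -_EPS) or np.any(p.data >= 1 + _EPS):
        raise ValueError("probabilities outside [0, 1]")
    p = p.clip(_EPS, 1.0 - _EPS)
    ll = nn.Tensor(c) * p.log() + nn.Tensor(1.0 - c) * (1.0 - p).log()
    return -ll.mean()


def similarity_matrix(v, a, tau: float = DEFAULT_TAU) -> SimilarityMatrix:
    """Exponentiated cosine similarities: values[j, i] = exp(cos(V_j, A_i)/tau)."""
    v, a = nn.astensor(v), nn.astensor(a)
    vn = v / ((v * v).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    an = a / ((a * a).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    scores = vn @ an.transpose(1, 0)
    return SimilarityMatrix((scores * (1.0 / tau)).exp(), tau)


def loss_contrastive(S: SimilarityMatrix, mode: str = "infonce",
                     per_anchor: bool = False):
    """Cross-modal contrastive loss over an N x N similarity matrix.

    Per anchor i: ``-log(S[i,i] / sum_j S[j,i])`` ("infonce", bounded below
    by 0) or ``-log(S[i,i] / sum_{j != i} S[j,i])`` ("literal").  Returns the
    mean over anchors, or the per-anchor vector when requested.
    """
    vals = nn.astensor(S.values if isinstance(S, SimilarityMatrix) else S)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 pairs in the batch")
    idx = np.arange(n)
    diag = vals[idx, idx]
    col_sums = vals.sum(axis=0)
    if mode == "infonce":
        denom = col_sums
    elif mode == "literal":
        denom = col_sums - diag
    else:
        raise ValueError(f"unknown contrastive mode {mode!r}")
    per = -(diag / denom).log()
    return per if per_anchor else per.mean()


def spatial_objective(head: SpatialFusionHead, v_maps, a, c,
                      tau: float = DEFAULT_TAU, mode: str = "infonce") -> nn.Tensor:
    """L_base + L_contra on spatial video features.

    The correspondence term scores the fused probability from the spatial
    head against the labels; the contrastive term uses the pooled response
    (mean of the response map between every V_j and A_i) as the raw
    similarity score.
    """
    v_maps, a = nn.astensor(v_maps), nn.astensor(a)
    _, p = head(v_maps, a)
    base = loss_base(p, c)
    pooled_maps = v_maps.mean(axis=(2, 3))            # (N, D)
    raw = pooled_maps @ a.transpose(1, 0)             # raw[j, i] = <mean map_j, a_i>
    contra = loss_contrastive(SimilarityMatrix((raw * (1.0 / tau)).exp(), tau), mode)
    return base + contra


def _masked_mean(per: nn.Tensor, keep: np.ndarray) -> nn.Tensor:
    """Mean of per-element losses over kept entries (0 if none kept)."""
    k = np.asarray(keep, dtype=per.data.dtype)
    n_keep = k.sum()
    if n_keep == 0:
        return nn.Tensor(np.asarray(0.0, dtype=per.data.dtype))
    return (per * nn.Tensor(k)).sum() / float(n_keep)


def _cell_cosine_scores(v_maps, other, beta: float = 5.0) -> nn.Tensor:
    """Pairwise spatial similarity by soft-max over cells.

    score[j, i] = smooth-max over cells of cos(map_j[cell], other_i): an
    attention-like aggregation that rewards a peaked response somewhere in
    the map rather than a diffuse average.
    """
    n, d, h, w = v_maps.shape
    cells = v_maps.reshape(n, d, h * w).transpose(0, 2, 1)        # (N, P, D)
    cn = cells / ((cells * cells).sum(axis=2, keepdims=True) + 1e-12) ** 0.5
    on = other / ((other * other).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    r = cn.reshape(n * h * w, d) @ on.transpose(1, 0)             # (N*P, M)
    r = r.reshape(n, h * w, other.shape[0])                       # (N, P, M)
    m = r.max(axis=1, keepdims=True)
    lse = m + (((r - m) * beta).exp().mean(axis=1, keepdims=True)).log() * (1.0 / beta)
    return lse.reshape(n, other.shape[0])


def joint_loss(batch: CorrespondenceBatch, weights: ObjectiveWeights,
               va_head, vt_head=None, tau: float = DEFAULT_TAU,
               mode: str = "infonce", spatial_pool: str = "mean") -> nn.Tensor:
    """Four-term joint objective over a correspondence batch.

    Contrastive terms use only the matched (c = 1) pairs as anchors; text
    terms additionally exclude pairs whose gated text feature is empty,
    renormalising over the remainder (weights stay as given; an absent term
    contributes 0).
    """
    spatial = nn.astensor(batch.video).ndim == 4
    v = nn.astensor(batch.video)
    a = nn.astensor(batch.audio)
    c = batch.labels

    def base_term(head, other):
        if spatial:
            _, p = head(v, other)
        else:
            p = head(v, other)
        return p

    total = nn.Tensor(np.asarray(0.0, dtype=np.float32))
    pos = c == 1

    if weights.alpha > 0:
        total = total + weights.alpha * loss_base(base_term(va_head, a), c)
    if weights.gamma > 0 and pos.sum() >= 2:
        # spatial features enter the contrastive term through their pooled
        # map; scores are cosines so the exponentials stay bounded
        if spatial and spatial_pool == "softmax":
            raw = _cell_cosine_scores(v[pos], a[pos])
            S = SimilarityMatrix((raw * (1.0 / tau)).exp(), tau)
        else:
            v_pos = v[pos] if not spatial else v[pos].mean(axis=(2, 3))
            S = similarity_matrix(v_pos, a[pos], tau)
        total = total + weights.gamma * loss_contrastive(S, mode)

    if batch.text is not None and (weights.beta > 0 or weights.delta > 0):
        if vt_head is None:
            raise ValueError("text terms requested but no video-text head given")
        t = nn.astensor(batch.text)
        keep = ~np.asarray(batch.text_empty)
        if weights.beta > 0 and keep.any():
            p_t = base_term(vt_head, t)
            pt = p_t.clip(_EPS, 1.0 - _EPS)
            cd = c.astype(pt.data.dtype)
            per = -(nn.Tensor(cd) * pt.log() + nn.Tensor(1.0 - cd) * (1.0 - pt).log())
            total = total + weights.beta * _masked_mean(per, keep)
        keep_pos = keep & pos
        if weights.delta > 0 and keep_pos.sum() >= 2:
            if spatial and spatial_pool == "softmax":
                raw = _cell_cosine_scores(v[keep_pos], t[keep_pos])
                S = SimilarityMatrix((raw * (1.0 / tau)).exp(), tau)
            else:
                v_kp = v[keep_pos] if not spatial else v[keep_pos].mean(axis=(2, 3))
                S = similarity_matrix(v_kp, t[keep_pos], tau)
            total = total + weights.delta * loss_contrastive(S, mode)
    return total
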