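"""Selective information gating (SIG) over transcribed text.

Transcripts carry two kinds of junk: corrupted out-of-vocabulary tokens
(ASR errors, flagged as <unk>) and fluent but off-topic speech ("how are
you?").  SIG learns a non-negative per-token gate and pools the projected
token embeddings under it.  Two variants:

* outlier filtering — gates are learned freely but forced to exactly 0 at
  <unk> positions, so corrupted tokens cannot influence the pooled feature;
* keyword spotting — additionally multiplies the gate of every token absent
  from an anatomy keyword dictionary by a depression factor ``lam`` in
  [0, 1) (default 0, i.e. hard selection); at ``lam = 1`` it coincides with
  outlier filtering.

The gate network is per-token (a 1x1 convolution along the token axis
followed by a fully-connected layer, softplus output), so gates at one
position never depend on embeddings at another: the pooled output is an
exact constant function of whatever sits at <unk> positions, and permuting
tokens permutes gates with them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encoders import TextEmbeddingSequence, TextEmbedder

__all__ = [
    "KeywordDictionary",
    "GatedTextFeature",
    "SIGModule",
    "sig_filter_outliers",
    "sig_keyword_spot",
]


@dataclass(frozen=True)
class KeywordDictionary:
    """Set of lowercase anatomy terms."""

    terms: frozenset

    def __post_init__(self):
        terms = frozenset(t.lower() for t in self.terms)
        if not terms:
            raise ValueError("keyword dictionary is empty")
        object.__setattr__(self, "terms", terms)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.terms


@dataclass
class GatedTextFeature:
    """Gated pooled text embedding.

    ``empty`` is raised when every gate is zero (all tokens <unk>, or all
    off-dictionary under hard keyword spotting); callers must exclude such
    features from text loss terms.
    """

    vector: object          # (D,) Tensor; zeros when empty
    gate_weights: np.ndarray
    empty: bool = False


class SIGModule(nn.Module):
    def __init__(self, embed_dim: int, hidden: int = 32, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        # 1x1 conv along the token axis == shared per-token linear map
        self.conv1x1 = nn.Linear(embed_dim, hidden, rng)
        self.fc = nn.Linear(hidden, 1, rng)

    def _raw_gates(self, projected: nn.Tensor) -> nn.Tensor:
        """(L, D) -> (L,) non-negative gate weights."""
        h = self.conv1x1(projected).relu()
        return self.fc(h).softplus().reshape(-1)

    def forward(
        self,
        projected: nn.Tensor,
        seq: TextEmbeddingSequence,
        dictionary: KeywordDictionary | None = None,
        lam: float = 0.0,
    ) -> GatedTextFeature:
        """Gate and pool.  With a dictionary this is keyword spotting, the
        depression factor ``lam`` scaling off-dictionary gates; without one
        it is plain outlier filtering."""
        gates = self._raw_gates(projected)
        keep = (~seq.unk_mask).astype(projected.data.dtype)
        if dictionary is not None:
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"depression factor must be in [0, 1], got {lam}")
            in_dict = np.array([t in dictionary for t in seq.tokens])
            keep = keep * np.where(in_dict, 1.0, lam).astype(keep.dtype)
        gates = gates * nn.Tensor(keep)
        total = gates.sum()
        if total.item() == 0.0:
            d = projected.shape[1]
            return GatedTextFeature(
                vector=nn.Tensor(np.zeros(d, dtype=projected.data.dtype)),
                gate_weights=gates.data.copy(),
                empty=True,
            )
        pooled = (projected * gates.reshape(-1, 1)).sum(axis=0) / total
        return GatedTextFeature(pooled, gates.data.copy(), empty=False)


def sig_filter_outliers(sig: SIGModule, embedder: TextEmbedder,
                        seq: TextEmbeddingSequence) -> GatedTextFeature:
    """Outlier-filtering SIG: <unk> tokens are exactly removed."""
    return sig(embedder.project(seq), seq)


def sig_keyword_spot(sig: SIGModule, embedder: TextEmbedder,
                     seq: TextEmbeddingSequence, dictionary: KeywordDictionary,
                     lam: float = 0.0) -> GatedTextFeature:
    """Keyword-spotting SIG: off-dictionary gates scaled by ``lam``."""
    return sig(embedder.project(seq), seq, dictionary=dictionary, lam=lam)
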