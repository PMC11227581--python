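"""Evaluation suite: classification metrics, the five standard saliency
metrics (KL, NSS, AUC, CC, SIM), and the saliency-compactness score Comp.

Comp targets a property the standard saliency metrics miss in medical
imaging: clinically useful attention maps are small and sharply peaked on
one anatomical structure.  With ``alpha_S`` the support-area fraction of
the prediction, ``alpha_H`` the area fraction above a confidence threshold,
``eta_H = alpha_H / alpha_S`` the high-response intensity, and IoU the
support overlap with the reference map,

    Comp = IoU * eta_H / alpha_S,

so compact, confident, correctly-placed maps score high.  Areas are
reported as fractions of total pixels by default, which makes Comp
invariant to image resolution; ``raw_counts=True`` gives literal pixel
counts instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_auc_score,
)

__all__ = [
    "SaliencyEvalResult",
    "CompResult",
    "classification_report",
    "saliency_metrics",
    "comp_metric",
    "KL_EPS",
]

KL_EPS = 1e-8


def _values(m) -> np.ndarray:
    return np.asarray(getattr(m, "values", m), dtype=np.float64)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classification_report(pred, true, n_classes: int) -> dict:
    """Per-class precision/recall/F1 + macro averages + confusion matrix.

    Macro averages are unweighted means over classes with support > 0.
    Confusion matrix rows are true classes, columns predictions.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size and (
        pred.min() < 0 or pred.max() >= n_classes or true.min() < 0 or true.max() >= n_classes
    ):
        raise ValueError(f"labels outside [0, {n_classes - 1}]")
    labels = np.arange(n_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        true, pred, labels=labels, zero_division=0
    )
    supported = support > 0
    cm = _sk_confusion(true, pred, labels=labels)
    return {
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "support": support,
        "macro_precision": float(prec[supported].mean()) if supported.any() else 0.0,
        "macro_recall": float(rec[supported].mean()) if supported.any() else 0.0,
        "macro_f1": float(f1[supported].mean()) if supported.any() else 0.0,
        "confusion_matrix": cm,
        "accuracy": float((pred == true).mean()) if pred.size else 0.0,
    }


# ---------------------------------------------------------------------------
# saliency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaliencyEvalResult:
    KL: float
    NSS: float
    AUC: float
    CC: float
    SIM: float


def _check_normalized(m: np.ndarray, name: str):
    if m.min() < -1e-9:
        raise ValueError(f"{name} map has negative values")
    if abs(m.sum() - 1.0) > 1e-3:
        raise ValueError(f"{name} map is not normalised (sum {m.sum():.6f})")


def saliency_metrics(pred, gt, fixations) -> SaliencyEvalResult:
    """The five standard saliency scores of ``pred`` against ``gt``.

    ``pred`` and ``gt`` are normalised distributions over pixels;
    ``fixations`` is a non-empty list of (row, col) gaze points used by NSS
    and AUC.  Degenerate constant predictions score NSS = 0 and AUC = 0.5.
    """
    p, g = _values(pred), _values(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    _check_normalized(p, "pred")
    _check_normalized(g, "gt")
    fixations = list(fixations)
    if not fixations:
        raise ValueError("NSS/AUC need a non-empty fixation list")

    nz = g > 0
    kl = float(np.sum(g[nz] * np.log((g[nz] + KL_EPS) / (p[nz] + KL_EPS))))

    sp, sg = p.std(), g.std()
    cc = 0.0 if sp == 0 or sg == 0 else float(
        np.corrcoef(p.ravel(), g.ravel())[0, 1]
    )

    sim = float(np.minimum(p, g).sum())

    rows, cols = np.array(fixations).T
    if sp == 0:
        nss = 0.0
    else:
        z = (p - p.mean()) / sp
        nss = float(z[rows, cols].mean())

    fix_mask = np.zeros(p.shape, dtype=bool)
    fix_mask[rows, cols] = True
    auc = float(roc_auc_score(fix_mask.ravel(), p.ravel()))

    return SaliencyEvalResult(KL=kl, NSS=nss, AUC=auc, CC=cc, SIM=sim)


# ---------------------------------------------------------------------------
# compactness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompResult:
    alpha_S: float    # support-area of the prediction
    alpha_H: float    # area above threshold
    eta_H: float      # alpha_H / alpha_S
    iou: float        # support IoU against the reference
    thres: float
    comp: float
    valid: bool = True


def comp_metric(pred, ref, thres: float = 0.5, raw_counts: bool = False,
                iou_at_thres: bool = False) -> CompResult:
    """Saliency compactness of ``pred`` against reference map/mask ``ref``.

    ``pred`` must be min-max normalised to [0, 1].  Supports are pixels
    with value > 0 (``iou_at_thres=True`` binarises both maps at ``thres``
    for the IoU instead).  An all-zero prediction has no support and yields
    a flagged-invalid result (``valid=False``, comp = nan).
    """
    p, r = _values(pred), _values(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred must be min-max normalised to [0, 1]")
    total = p.size
    scale = 1.0 if raw_counts else float(total)
    n_support = int((p > 0).sum())
    if n_support == 0:
        return CompResult(0.0, 0.0, 0.0, 0.0, thres, float("nan"), valid=False)
    alpha_s = n_support / scale
    alpha_h = int((p > thres).sum()) / scale
    eta = alpha_h / alpha_s
    if iou_at_thres:
        ps, rs = p > thres, r > thres
    else:
        ps, rs = p > 0, r > 0
    union = int((ps | rs).sum())
    iou = int((ps & rs).sum()) / union if union else 0.0
    return CompResult(
        alpha_S=alpha_s,
        alpha_H=alpha_h,
        eta_H=eta,
        iou=iou,
        thres=thres,
        comp=iou * eta / alpha_s,
    )
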