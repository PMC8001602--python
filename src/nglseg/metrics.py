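"""Pixel-level detection metrics: error matrix, accuracy, Cohen's kappa,
ROC/AUC, and tri-color result maps.

The error matrix follows the convention rows = detection, columns = truth:
Pa = detected & true (TP), Pb = detected & not true (FP),
Pc = missed & true (FN), Pd = correctly rejected (TN).
Kappa is the chance-corrected agreement K = (Po - Pe) / (1 - Pe) with
observed agreement Po = (Pa + Pd)/N and chance agreement
Pe = (Pa+Pb)(Pa+Pc)/N^2 + (Pc+Pd)(Pb+Pd)/N^2.  K = 1 for a perfect map and
K = 0 for a constant (all-target or all-background) map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ErrorMatrix:
    Pa: int  # TP
    Pb: int  # FP
    Pc: int  # FN
    Pd: int  # TN

    def __post_init__(self) -> None:
        if min(self.Pa, self.Pb, self.Pc, self.Pd) < 0:
            raise ValueError("error-matrix counts must be non-negative")

    @property
    def N(self) -> int:
        return self.Pa + self.Pb + self.Pc + self.Pd

    @property
    def tpr(self) -> float:
        pos = self.Pa + self.Pc
        return self.Pa / pos if pos else float("nan")

    @property
    def fpr(self) -> float:
        neg = self.Pb + self.Pd
        return self.Pb / neg if neg else float("nan")


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class EvaluationReport:
    auc: float
    tpr: float
    fpr: float
    acc: float
    kappa: float


def _check_binary_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs truth {truth.shape}")
    for name, a in (("prediction", pred), ("truth", truth)):
        u = np.unique(a)
        if not np.isin(u, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary 0/1, found values {u}")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred_mask, truth_mask) -> ErrorMatrix:
    pred, truth = _check_binary_pair(pred_mask, truth_mask)
    return ErrorMatrix(
        Pa=int(np.count_nonzero(pred & truth)),
        Pb=int(np.count_nonzero(pred & ~truth)),
        Pc=int(np.count_nonzero(~pred & truth)),
        Pd=int(np.count_nonzero(~pred & ~truth)),
    )


def accuracy(em: ErrorMatrix) -> float:
    if em.N == 0:
        raise ValueError("empty error matrix")
    return (em.Pa + em.Pd) / em.N


def cohens_kappa(em: ErrorMatrix) -> float:
    """Chance-corrected agreement; NaN when both marginals are degenerate
    and identical (Pe = 1), where kappa is undefined."""
    if em.N == 0:
        raise ValueError("empty error matrix")
    n = float(em.N)
    po = (em.Pa + em.Pd) / n
    pe = ((em.Pa + em.Pb) * (em.Pa + em.Pc)
          + (em.Pc + em.Pd) * (em.Pb + em.Pd)) / (n * n)
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        return float("nan")
    return (po - pe) / (1.0 - pe)


def roc_auc(scores, truth_mask) -> RocCurve:
    """Threshold-sweep ROC and trapezoidal AUC.

    Requires both classes in the truth.  Ties in the scores are handled as
    concordance with tie-correction (equivalent to the trapezoid over the
    swept curve).  Hard 0/1 score grids degenerate to a three-point curve.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth_mask).ravel()
    u = np.unique(truth)
    if not np.isin(u, (0, 1)).all():
        raise ValueError("truth mask must be binary 0/1")
    if u.size < 2:
        raise ValueError("ROC requires both classes present in the truth mask")
    fpr, tpr, thr = _skm.roc_curve(truth, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(_skm.auc(fpr, tpr)))


# tri-color convention: hits red, false alarms blue, misses yellow
_RED = (255, 0, 0)
_BLUE = (0, 0, 255)
_YELLOW = (255, 255, 0)


def render_result_map(pred_mask, truth_mask, source=None) -> np.ndarray:
    """uint8 (H, W, 3) map: TP red, FP blue, FN yellow; TN keep the
    grayscale of ``source`` (black if none)."""
    pred, truth = _check_binary_pair(pred_mask, truth_mask)
    H, W = pred.shape
    if source is not None:
        src = np.asarray(source, dtype=np.float64)
        if src.ndim == 3:
            src = src.mean(axis=2)
        if src.shape != (H, W):
            raise ValueError("source shape mismatch")
        if src.max() <= 1.0:
            src = src * 255.0
        out = np.repeat(src[:, :, None], 3, axis=2)
    else:
        out = np.zeros((H, W, 3))
    out[pred & truth] = _RED
    out[pred & ~truth] = _BLUE
    out[~pred & truth] = _YELLOW
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def evaluate(scores, truth_mask, threshold: float = 0.5) -> EvaluationReport:
    """Five-number report (AUC, TPR, FPR, ACC, kappa) at a hard threshold.

    AUC is computed from the raw scores; the other four from the
    thresholded mask.  The default threshold 0.5 is the sigmoid midpoint.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pred = (scores >= threshold).astype(np.uint8)
    em = confusion_counts(pred, truth_mask)
    roc = roc_auc(scores, truth_mask)
    return EvaluationReport(auc=roc.auc, tpr=em.tpr, fpr=em.fpr,
                            acc=accuracy(em), kappa=cohens_kappa(em))
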