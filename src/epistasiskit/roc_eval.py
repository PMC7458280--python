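"""ROC analysis: AUC with Hanley-McNeil standard error, Youden cutoff,
and hold-out confusion metrics (shared with the MDR metric code).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .genotype_io import DataError
from .mdr import ClassificationMetrics, evaluate


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpf: np.ndarray          # sensitivity, non-decreasing from 0 to 1
    fpf: np.ndarray          # 1 - specificity
    auc: float
    auc_se: float
    auc_ci_95: tuple[float, float]
    z_vs_half: float
    degenerate: bool = False

    @property
    def youden_j(self) -> float:
        return float(np.max(self.tpf - self.fpf))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley & McNeil (1982) standard error of a trapezoidal AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc(scores, truth) -> RocCurve:
    """ROC curve over all distinct score thresholds.

    AUC is the trapezoidal area, identical to the Mann-Whitney concordance
    probability with ties counted one half; its SE follows Hanley-McNeil and
    the 95% CI is AUC +/- 1.96 SE truncated to [0, 1].  Constant scores yield
    the chance diagonal (AUC = 0.5) with a degenerate flag.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if np.unique(truth).size < 2:
        raise DataError("truth must contain both classes")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    degenerate = bool(np.unique(scores).size == 1)
    if degenerate:
        fpf = np.array([0.0, 1.0])
        tpf = np.array([0.0, 1.0])
        thresholds = np.array([math.inf, scores[0]])
        auc = 0.5
    else:
        fpf, tpf, thresholds = _sk_roc_curve(truth, scores, drop_intermediate=False)
        auc = float(np.trapezoid(tpf, fpf))
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    z = (auc - 0.5) / se if se > 0 else math.inf
    return RocCurve(
        thresholds=np.asarray(thresholds), tpf=np.asarray(tpf), fpf=np.asarray(fpf),
        auc=auc, auc_se=se, auc_ci_95=ci, z_vs_half=z, degenerate=degenerate,
    )


def youden_cutoff(curve: RocCurve) -> tuple[float, float]:
    """Score threshold maximizing Youden's J = TPF - FPF.

    Ties are broken toward higher specificity (lower FPF, i.e. the higher
    threshold).  The returned cutoff is a realized score value: predictions
    are case iff score >= cutoff.
    """
    j = curve.tpf - curve.fpf
    best = np.flatnonzero(j >= j.max() - 1e-12)
    # sklearn thresholds decrease along the curve; earliest index = highest
    # threshold = fewest positives = highest specificity
    idx = int(best[0])
    return float(curve.thresholds[idx]), float(j[idx])


def apply_cutoff(scores, cutoff: float, truth) -> ClassificationMetrics:
    """Classify case iff score >= cutoff and evaluate against truth."""
    scores = np.asarray(scores, dtype=float)
    preds = (scores >= cutoff).astype(int)
    return evaluate(preds, truth)
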