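"""Multifactor Dimensionality Reduction from scratch.

MDR pools the multilocus genotype cells of a k-SNP combination into high- and
low-risk classes by comparing each cell's case:control ratio against the
overall (class-balanced) training ratio, then scores the resulting one-
dimensional classifier by balanced accuracy under stratified k-fold
cross-validation.  Combinations are ranked by mean test balanced accuracy with
cross-validation consistency (CVC — the number of folds in which the
combination had the best training balanced accuracy among its peers of the
same size) as tiebreak.  Model significance comes from a label-permutation
test on the same statistic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .genotype_io import DataError, GenotypeMatrix

logger = logging.getLogger("epistasiskit")

HIGH, LOW = "high", "low"
_FALLBACK = {"control": 0, "case": 1, "abstain": -1}


@dataclass
class MdrModel:
    combo: tuple[str, ...]
    cell_labels: dict[tuple[int, ...], str]
    threshold: float
    train_bal_acc: list[float]
    test_bal_acc: list[float]
    cvc: int = 0

    @property
    def mean_train_bal_acc(self) -> float:
        return float(np.mean(self.train_bal_acc)) if self.train_bal_acc else math.nan

    @property
    def mean_test_bal_acc(self) -> float:
        return float(np.mean(self.test_bal_acc)) if self.test_bal_acc else math.nan


@dataclass
class ClassificationMetrics:
    """Confusion-table summary: rates, kappa, F1, OR with Woolf CI, chi2."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_abstained: int = 0
    derived: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        n = tp + tn + fp + fn
        sens = tp / (tp + fn) if tp + fn else math.nan
        spec = tn / (tn + fp) if tn + fp else math.nan
        prec = tp / (tp + fp) if tp + fp else math.nan
        acc = (tp + tn) / n
        bal = (sens + spec) / 2.0
        f1 = (
            2.0 * prec * sens / (prec + sens)
            if (prec + sens) and not math.isnan(prec + sens) else math.nan
        )
        p_e = ((tp + fp) / n) * ((tp + fn) / n) + ((tn + fn) / n) * ((tn + fp) / n)
        kappa = (acc - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
        # odds ratio with Haldane correction on any zero cell, Woolf log-SE CI
        cells = np.array([tp, fp, fn, tn], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        a, b, c, d = cells
        oratio = (a * d) / (b * c)
        log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci = (
            math.exp(math.log(oratio) - 1.96 * log_se),
            math.exp(math.log(oratio) + 1.96 * log_se),
        )
        # Pearson chi-square on the 2x2 confusion table, no continuity correction
        observed = np.array([[tp, fn], [fp, tn]], dtype=float)
        if observed.sum(axis=0).all() and observed.sum(axis=1).all():
            chi2, chi2_p, _, _ = stats.chi2_contingency(observed, correction=False)
        else:
            chi2, chi2_p = 0.0, 1.0
        self.derived = {
            "sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "balanced_accuracy": bal, "f1": f1, "kappa": kappa,
            "odds_ratio": oratio, "or_ci_95": ci,
            "chi2": float(chi2), "chi2_p": float(chi2_p),
        }

    def __getattr__(self, item):
        d = object.__getattribute__(self, "__dict__").get("derived", {})
        if item in d:
            return d[item]
        raise AttributeError(item)


# ---------------------------------------------------------------------------
# Vectorised cell machinery
# ---------------------------------------------------------------------------

def _as_matrix(genotypes) -> np.ndarray:
    g = np.asarray(genotypes, dtype=int)
    if g.ndim == 1:
        g = g.reshape(-1, 1)
    return g


def _encode_cells(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-radix integer code per subject + the distinct cell tuples."""
    radix = geno.max(axis=0) + 1
    codes = np.zeros(geno.shape[0], dtype=np.int64)
    for j in range(geno.shape[1]):
        codes = codes * radix[j] + geno[:, j]
    uniq, inverse = np.unique(codes, return_inverse=True)
    # decode distinct codes back to genotype tuples for the label map
    cells = np.zeros((uniq.size, geno.shape[1]), dtype=int)
    rem = uniq.copy()
    for j in range(geno.shape[1] - 1, -1, -1):
        cells[:, j] = rem % radix[j]
        rem //= radix[j]
    return inverse, cells


def _cell_predictions(
    cell_idx: np.ndarray,
    n_cells: int,
    pheno: np.ndarray,
    train_mask: np.ndarray,
    weighting: str,
    unseen_policy: str,
) -> np.ndarray:
    """Per-cell prediction (1 high, 0 low, -1 abstain) from training counts.

    A cell is high-risk iff cases >= threshold * controls, with
    threshold = training n_cases/n_controls under balanced weighting
    (ties -> high); unseen training cells follow ``unseen_policy``.
    """
    tr_pheno = pheno[train_mask]
    n_cases = int(tr_pheno.sum())
    n_controls = tr_pheno.size - n_cases
    if n_cases == 0 or n_controls == 0:
        raise DataError("training data needs both cases and controls")
    if weighting == "balanced":
        threshold = n_cases / n_controls
    elif weighting == "none":
        threshold = 1.0
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    tr_idx = cell_idx[train_mask]
    case_counts = np.bincount(tr_idx[tr_pheno == 1], minlength=n_cells)
    ctrl_counts = np.bincount(tr_idx[tr_pheno == 0], minlength=n_cells)
    pred = (case_counts >= threshold * ctrl_counts).astype(int)
    pred[case_counts == 0] = 0  # empty-case cells are low even with 0 controls
    unseen = (case_counts + ctrl_counts) == 0
    pred[unseen] = _FALLBACK[unseen_policy]
    return pred


def _balanced_accuracy(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Mean recall over the classes present; abstentions (-1) excluded."""
    keep = predictions != -1
    predictions, truth = predictions[keep], truth[keep]
    recalls = []
    for cls in (0, 1):
        sel = truth == cls
        if sel.any():
            recalls.append(float((predictions[sel] == cls).mean()))
    return float(np.mean(recalls)) if recalls else math.nan


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def label_cells(
    genotypes,
    phenotype,
    weighting: str = "balanced",
) -> tuple[dict[tuple[int, ...], str], float]:
    """High/low-risk labels for every observed multilocus cell.

    With ``weighting="balanced"`` each control is down-weighted by
    n_cases/n_controls, so a cell is high-risk iff its case:control ratio is
    at least the overall ratio (ties -> high).  ``"none"`` compares the raw
    ratio against 1.  Returns the label map and the ratio threshold used.
    """
    geno = _as_matrix(genotypes)
    pheno = np.asarray(phenotype, dtype=int)
    cell_idx, cells = _encode_cells(geno)
    all_train = np.ones(len(pheno), dtype=bool)
    pred = _cell_predictions(cell_idx, len(cells), pheno, all_train, weighting, "control")
    observed = np.zeros(len(cells), dtype=bool)
    observed[np.unique(cell_idx)] = True
    labels = {
        tuple(cells[c]): (HIGH if pred[c] == 1 else LOW)
        for c in range(len(cells)) if observed[c]
    }
    n_cases = int(pheno.sum())
    threshold = n_cases / (len(pheno) - n_cases) if weighting == "balanced" else 1.0
    return labels, threshold


def classify(
    genotypes,
    cell_labels: dict[tuple[int, ...], str],
    unseen_policy: str = "control",
) -> np.ndarray:
    """Predict case (1) for high-risk cells, control (0) for low-risk.

    Cells unseen in training follow ``unseen_policy``: ``"control"`` (default)
    predicts 0, ``"case"`` predicts 1, ``"abstain"`` yields -1 (excluded from
    metrics downstream, count logged).
    """
    geno = _as_matrix(genotypes)
    fallback = _FALLBACK[unseen_policy]
    preds = np.empty(geno.shape[0], dtype=int)
    n_unseen = 0
    for i, row in enumerate(geno):
        lab = cell_labels.get(tuple(row))
        if lab is None:
            preds[i] = fallback
            n_unseen += 1
        else:
            preds[i] = 1 if lab == HIGH else 0
    if n_unseen:
        logger.info("classify: %d subject(s) in unseen cells (policy=%s)",
                    n_unseen, unseen_policy)
    return preds


def evaluate(predictions, truth) -> ClassificationMetrics:
    """Confusion-table metrics; abstained predictions (-1) are excluded."""
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError("length mismatch")
    mask = predictions != -1
    n_abstained = int((~mask).sum())
    if n_abstained:
        logger.info("evaluate: %d abstained prediction(s) excluded", n_abstained)
    predictions, truth = predictions[mask], truth[mask]
    if np.unique(truth).size < 2:
        raise DataError("truth must contain both classes")
    tp = int(((predictions == 1) & (truth == 1)).sum())
    fp = int(((predictions == 1) & (truth == 0)).sum())
    tn = int(((predictions == 0) & (truth == 0)).sum())
    fn = int(((predictions == 0) & (truth == 1)).sum())
    return ClassificationMetrics(tp=tp, fp=fp, tn=tn, fn=fn, n_abstained=n_abstained)


def _cv_eval(
    cell_idx: np.ndarray,
    n_cells: int,
    pheno: np.ndarray,
    fold_assignment: np.ndarray,
    weighting: str,
    unseen_policy: str,
) -> tuple[list[float], list[float]]:
    train_scores, test_scores = [], []
    for fold in np.unique(fold_assignment):
        test_mask = fold_assignment == fold
        pred = _cell_predictions(
            cell_idx, n_cells, pheno, ~test_mask, weighting, unseen_policy
        )
        train_scores.append(_balanced_accuracy(pred[cell_idx[~test_mask]], pheno[~test_mask]))
        test_scores.append(_balanced_accuracy(pred[cell_idx[test_mask]], pheno[test_mask]))
    return train_scores, test_scores


def _fold_assignment(phenotype: np.ndarray, folds: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(phenotype), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(phenotype)), phenotype)):
        assignment[test_idx] = f
    return assignment


def search(
    gm_train: GenotypeMatrix,
    max_k: int = 2,
    folds: int = 10,
    seed: int = 0,
    snps: list[str] | None = None,
    weighting: str = "balanced",
    unseen_policy: str = "control",
    force: bool = False,
) -> list[MdrModel]:
    """Exhaustive MDR combination search under stratified k-fold CV.

    Evaluates every combination of size 1..max_k; per fold the combination
    with the best training balanced accuracy (within its size class) earns a
    CVC increment.  Models are ranked by mean test balanced accuracy, CVC as
    tiebreak.  Deterministic given ``seed``.
    """
    snps = list(snps or gm_train.snp_names)
    if max_k > len(snps):
        raise ValueError("max_k exceeds number of attributes")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(snps) > 20 and max_k > 4 and not force:
        raise ValueError(
            "refusing exhaustive search over >20 attributes at k>4 (pass force=True)"
        )

    models: list[MdrModel] = []
    for k in range(1, max_k + 1):
        per_combo: list[MdrModel] = []
        fold_cache: dict[tuple[int, ...], np.ndarray] = {}
        for combo in itertools.combinations(snps, k):
            keep = gm_train.complete_cases(list(combo))
            geno = np.column_stack([gm_train.column(s)[keep] for s in combo])
            pheno = gm_train.phenotype[keep]
            key = tuple(keep.tolist())
            if key not in fold_cache:
                fold_cache[key] = _fold_assignment(pheno, folds, seed)
            cell_idx, cells = _encode_cells(geno)
            tr, te = _cv_eval(
                cell_idx, len(cells), pheno, fold_cache[key], weighting, unseen_policy
            )
            labels, threshold = label_cells(geno, pheno, weighting=weighting)
            per_combo.append(MdrModel(
                combo=combo, cell_labels=labels, threshold=threshold,
                train_bal_acc=tr, test_bal_acc=te,
            ))
        for f in range(folds):
            best = max(per_combo, key=lambda m: m.train_bal_acc[f])
            best.cvc += 1
        models.extend(per_combo)

    models.sort(key=lambda m: (-m.mean_test_bal_acc, -m.cvc, m.combo))
    return models


def permutation_test(
    gm_train: GenotypeMatrix,
    model_combo: tuple[str, ...],
    n_perm: int = 1000,
    folds: int = 10,
    seed: int = 0,
    weighting: str = "balanced",
    unseen_policy: str = "control",
) -> float:
    """Label-permutation p-value for one combination's CV balanced accuracy.

    p = (1 + #{permuted statistic >= observed}) / (1 + n_perm), the add-one
    estimator; the statistic is the mean test balanced accuracy.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    keep = gm_train.complete_cases(list(model_combo))
    geno = np.column_stack([gm_train.column(s)[keep] for s in model_combo])
    pheno = gm_train.phenotype[keep]
    cell_idx, cells = _encode_cells(geno)
    assignment = _fold_assignment(pheno, folds, seed)
    _, observed_scores = _cv_eval(
        cell_idx, len(cells), pheno, assignment, weighting, unseen_policy
    )
    observed = float(np.mean(observed_scores))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pheno)
        perm_assignment = _fold_assignment(perm, folds, int(rng.integers(2**31)))
        _, scores = _cv_eval(
            cell_idx, len(cells), perm, perm_assignment, weighting, unseen_policy
        )
        if float(np.mean(scores)) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def search_report(models: list[MdrModel]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "combo": "+".join(m.combo), "k": len(m.combo),
            "mean_train_bal_acc": m.mean_train_bal_acc,
            "mean_test_bal_acc": m.mean_test_bal_acc,
            "cvc": m.cvc,
        }
        for m in models
    ])
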