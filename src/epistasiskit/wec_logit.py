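"""Weighted-effect-coded logistic regression with genotype interaction terms.

Weighted effect coding (WEC) expresses each category effect as a deviation
from the sample-frequency-weighted mean, so with unbalanced genotype groups
the coefficients satisfy the weighted zero-sum identity sum_g n_g b_g = 0.
For a two-factor interaction the (G-1)(H-1) estimated product terms extend to
a full G x H surface b_ij obeying the double zero-sum constraints

    sum_i n_ij b_ij = 0  for every j,    sum_j n_ij b_ij = 0  for every i,

which is what makes "pure" epistatic effects interpretable in unbalanced
case-control samples: the interaction block spans exactly the surfaces that
are orthogonal (in the weighted sense) to all marginal effects, and the
fitted surface — hence the log-likelihood — does not depend on which cell is
declared the reference.

The design matrices are built here; the maximum-likelihood fit itself is
delegated to statsmodels' Logit behind :func:`fit_logistic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import DataError

SCHEMES = ("dummy", "effect", "wec", "wec_interaction_only", "additive_numeric")


@dataclass
class CodedDesign:
    """A regression design matrix with per-cell effect reconstruction metadata.

    ``X`` includes the intercept column.  ``cell_maps`` stores, per factor
    block or interaction block, the linear map from estimated coefficients to
    the full set of category (or cell) effects, so reference-category effects
    can be reconstructed and the WEC zero-sum identities audited.
    """

    X: np.ndarray
    columns: list[str]
    scheme: str
    cell_maps: dict[str, dict] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    null_log_likelihood: float
    df: int
    converged: bool = True
    separation: bool = False
    design: CodedDesign | None = None

    @property
    def lr_chi2(self) -> float:
        return 2.0 * (self.log_likelihood - self.null_log_likelihood)

    @property
    def lr_p(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.lr_chi2, self.df))

    @property
    def mcfadden_r2(self) -> float:
        return 1.0 - self.log_likelihood / self.null_log_likelihood

    def wald_ci_95(self) -> dict[str, tuple[float, float]]:
        return {
            k: (b - 1.96 * self.standard_errors[k], b + 1.96 * self.standard_errors[k])
            for k, b in self.coefficients.items()
        }

    def wald_table(self, bonferroni_family: int | None = None) -> pd.DataFrame:
        """Coefficient table: b, CI half-width, SE, Wald chi2 = z^2, p."""
        rows = []
        family = bonferroni_family or len(self.coefficients)
        for name, b in self.coefficients.items():
            se = self.standard_errors[name]
            z = b / se if se > 0 else math.inf
            p = float(2.0 * stats.norm.sf(abs(z)))
            rows.append({
                "term": name, "b": b, "ci_95_halfwidth": 1.96 * se, "se": se,
                "wald_chi2": z * z, "p": p,
                "p_bonferroni": min(1.0, p * family),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coding schemes
# ---------------------------------------------------------------------------

def _category_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cats, counts = np.unique(values, return_counts=True)
    return cats, counts


def build_wec_main(
    values,
    reference: int,
    name: str = "snp",
) -> tuple[np.ndarray, list[str], dict]:
    """WEC main-effect columns for one categorical factor.

    For each non-reference category g the column is 1 in g, -n_g/n_ref in the
    reference category and 0 elsewhere.  Returns (columns, names, cell_map)
    where cell_map carries the category -> effect reconstruction matrix and
    the counts (the reference effect is -sum_{g != ref} n_g b_g / n_ref).
    """
    values = np.asarray(values, dtype=int)
    cats, counts = _category_counts(values)
    if reference not in cats:
        raise DataError(f"reference category {reference} unobserved for {name}")
    count_of = dict(zip(cats.tolist(), counts.tolist()))
    if min(counts) == 0:
        raise DataError(f"empty category in {name}")
    free = [c for c in cats if c != reference]
    # M[h, g] = effect of category h under unit coefficient on free category g
    M = np.zeros((len(cats), len(free)))
    cat_pos = {c: i for i, c in enumerate(cats.tolist())}
    for j, g in enumerate(free):
        M[cat_pos[g], j] = 1.0
        M[cat_pos[reference], j] = -count_of[g] / count_of[reference]
    X = M[np.searchsorted(cats, values)]
    names = [f"{name}[{g}]" for g in free]
    cell_map = {
        "kind": "main", "categories": cats.tolist(), "counts": counts.tolist(),
        "reference": reference, "effect_matrix": M, "columns": names,
    }
    return X, names, cell_map


def _interaction_effect_matrix(
    counts: np.ndarray, ref_a: int, ref_b: int,
    cats_a: list[int], cats_b: list[int],
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Map from free interaction coefficients to the full G x H surface.

    Each free (a, b) pair (both non-reference) contributes a basis surface:
    1 at (a, b), 0 at the other free cells, reference row/column filled so
    every weighted row and column sum is zero.
    """
    ia = {c: i for i, c in enumerate(cats_a)}
    ib = {c: i for i, c in enumerate(cats_b)}
    free = [(a, b) for a in cats_a if a != ref_a for b in cats_b if b != ref_b]
    G, H = len(cats_a), len(cats_b)
    T = np.zeros((G, H, len(free)))
    ra, rb = ia[ref_a], ib[ref_b]
    for k, (a, b) in enumerate(free):
        surf = np.zeros((G, H))
        surf[ia[a], ib[b]] = 1.0
        for j in range(H):
            if j == rb:
                continue
            surf[ra, j] = -(counts[:, j] @ surf[:, j] - counts[ra, j] * surf[ra, j]) / counts[ra, j]
        for i in range(G):
            if i == ra:
                continue
            surf[i, rb] = -(counts[i] @ surf[i] - counts[i, rb] * surf[i, rb]) / counts[i, rb]
        surf[ra, rb] = -(counts[:, rb] @ surf[:, rb] - counts[ra, rb] * surf[ra, rb]) / counts[ra, rb]
        T[:, :, k] = surf
    return T, free


def build_wec_interaction(
    values_a,
    values_b,
    reference_a: int,
    reference_b: int,
    names: tuple[str, str] = ("A", "B"),
    interaction_only: bool = False,
) -> CodedDesign:
    """WEC design for two factors with a (G-1)(H-1) interaction block.

    Every cell of the A x B cross-table must be non-empty (empty cells are a
    hard error listing the offenders — such SNP pairs are not processed).
    With ``interaction_only`` the main-effect blocks are dropped, keeping
    intercept + interaction columns.
    """
    va = np.asarray(values_a, dtype=int)
    vb = np.asarray(values_b, dtype=int)
    cats_a = np.unique(va).tolist()
    cats_b = np.unique(vb).tolist()
    counts = np.zeros((len(cats_a), len(cats_b)))
    ia = {c: i for i, c in enumerate(cats_a)}
    ib = {c: i for i, c in enumerate(cats_b)}
    for a, b in zip(va, vb):
        counts[ia[a], ib[b]] += 1
    empty = [
        (cats_a[i], cats_b[j])
        for i in range(len(cats_a)) for j in range(len(cats_b))
        if counts[i, j] == 0
    ]
    if empty:
        raise DataError(f"empty {names[0]} x {names[1]} cells: {empty}")

    blocks = [np.ones((len(va), 1))]
    col_names = ["intercept"]
    cell_maps: dict[str, dict] = {}
    if not interaction_only:
        for vals, ref, nm in ((va, reference_a, names[0]), (vb, reference_b, names[1])):
            X, cn, cm = build_wec_main(vals, ref, name=nm)
            blocks.append(X)
            col_names.extend(cn)
            cell_maps[nm] = cm

    T, free = _interaction_effect_matrix(counts, reference_a, reference_b, cats_a, cats_b)
    Xint = np.column_stack([
        T[[ia[a] for a in va], [ib[b] for b in vb], k] for k in range(len(free))
    ])
    int_names = [f"{names[0]}[{a}]x{names[1]}[{b}]" for a, b in free]
    blocks.append(Xint)
    col_names.extend(int_names)
    cell_maps["interaction"] = {
        "kind": "interaction", "categories_a": cats_a, "categories_b": cats_b,
        "counts": counts, "reference": (reference_a, reference_b),
        "effect_tensor": T, "free_cells": free, "columns": int_names,
    }
    scheme = "wec_interaction_only" if interaction_only else "wec"
    return CodedDesign(
        X=np.column_stack(blocks), columns=col_names, scheme=scheme,
        cell_maps=cell_maps,
    )


def build_design(
    factors: dict[str, np.ndarray],
    scheme: str = "dummy",
    references: dict[str, int] | None = None,
) -> CodedDesign:
    """Intercept + per-factor blocks under dummy, unweighted-effect, WEC or
    additive-numeric (0/1/2 score) coding; no interaction terms."""
    if scheme not in ("dummy", "effect", "wec", "additive_numeric"):
        raise ValueError(f"unknown scheme {scheme!r}")
    references = references or {}
    n = len(next(iter(factors.values())))
    blocks = [np.ones((n, 1))]
    col_names = ["intercept"]
    cell_maps: dict[str, dict] = {}
    for name, vals in factors.items():
        vals = np.asarray(vals, dtype=int)
        cats, counts = _category_counts(vals)
        ref = references.get(name, cats[-1])
        if scheme == "additive_numeric":
            blocks.append(vals.reshape(-1, 1).astype(float))
            col_names.append(f"{name}[score]")
            continue
        if scheme == "wec":
            X, cn, cm = build_wec_main(vals, ref, name=name)
            cell_maps[name] = cm
        else:
            free = [c for c in cats if c != ref]
            X = np.zeros((n, len(free)))
            for j, g in enumerate(free):
                X[vals == g, j] = 1.0
                if scheme == "effect":
                    X[vals == ref, j] = -1.0
            cn = [f"{name}[{g}]" for g in free]
        blocks.append(X)
        col_names.extend(cn)
    return CodedDesign(
        X=np.column_stack(blocks), columns=col_names, scheme=scheme,
        cell_maps=cell_maps,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    deficient = [columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if deficient:
        raise DataError(f"design is rank deficient; collinear columns: {deficient}")


def null_log_likelihood(outcome: np.ndarray) -> float:
    """Closed-form intercept-only Bernoulli log-likelihood."""
    y = np.asarray(outcome, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    p = n1 / y.size
    return float(n1 * math.log(p) + n0 * math.log(1.0 - p))


def fit_logistic(design: CodedDesign, outcome) -> LogisticFit:
    """Maximum-likelihood logistic fit (statsmodels Logit behind the scenes).

    Convergence contract: Newton iterations until the gradient max-norm falls
    below 1e-8 or 100 iterations (then flagged non-converged); standard errors
    from the inverse observed information; coefficients diverging beyond |b| >
    15 are flagged as (quasi-)separation.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=int)
    if np.unique(y).size < 2:
        raise DataError("outcome must contain both classes")
    X = design.X
    _check_full_rank(X, design.columns)
    model = sm.Logit(y, X)
    with np.errstate(all="ignore"):
        res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
    grad = model.score(res.params)
    converged = bool(res.mle_retvals.get("converged", True)) and (
        float(np.abs(grad).max()) < 1e-8
    )
    separation = bool(np.any(np.abs(res.params) > 15))
    coeffs = dict(zip(design.columns, res.params.tolist()))
    ses = dict(zip(design.columns, res.bse.tolist()))
    return LogisticFit(
        coefficients=coeffs, standard_errors=ses,
        log_likelihood=float(res.llf),
        null_log_likelihood=null_log_likelihood(y),
        df=X.shape[1] - 1, converged=converged, separation=separation,
        design=design,
    )


# ---------------------------------------------------------------------------
# Effect reconstruction & model comparison
# ---------------------------------------------------------------------------

def reconstruct_main_effects(fit: LogisticFit, factor: str) -> dict[int, float]:
    """Full per-category effects of a WEC factor, reference included."""
    cm = fit.design.cell_maps[factor]
    beta = np.array([fit.coefficients[c] for c in cm["columns"]])
    effects = cm["effect_matrix"] @ beta  # includes the reference row
    return {c: float(effects[i]) for i, c in enumerate(cm["categories"])}


def reconstruct_interaction_surface(fit: LogisticFit) -> pd.DataFrame:
    """Full G x H interaction-effect surface from the fitted coefficients."""
    cm = fit.design.cell_maps["interaction"]
    beta = np.array([fit.coefficients[c] for c in cm["columns"]])
    surface = cm["effect_tensor"] @ beta
    return pd.DataFrame(
        surface, index=cm["categories_a"], columns=cm["categories_b"]
    )


def predict_pair_proba(fit: LogisticFit, values_a, values_b) -> np.ndarray:
    """Fitted case probabilities for (possibly new) subjects of a pair model.

    Scores through the reconstructed per-cell effects (intercept + main
    effects + interaction surface), so held-out subjects are scored with the
    training-data coding weights.  Raises KeyError for a genotype category
    unobserved in training.
    """
    cm = fit.design.cell_maps
    va = np.asarray(values_a, dtype=int)
    vb = np.asarray(values_b, dtype=int)
    eta = np.full(len(va), fit.coefficients["intercept"])
    main_names = [k for k in cm if k != "interaction"]
    if main_names:
        name_a, name_b = main_names
        eff_a = reconstruct_main_effects(fit, name_a)
        eff_b = reconstruct_main_effects(fit, name_b)
        eta += np.array([eff_a[g] for g in va])
        eta += np.array([eff_b[g] for g in vb])
    surface = reconstruct_interaction_surface(fit)
    eta += np.array([surface.loc[a, b] for a, b in zip(va, vb)])
    return 1.0 / (1.0 + np.exp(-eta))


def _is_nested(sub: CodedDesign, full: CodedDesign, tol: float = 1e-8) -> bool:
    """Numerically: is col-space(sub.X) contained in col-space(full.X)?"""
    Q, _ = np.linalg.qr(full.X)
    resid = sub.X - Q @ (Q.T @ sub.X)
    return bool(np.abs(resid).max() < tol * max(1.0, np.abs(sub.X).max()))


def lr_test(fit_sub: LogisticFit, fit_full: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits; errors on non-nested designs."""
    if not _is_nested(fit_sub.design, fit_full.design):
        raise DataError(
            "models are not nested; compare by AIC instead "
            f"(AIC sub={2 * (fit_sub.df + 1) - 2 * fit_sub.log_likelihood:.3f}, "
            f"full={2 * (fit_full.df + 1) - 2 * fit_full.log_likelihood:.3f})"
        )
    chi2 = 2.0 * (fit_full.log_likelihood - fit_sub.log_likelihood)
    df = fit_full.df - fit_sub.df
    p = float(stats.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
    return max(chi2, 0.0), df, p


def compare_models(fits: dict[str, LogisticFit]) -> pd.DataFrame:
    """Per-model LL, df, LR chi2 vs null, p and McFadden R^2, plus pairwise
    LR tests for nested pairs (non-nested pairs are skipped)."""
    rows = []
    for name, fit in fits.items():
        rows.append({
            "model": name, "log_likelihood": fit.log_likelihood,
            "df": fit.df, "lr_chi2": fit.lr_chi2, "lr_p": fit.lr_p,
            "mcfadden_r2": fit.mcfadden_r2,
        })
    table = pd.DataFrame(rows)
    pairwise = []
    names = list(fits)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            lo, hi = (a, b) if fits[a].df <= fits[b].df else (b, a)
            try:
                chi2, df, p = lr_test(fits[lo], fits[hi])
            except DataError:
                continue
            pairwise.append({"sub": lo, "full": hi, "lr_chi2": chi2, "df": df, "p": p})
    table.attrs["pairwise"] = pd.DataFrame(pairwise)
    return table
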