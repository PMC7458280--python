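"""Inheritance-model selection from genotype odds ratios.

From a 2x3 case-control table the per-genotype odds odd_g = cases_g/controls_g
give OR1 = odd_Mm/odd_MM (heterozygote vs major homozygote) and
OR2 = odd_mm/odd_Mm (minor homozygote vs heterozygote).  Each classical
inheritance model imposes a constraint on the pair (OR1, OR_mm) where
OR_mm = OR1*OR2:

    dominant        OR_mm = OR1        (OR2 = 1)
    recessive       OR1   = 1
    over-dominant   OR_mm = 1
    multiplicative  OR_mm = OR1^2
    additive        OR_mm = 2*OR1 - 1

The selected model minimises the squared deviation of its constraint on the
log-odds-ratio scale; all residuals are exposed so near-ties can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .qc import ContingencyTable

MODELS = ("dominant", "recessive", "additive", "multiplicative", "over-dominant")

# collapsed genotype coding per model, applied to 0/1/2 minor-allele counts
_RECODE = {
    "dominant": {0: 0, 1: 1, 2: 1},        # MM vs {Mm, mm}
    "recessive": {0: 0, 1: 0, 2: 1},       # {MM, Mm} vs mm
    "over-dominant": {0: 0, 1: 1, 2: 0},   # Mm vs {MM, mm}
    "additive": {0: 0, 1: 1, 2: 2},
    "multiplicative": {0: 0, 1: 1, 2: 2},
}


@dataclass
class ModelAssignment:
    snp: str
    or1: float
    or2: float
    model: str
    fit_residuals: dict[str, float] = field(default_factory=dict)
    excluded: tuple[str, ...] = ()
    zero_cell: bool = False


def odds_ratios(table: ContingencyTable) -> tuple[float, float, bool]:
    """(OR1, OR2, zero_cell_corrected) from a 2x3 case-control table.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all six
    cells, flagged in the third return value.
    """
    counts = table.counts.astype(float)
    if counts.shape[1] != 3:
        raise ValueError("odds_ratios requires a 2x3 table")
    corrected = bool((counts == 0).any())
    if corrected:
        counts = counts + 0.5
    odds = counts[1] / counts[0]
    or1 = odds[1] / odds[0]
    or2 = odds[2] / odds[1]
    return float(or1), float(or2), corrected


def model_residuals(or1: float, or2: float) -> tuple[dict[str, float], tuple[str, ...]]:
    """Per-model squared log-scale constraint deviations and exclusions."""
    if not (or1 > 0 and or2 > 0 and math.isfinite(or1) and math.isfinite(or2)):
        raise ValueError("OR1 and OR2 must be finite and positive")
    or_mm = or1 * or2
    residuals = {
        "dominant": math.log(or2) ** 2,
        "recessive": math.log(or1) ** 2,
        "over-dominant": math.log(or_mm) ** 2,
        "multiplicative": (math.log(or_mm) - 2.0 * math.log(or1)) ** 2,
    }
    excluded: tuple[str, ...] = ()
    additive_pred = 2.0 * or1 - 1.0
    if additive_pred > 0:
        residuals["additive"] = (math.log(or_mm) - math.log(additive_pred)) ** 2
    else:
        excluded = ("additive",)
    return residuals, excluded


def select_model(or1: float, or2: float, snp: str = "") -> ModelAssignment:
    """Pick the inheritance model whose constraint best matches (OR1, OR2)."""
    residuals, excluded = model_residuals(or1, or2)
    best = min(residuals, key=residuals.get)
    return ModelAssignment(
        snp=snp, or1=or1, or2=or2, model=best,
        fit_residuals=residuals, excluded=excluded,
    )


def assign_model(table: ContingencyTable, snp: str = "") -> ModelAssignment:
    """odds_ratios + select_model on one SNP's contingency table."""
    or1, or2, corrected = odds_ratios(table)
    assignment = select_model(or1, or2, snp=snp)
    assignment.zero_cell = corrected
    return assignment


def recode(gm: GenotypeMatrix, snp: str, model: str) -> np.ndarray:
    """Recode a SNP column under an inheritance model (missing passes through).

    dominant -> {MM} vs {Mm,mm}; recessive -> {MM,Mm} vs {mm}; over-dominant
    -> {Mm} vs {MM,mm}; additive/multiplicative keep the 3 ordered categories.
    """
    if model not in _RECODE:
        raise ValueError(f"unknown model {model!r}")
    mapping = _RECODE[model]
    col = gm.column(snp)
    out = np.full_like(col, MISSING)
    for g, v in mapping.items():
        out[col == g] = v
    return out


def model_report(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP OR1/OR2, chosen model and residuals (TSV-ready)."""
    from .qc import genotype_counts

    rows = []
    for snp in gm.snp_names:
        a = assign_model(genotype_counts(gm, snp), snp=snp)
        row = {
            "snp": snp, "OR1": a.or1, "OR2": a.or2, "model": a.model,
            "zero_cell": a.zero_cell,
        }
        row.update({f"resid_{m}": a.fit_residuals.get(m, float("nan")) for m in MODELS})
        rows.append(row)
    return pd.DataFrame(rows)
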