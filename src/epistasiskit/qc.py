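"""Per-SNP quality control: genotype counts, MAF, Hardy-Weinberg equilibrium.

HWE is tested with the plain one-degree-of-freedom chi-square against the
expected proportions (p^2, 2pq, q^2); a locus passes at the alpha = 0.01
criterion chi2 <= 6.635.  By default the test pools cases and controls; the
conventional control-only alternative is available through ``group``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, DataError, GenotypeMatrix

HWE_CHI2_THRESHOLD = 6.635  # chi2(0.99, df=1)


@dataclass
class ContingencyTable:
    """Case/control x genotype-category counts.

    ``counts`` has shape (2, G) with row 0 = controls, row 1 = cases;
    G is 3 for raw 0/1/2 genotypes or 2 for a collapsed model coding.
    """

    counts: np.ndarray
    category_labels: tuple[str, ...] = ("0", "1", "2")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise DataError("counts must be 2 x G")
        if (self.counts < 0).any():
            raise DataError("negative counts")

    @property
    def case_row(self) -> np.ndarray:
        return self.counts[1]

    @property
    def control_row(self) -> np.ndarray:
        return self.counts[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def genotype_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class HweResult:
    chi2: float
    df: int
    threshold: float
    in_equilibrium: bool
    expected_counts: np.ndarray
    monomorphic: bool = False


def genotype_counts(gm: GenotypeMatrix, snp: str, group: str = "all") -> ContingencyTable:
    """2x3 contingency table of a SNP over {0,1,2} counts, missing excluded.

    ``group`` restricts the table to ``"case"`` or ``"control"`` subjects
    (the other row is left zero); default uses both.
    """
    col = gm.column(snp)
    ok = col != MISSING
    if group == "case":
        ok &= gm.phenotype == 1
    elif group == "control":
        ok &= gm.phenotype == 0
    elif group != "all":
        raise ValueError(f"unknown group {group!r}")
    if not ok.any():
        raise DataError(f"no non-missing genotypes for {snp} in group {group!r}")
    counts = np.zeros((2, 3), dtype=int)
    for row, pheno in ((0, 0), (1, 1)):
        sel = ok & (gm.phenotype == pheno)
        counts[row] = np.bincount(col[sel], minlength=3)[:3]
    return ContingencyTable(counts=counts)


def minor_allele_frequency(counts) -> tuple[float, bool]:
    """MAF from genotype counts (n0, n1, n2); returns (maf, flipped).

    MAF = (2*n2 + n1) / 2N on the stored derived-allele orientation; if that
    exceeds 0.5 the orientation is flipped and the flag set, so the returned
    frequency is always in [0, 0.5].
    """
    n0, n1, n2 = (int(x) for x in np.asarray(counts).reshape(3))
    n = n0 + n1 + n2
    if n == 0:
        raise DataError("empty genotype counts")
    freq = (2 * n2 + n1) / (2 * n)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


def hwe_test(counts, threshold: float = HWE_CHI2_THRESHOLD) -> HweResult:
    """Chi-square HWE test on genotype counts (n0, n1, n2), df = 1.

    Expected counts are (N p^2, 2 N p q, N q^2) at the sample allele
    frequency.  A monomorphic locus is flagged and assigned chi2 = 0.
    """
    n0, n1, n2 = (int(x) for x in np.asarray(counts).reshape(3))
    n = n0 + n1 + n2
    if n < 1:
        raise DataError("empty genotype counts")
    q = (2 * n2 + n1) / (2 * n)  # derived-allele frequency
    p = 1.0 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if q in (0.0, 1.0):
        return HweResult(
            chi2=0.0, df=1, threshold=threshold, in_equilibrium=True,
            expected_counts=expected, monomorphic=True,
        )
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(
        chi2=chi2, df=1, threshold=threshold,
        in_equilibrium=chi2 <= threshold, expected_counts=expected,
    )


def qc_report(gm: GenotypeMatrix, groups: tuple[str, ...] = ("all", "case", "control")) -> pd.DataFrame:
    """One row per SNP x group: genotype counts, MAF, HWE chi2 and pass flag."""
    rows = []
    for snp in gm.snp_names:
        for group in groups:
            table = genotype_counts(gm, snp, group=group)
            n0, n1, n2 = table.genotype_totals
            maf, flipped = minor_allele_frequency((n0, n1, n2))
            hwe = hwe_test((n0, n1, n2))
            rows.append({
                "snp": snp, "group": group,
                "n0": n0, "n1": n1, "n2": n2,
                "MAF": maf, "maf_flipped": flipped,
                "HWE_chi2": hwe.chi2, "HWE_pass": hwe.in_equilibrium,
                "monomorphic": hwe.monomorphic,
            })
    return pd.DataFrame(rows)
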