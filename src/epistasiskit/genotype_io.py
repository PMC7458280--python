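"""Reading, validating and representing case-control genotype data.

The central container is :class:`GenotypeMatrix`: subjects x SNPs with a binary
phenotype (1 = case/athlete, 0 = control/sedentary) and genotypes stored as
minor/derived-allele counts in {0, 1, 2} (``-1`` marks missing).  Allele-pair
strings in input tables ("RX", "GA", ...) are mapped onto counts using per-SNP
allele labels; the 1/2/3 disfavorable/het/favorable display coding used in some
reports is a presentation mapping applied only once a model orientation is
known, never the storage encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("epistasiskit")

MISSING: int = -1


class FormatError(ValueError):
    """Malformed input file (header, encoding, column structure)."""


class DataError(ValueError):
    """Structurally valid input with inadmissible content."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs genotype matrix with a binary phenotype.

    Parameters
    ----------
    sample_ids
        Opaque unique subject identifiers, length ``n``.
    phenotype
        int array of shape ``(n,)`` with values in {0, 1}; 1 = case.
    snp_names
        Unique locus identifiers (rs numbers), length ``m``.
    genotypes
        int array of shape ``(n, m)`` holding minor-allele counts
        {0, 1, 2}, with ``-1`` for missing calls.
    allele_labels
        Optional per-SNP ``(ancestral, derived)`` symbol pair,
        e.g. ``("R", "X")`` for rs1815739.
    """

    sample_ids: list[str]
    phenotype: np.ndarray
    snp_names: list[str]
    genotypes: np.ndarray
    allele_labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        n, m = len(self.sample_ids), len(self.snp_names)
        if self.genotypes.shape != (n, m):
            raise DataError(
                f"genotypes shape {self.genotypes.shape} != (n_samples={n}, n_snps={m})"
            )
        if self.phenotype.shape != (n,):
            raise DataError("phenotype length does not match sample count")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError(f"invalid genotype values: {np.unique(self.genotypes[bad])}")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise DataError("phenotype must be binary 0/1")
        if self.n_cases == 0 or self.n_controls == 0:
            raise DataError("phenotype must contain at least one case and one control")
        if len(set(self.snp_names)) != m:
            raise DataError("snp_names are not unique")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample_ids are not unique")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_names)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def snp_index(self, snp: str) -> int:
        try:
            return self.snp_names.index(snp)
        except ValueError:
            raise KeyError(f"unknown SNP {snp!r}") from None

    def column(self, snp: str) -> np.ndarray:
        """Genotype column for one SNP (missing = -1)."""
        return self.genotypes[:, self.snp_index(snp)]

    def subset(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            phenotype=self.phenotype[idx],
            snp_names=list(self.snp_names),
            genotypes=self.genotypes[idx],
            allele_labels=dict(self.allele_labels),
        )

    def complete_cases(self, snps: list[str] | None = None) -> np.ndarray:
        """Indices of subjects with no missing genotype at the given SNPs.

        Missing-data policy is pairwise per analysis: each analysis drops only
        the subjects missing at the SNPs it actually uses.
        """
        cols = self.genotypes if snps is None else np.column_stack(
            [self.column(s) for s in snps]
        )
        keep = np.flatnonzero((cols != MISSING).all(axis=1))
        dropped = self.n_samples - keep.size
        if dropped:
            logger.info("dropped %d subject(s) with missing genotypes", dropped)
        return keep

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=self.snp_names)
        df.insert(0, "status", self.phenotype)
        df.insert(0, "sample", self.sample_ids)
        return df


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/test index sets over the samples of a GenotypeMatrix."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise DataError("train/test indices overlap")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_pair(token: str, labels: tuple[str, str]) -> int:
    """Map an allele-pair string onto a derived-allele count, -1 if unknown."""
    anc, der = labels
    count = 0
    for ch in token:
        if ch == der:
            count += 1
        elif ch != anc:
            return MISSING
    if len(token) != 2:
        return MISSING
    return count


def read_genotype_table(
    path,
    allele_labels: dict[str, tuple[str, str]] | None = None,
    sample_col: str = "sample",
    status_col: str = "status",
    sep: str = "\t",
) -> GenotypeMatrix:
    """Read a genotype TSV: header ``sample<TAB>status<TAB><rs...>``.

    Genotype cells hold either integers 0/1/2 (minor-allele counts, empty or
    ``NA`` for missing) or two-letter allele pairs interpreted through
    ``allele_labels``.  When labels are absent for a pair-coded SNP, the two
    observed allele symbols are oriented by frequency (most common = ancestral).
    Unknown strings become missing values with a logged warning.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (sample_col, status_col):
        if col not in df.columns:
            raise FormatError(f"header lacks required column {col!r}")
    snp_cols = [c for c in df.columns if c not in (sample_col, status_col)]
    if not snp_cols:
        raise FormatError("no SNP columns found after sample/status")
    try:
        status = df[status_col].astype(int).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-integer status values: {exc}") from None

    labels = dict(allele_labels or {})
    n = len(df)
    geno = np.full((n, len(snp_cols)), MISSING, dtype=int)
    for j, snp in enumerate(snp_cols):
        raw = df[snp].str.strip()
        numeric = raw.isin(["0", "1", "2"])
        blank = raw.isin(["", "NA", "NaN", "."])
        if numeric.any() and not (numeric | blank).all():
            bad = raw[~(numeric | blank)].unique()
            logger.warning("SNP %s: unknown tokens %s set to missing", snp, list(bad))
        if numeric.any():
            geno[numeric.to_numpy(), j] = raw[numeric].astype(int).to_numpy()
            continue
        # allele-pair coded column
        tokens = raw[~blank]
        alleles = sorted({ch for t in tokens for ch in t if ch.isalpha()})
        if len(alleles) > 2:
            raise DataError(f"SNP {snp} has >2 distinct alleles: {alleles}")
        if snp not in labels:
            counts = {a: sum(t.count(a) for t in tokens) for a in alleles}
            ordered = sorted(alleles, key=lambda a: -counts[a])
            labels[snp] = (ordered[0], ordered[-1]) if ordered else ("?", "?")
        parsed = np.array([_parse_pair(t, labels[snp]) for t in raw], dtype=int)
        parsed[blank.to_numpy()] = MISSING
        unknown = (~blank.to_numpy()) & (parsed == MISSING)
        if unknown.any():
            logger.warning(
                "SNP %s: %d unparseable genotype string(s) set to missing",
                snp, int(unknown.sum()),
            )
        geno[:, j] = parsed

    return GenotypeMatrix(
        sample_ids=df[sample_col].tolist(),
        phenotype=status,
        snp_names=snp_cols,
        genotypes=geno,
        allele_labels=labels,
    )


def write_genotype_table(gm: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write the integer-coded genotype TSV (round-trips with the reader)."""
    df = gm.to_frame()
    df[gm.snp_names] = df[gm.snp_names].astype(object).where(
        df[gm.snp_names] != MISSING, "NA"
    )
    df.to_csv(path, sep=sep, index=False)


def read_vcf_biallelic(path, sample_status_map: dict[str, int]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from bi-allelic SNP records of a VCF.

    GT "0/0" -> 0, "0/1"/"1/0" -> 1, "1/1" -> 2, "./." -> missing.
    Multi-allelic records are skipped; the skip count is logged and stored on
    the returned matrix as ``gm.n_skipped_multiallelic``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_status = [s for s in samples if s not in sample_status_map]
    if missing_status:
        raise DataError(f"samples absent from status map: {missing_status}")

    names: list[str] = []
    cols: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        # gts012: 0/1/2 minor-allele count, 3 = unknown
        g = np.asarray(rec.gt_types, dtype=int)
        g[g == 3] = MISSING
        names.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(g)
    if skipped:
        logger.info("skipped %d multi-allelic record(s)", skipped)
    if not cols:
        raise DataError("no bi-allelic records in VCF")

    gm = GenotypeMatrix(
        sample_ids=samples,
        phenotype=np.array([sample_status_map[s] for s in samples], dtype=int),
        snp_names=names,
        genotypes=np.column_stack(cols),
    )
    gm.n_skipped_multiallelic = skipped  # type: ignore[attr-defined]
    return gm


# ---------------------------------------------------------------------------
# Hold-out split
# ---------------------------------------------------------------------------

def holdout_split(gm: GenotypeMatrix, test_fraction: float, seed: int = 0) -> DataSplit:
    """Stratified hold-out split; |test| = round(test_fraction * N) exactly.

    Per-stratum test counts are allocated by largest remainder so the overall
    test size matches the rounded target while preserving the case fraction
    within one subject per stratum.  Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 0.5:
        raise ValueError("test_fraction must be in (0, 0.5)")
    n = gm.n_samples
    n_test = int(round(test_fraction * n))
    rng = np.random.default_rng(seed)

    strata = [np.flatnonzero(gm.phenotype == v) for v in (1, 0)]
    for s in strata:
        if s.size < 2:
            raise DataError("each phenotype stratum needs at least 2 subjects")
    exact = [test_fraction * s.size for s in strata]
    base = [int(np.floor(e)) for e in exact]
    rem = n_test - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # largest remainder first
    for i in range(rem):
        base[order[i % len(strata)]] += 1

    test_parts = []
    for s, k in zip(strata, base):
        perm = rng.permutation(s.size)
        test_parts.append(s[perm[:k]])
    test_idx = np.sort(np.concatenate(test_parts))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return DataSplit(train_indices=train_idx, test_indices=test_idx, seed=seed)
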