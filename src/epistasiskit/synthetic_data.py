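"""Case-control genotype simulation with a known two-locus epistatic signal.

Loci are independent and drawn under Hardy-Weinberg equilibrium at configured
minor-allele frequencies.  Disease (case) status comes from a penetrance
surface over the genotype cells of one designated SNP pair; every other locus
is pure noise.  The bundled "pure epistasis" surface is the rank-one centered
design

    f[i, j] = c * (1 + d * s_i * t_j),       E_HWE[s] = E_HWE[t] = 0,

whose single-locus marginal penetrances are exactly flat at any MAF (the
familiar XOR/parity pattern is the MAF = 0.5 special case), so all signal
lives in the interaction.  Case/control status is assigned by rejection
sampling (accept a drawn subject as a case with probability equal to its
penetrance) until the requested group sizes are reached, which is exact for
case-control designs with fixed group counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix
from .infotheory import LN2

STUDY_SNPS: tuple[str, ...] = (
    "rs1815739", "rs8192678", "rs4253778", "rs6265",
    "rs5443", "rs1076560", "rs362584",
)
# control-group MAFs emulating the study's spectrum (all >= 0.165, the
# study's reported minimum, at the locus standing in for rs4253778)
STUDY_MAFS: tuple[float, ...] = (0.42, 0.35, 0.165, 0.20, 0.31, 0.25, 0.45)


@dataclass
class SimulationConfig:
    n_cases: int = 73
    n_controls: int = 245
    snps: list[tuple[str, float]] = field(
        default_factory=lambda: list(zip(STUDY_SNPS, STUDY_MAFS))
    )
    epistatic_pair: tuple[str, str, np.ndarray] | None = None
    baseline_penetrance: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.snps]
        if len(set(names)) != len(names):
            raise ValueError("duplicate SNP names")
        for n, maf in self.snps:
            if not 0 < maf <= 0.5:
                raise ValueError(f"MAF for {n} must be in (0, 0.5]")
        if not 0 < self.baseline_penetrance < 1:
            raise ValueError("baseline_penetrance must be in (0, 1)")
        if self.epistatic_pair is not None:
            a, b, f = self.epistatic_pair
            f = np.asarray(f, dtype=float)
            if f.shape != (3, 3) or (f < 0).any() or (f > 1).any():
                raise ValueError("penetrance must be a 3x3 matrix with entries in [0,1]")
            if a not in names or b not in names:
                raise ValueError("epistatic SNPs must be among the configured loci")
            self.epistatic_pair = (a, b, f)


def hwe_genotype_probs(maf: float) -> np.ndarray:
    q = maf
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def pure_epistasis_penetrance(
    maf_a: float, maf_b: float, baseline: float = 0.2, contrast: float = 0.75
) -> np.ndarray:
    """Marginal-free interaction penetrance f = c (1 + d s_i t_j).

    ``s`` is the centered over-dominant code (1, -k, 1) with k chosen so that
    its HWE expectation vanishes, normalized to max |s| = 1; likewise ``t``.
    ``contrast`` = d scales the interaction (0 = no signal); entries are
    clipped-free by construction when baseline*(1+contrast) <= 1.
    """
    def centered(maf: float) -> np.ndarray:
        p0, p1, p2 = hwe_genotype_probs(maf)
        s = np.array([1.0, -(p0 + p2) / p1, 1.0])
        return s / np.abs(s).max()

    s, t = centered(maf_a), centered(maf_b)
    f = baseline * (1.0 + contrast * np.outer(s, t))
    if (f < 0).any() or (f > 1).any():
        raise ValueError("penetrance out of [0,1]; lower baseline or contrast")
    return f


def xor_penetrance(high: float = 0.9, low: float = 0.1) -> np.ndarray:
    """Classic parity penetrance: high where genotype parities differ.

    Marginal-free only at MAF = 0.5; useful for oracle tests.
    """
    f = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            f[i, j] = high if (i % 2) != (j % 2) else low
    return f


def generate(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a GenotypeMatrix with the configured group sizes; deterministic
    given ``config.seed``.  Raises if the case quota is unreachable."""
    rng = np.random.default_rng(config.seed)
    names = [n for n, _ in config.snps]
    probs = np.array([hwe_genotype_probs(maf) for _, maf in config.snps])
    if config.epistatic_pair is not None:
        a, b, f = config.epistatic_pair
        idx_a, idx_b = names.index(a), names.index(b)
    else:
        idx_a = idx_b = -1
        f = None

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_total = config.n_cases + config.n_controls
    max_draws = 2000 * n_total + 100_000
    drawn = 0
    batch = max(1024, n_total)
    while (len(cases) < config.n_cases or len(controls) < config.n_controls):
        if drawn >= max_draws:
            raise RuntimeError(
                f"case quota unreachable after {drawn} draws "
                "(penetrance too extreme for the requested group sizes)"
            )
        g = np.column_stack([
            rng.choice(3, size=batch, p=probs[j]) for j in range(len(names))
        ])
        if f is not None:
            pen = f[g[:, idx_a], g[:, idx_b]]
        else:
            pen = np.full(batch, config.baseline_penetrance)
        is_case = rng.random(batch) < pen
        drawn += batch
        for row, c in zip(g, is_case):
            if c and len(cases) < config.n_cases:
                cases.append(row)
            elif not c and len(controls) < config.n_controls:
                controls.append(row)

    geno = np.vstack(cases + controls)
    pheno = np.concatenate([
        np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)
    ])
    ids = [f"case{i+1}" for i in range(config.n_cases)] + [
        f"ctrl{i+1}" for i in range(config.n_controls)
    ]
    return GenotypeMatrix(
        sample_ids=ids, phenotype=pheno, snp_names=names, genotypes=geno
    )


def study_like_config(
    seed: int = 0, contrast: float = 0.53, baseline: float = 0.2
) -> SimulationConfig:
    """Packaged default emulating the study's shape: 73 cases, 245 controls,
    7 HWE loci (MAF in [0.165, 0.5]) and a marginal-free epistatic pair on
    the loci standing in for rs1815739 and rs362584.

    The default contrast 0.53 is calibrated so the closed-form I(A;B;C) of
    the configured joint model is ~0.054 bits, the interaction effect size
    the study reports for its top pair."""
    mafs = dict(zip(STUDY_SNPS, STUDY_MAFS))
    f = pure_epistasis_penetrance(
        mafs["rs1815739"], mafs["rs362584"], baseline=baseline, contrast=contrast
    )
    return SimulationConfig(
        n_cases=73, n_controls=245,
        epistatic_pair=("rs1815739", "rs362584", f),
        baseline_penetrance=baseline, seed=seed,
    )


def expected_interaction_information(
    config: SimulationConfig,
) -> float:
    """Closed-form I(A;B;C) in bits implied by the configured joint model.

    Uses the case-control class prior n_cases/(n_cases+n_controls) with
    P(g_a, g_b | case) proportional to p_a p_b f and
    P(g_a, g_b | control) proportional to p_a p_b (1 - f).
    """
    if config.epistatic_pair is None:
        return 0.0
    a, b, f = config.epistatic_pair
    mafs = dict(config.snps)
    pa = hwe_genotype_probs(mafs[a])
    pb = hwe_genotype_probs(mafs[b])
    cell = np.outer(pa, pb)
    pi = config.n_cases / (config.n_cases + config.n_controls)
    j_case = cell * f / (cell * f).sum() * pi
    j_ctrl = cell * (1.0 - f) / (cell * (1.0 - f)).sum() * (1.0 - pi)
    joint = np.stack([j_ctrl, j_case])  # (class, g_a, g_b)

    def h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum() / LN2)

    h_c = h(joint.sum(axis=(1, 2)))
    ig_ab = h_c + h(joint.sum(axis=0)) - h(joint.reshape(-1))
    ig_a = h_c + h(joint.sum(axis=(0, 2))) - h(joint.sum(axis=2).reshape(-1))
    ig_b = h_c + h(joint.sum(axis=(0, 1))) - h(joint.sum(axis=1).reshape(-1))
    return ig_ab - ig_a - ig_b
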