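# Methods

This note documents the statistical machinery implemented in `epistasiskit`,
its assumptions, default parameters, and the design decisions taken where
several reasonable conventions exist.

## Data model

The universal container is a subjects × SNPs matrix of minor/derived-allele
counts in {0, 1, 2} with a binary phenotype (1 = case). Any "disfavorable /
heterozygote / favorable" display coding is a presentation mapping applied
after a model orientation is known; keeping a single canonical storage
encoding prevents orientation bugs. Missing genotypes (−1) are dropped
pairwise per analysis — each stage excludes only the subjects missing at the
SNPs it uses — with dropped counts logged; no imputation is attempted.

The hold-out split is stratified by case status with per-stratum test counts
allocated by largest remainder, so |test| = round(fraction·N) exactly while
the case fraction is preserved within one subject per stratum. Default
fraction 36/318 ≈ 11.3% (a ~10% hold-out of a 318-subject panel); the split
mechanism is seeded and deterministic.

## Quality control

- MAF = (2n₂ + n₁)/2N; if the stored orientation exceeds 0.5 the allele is
  flipped and flagged, so reported MAF ∈ [0, 0.5].
- HWE: plain χ² against (Np̂², 2Np̂q̂, Nq̂²), df = 1, no continuity
  correction; a locus passes at χ² ≤ 6.635 (α = 0.01). The test pools cases
  and controls by default; control-only testing (the conventional
  alternative for disease studies) is available via `group="control"`.
  Monomorphic loci are flagged rather than tested. A Monte-Carlo
  calibration (10,000 HWE-true replicates at p = 0.3, N = 300) confirms the
  nominal 1% type-I error in the acceptance suite.

## Inheritance-model selection

With odds odd_g = cases_g/controls_g, OR₁ = odd(Mm)/odd(MM) and
OR₂ = odd(mm)/odd(Mm); OR_mm = OR₁·OR₂. Each model's defining constraint —
dominant OR₂ = 1; recessive OR₁ = 1; over-dominant OR_mm = 1;
multiplicative OR_mm = OR₁²; additive OR_mm = 2·OR₁ − 1 — is scored by the
squared deviation on the log-OR scale, and the argmin wins. All residuals
are exposed so near-ties can be audited; when 2·OR₁ − 1 ≤ 0 the additive
model is excluded and flagged. Zero cells trigger the Haldane–Anscombe
+0.5 correction on all six cells (flagged). This nearest-constraint rule is
a deliberate design choice: no published decision rule pins the convention
down, and the log scale makes the five constraints comparable and
scale-free. One known ambiguity: OR pairs like (0.749, 0.570) sit between
the additive and multiplicative constraints; the rule picks additive there,
and the exposed residuals show the margin.

## Entropy analysis

All entropies are Shannon entropies in bits. IG(C;A) = H(C) − H(C|A) is
reported in bits and in the percent display convention (bits × 100);
G² = 2N·ln2·IG with df = (|C|−1)(|A|−1) supplies the significance test (an
exact algebraic identity, asserted to 1e-12 in tests). Interaction
information I(A;B;C) uses the Cartesian-product attribute over *observed*
cells only (absent cells are absent categories, no pseudo-counts);
I is symmetric in A, B, bounded below by −min(IG(A;C), IG(B;C)), equals +1
bit on balanced XOR, and equals −IG(A;C) for a duplicated attribute.
Interaction information is computed on the full data set by default (the
training-only alternative is a caller choice of input).

The attribute dendrogram agglomerates the pairwise Rajski-distance matrix
(d = 1 − I/H_joint; a metric with d = 0 for informationally identical and
d = 1 for independent attributes; a constant pair is defined as d = 0)
using the Lance–Williams recurrence with Ward coefficients
α_i = (n_i+n_k)/(n_i+n_j+n_k), β = −n_k/(n_i+n_j+n_k), γ = 0 applied to the
distances as given (the plain-distance "ward.D" convention, not the
squared-distance variant). Since α_i + α_j + β = 1 and γ = 0 the recurrence
is monotone — merge heights never invert — which the tests assert. The
generic recurrence engine is validated against scipy's average linkage
(identical Lance–Williams form) on random matrices. Output is a
scipy-style merge table and Newick text whose child branch lengths are
parent height minus child height.

## Multifactor Dimensionality Reduction

Cell labeling uses class-balanced weighting: a multilocus cell is high-risk
iff cases_cell ≥ (n_cases/n_controls)·controls_cell on the training data —
equivalently, its case:control ratio is at least the overall training ratio
— with ties labeled high (the common MDR convention) and pure-control cells
low. Unseen cells predict control by default; `case` and `abstain`
(excluded from metrics, counted) policies are available.

The search evaluates every combination of size 1..max_k under stratified
k-fold CV (default 10 folds, seeded); per fold, the best-training-balanced-
accuracy combination of each size earns a CVC increment. Models are ranked
by mean CV *test* balanced accuracy with CVC as tiebreak — selection by
balanced accuracy in 10-fold CV. A combinatorial guard refuses exhaustive
search over >20 attributes at k>4 unless forced. Significance comes from a
label-permutation test (default 1000 permutations) on the same statistic
with the add-one estimator p = (1 + #{perm ≥ obs})/(1 + n_perm).

Classification metrics come from the 2×2 confusion table: balanced
accuracy, sensitivity, specificity, precision, F1, Cohen's κ, Pearson χ²
(no continuity correction), and the odds ratio with Haldane correction on
zero cells and a Woolf log-SE 95% CI.

## Weighted effect coding

Main effects: for category g ≠ ref, the column is 1 in g, −n_g/n_ref in the
reference, 0 elsewhere, so fitted effects satisfy Σ_g n_g·b_g = 0 and the
reference effect is recoverable as −Σ n_g b_g / n_ref.

Interactions: rather than hand-coding matrix entries, the implementation
parametrizes the full G×H interaction surface directly. Each free
coefficient (a, b), a ≠ refA, b ≠ refB, corresponds to a basis surface with
1 at (a,b), 0 at other free cells, and reference row/column filled so that
Σ_i n_ij·b_ij = 0 for every column j and Σ_j n_ij·b_ij = 0 for every row i
(the constraint system is consistent: rows and columns share one
dependency, leaving exactly (G−1)(H−1) degrees of freedom). The design
column for a subject in cell (i,j) is that basis surface's (i,j) entry.
Because every reference choice spans the same constrained subspace, the
log-likelihood, fitted probabilities and the reconstructed surface are
reference-invariant (asserted to 1e-8), and all 9 cell effects are
recoverable from the 4 estimated ones. Any A×B cell empty in the data is a
hard error naming the cells — such pairs are not processed further.

Fitting is delegated to statsmodels' Logit (Newton, tol 1e-10, max 100
iterations); convergence requires gradient max-norm < 1e-8, else the fit is
flagged; |b| > 15 flags (quasi-)separation; rank-deficient designs raise
with the collinear columns named. Standard errors come from the inverse
observed information; Wald 95% CIs are b ± 1.96·SE; per-coefficient χ² is
the Wald z². The null is the closed-form intercept-only likelihood.
LR tests require nestedness (checked numerically by column-space
containment); non-nested requests error with AICs. The additive comparison
model codes each SNP as a numeric 0/1/2 score (1 df each). Bonferroni
columns (family = coefficients per model) are always emitted next to raw
p-values, with the significance threshold defaulting to 0.05.

## ROC evaluation

The curve runs over all distinct score thresholds; AUC is the trapezoid
area (equal to Mann–Whitney concordance with ties counted ½, asserted
against brute force); SE is Hanley–McNeil; the z-score tests AUC against
0.5. The Youden cutoff maximizes TPF − FPF with ties broken toward higher
specificity, and prediction is case iff score ≥ cutoff (closed on the case
side). Held-out subjects are scored through the reconstructed per-cell
effects of the training fit, so test-set coding never re-weights.

## Synthetic data

The generator draws independent loci under HWE at configured MAFs and
assigns case status by rejection sampling against a penetrance surface over
one designated SNP pair (exact for case-control designs with fixed group
counts; a bounded draw budget guards unreachable quotas). The default
"pure epistasis" surface is f_ij = c(1 + d·s_i·t_j) with s the centered
over-dominant code (1, −(p₀+p₂)/p₁, 1) normalized to max|s| = 1: its HWE
expectation vanishes, so single-locus marginal penetrances are *exactly*
flat at any MAF and all signal is interaction. The XOR/parity surface is
the MAF = 0.5 special case. The closed-form I(A;B;C) of the configured
joint model is available and is matched by large-sample simulation in the
tests.

The packaged study-like world has 73 cases, 245 controls (1:3.36), seven
loci with control MAFs 0.165–0.45 (minimum at the locus standing in for
the PPARα variant, matching the reported QC floor), baseline penetrance
0.20 (a plausible population fraction qualifying as "athlete-capable" in a
volunteer design; the absolute level is irrelevant to case-control
inference, only feasibility of the rejection sampler), and interaction
contrast d = 0.53, calibrated so the implied I(A;B;C) ≈ 0.054 bits — the
effect size reported for the strongest observed SNP-pair synergy in the
motivating study design. Loci are simulated without LD; covariates,
quantitative phenotypes and haplotype structure are out of scope. A green
test on this generator establishes that the pipeline recovers a known
planted interaction of realistic size under HWE and independence — not
that it would survive LD, genotyping error, or population stratification.

## Numerical choices and degenerate inputs

- 0·log 0 = 0 throughout; IG clipped at 0 against floating-point noise.
- Single-category attributes: IG = 0, df = 0, p = 1 (no test).
- Monomorphic loci: HWE χ² = 0, flagged.
- Balanced-accuracy on a one-class CV fold = recall of the present class.
- Degenerate (constant-score) ROC: chance diagonal, AUC = 0.5, flagged.
- All stochastic steps (hold-out split, CV folds, permutations, simulation)
  consume explicit integer seeds; identical config + seed yields
  byte-identical reports.

## Known limitations

- The inheritance-model rule can be ambiguous for OR pairs near two
  constraint manifolds; residuals are exposed rather than hidden.
- The MDR permutation statistic is mean CV test balanced accuracy; other
  published variants (sign tests over folds) are not implemented.
- Hanley–McNeil SE assumes the binormal-ish smooth-curve regime; with very
  few positives the CI is approximate.
- Only two-way interactions are modeled (three-way and higher are out of
  scope by design), and only four coding schemes (dummy, unweighted effect,
  WEC, additive-numeric) are implemented.
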