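# Methods

This note documents the statistical models implemented in `priorvar`, the
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Null model

All quantitative-trait tests are score-type tests against a fitted null
model `y = Xβ + ε` with residual covariance `Σ = σ_g²·2K + σ_e²·I` for
family samples (K the pedigree kinship matrix) or `Σ = σ_e²·I` for
unrelated designs. Variance components are estimated by restricted maximum
likelihood through a one-dimensional profile over the heritability ratio
`h² = σ_g²/(σ_g²+σ_e²)`: the kinship matrix is eigendecomposed once, the
profiled REML criterion is evaluated on a 41-point grid over [0, 0.999],
and the best cell is refined by bounded scalar minimization to tolerance
1e-6. `h²` is allowed to sit on the boundary 0. Binary traits get a null
proportion model; the only binary-trait test is the permutation LRT
(quantitative-trait SKAT/T5 machinery is not exposed for binary outcomes).

Downstream tests work in *whitened* coordinates: every vector is multiplied
by the symmetric inverse square root of the fitted `Σ`, after which null
residuals have (approximately) unit covariance and covariates are removed
by an orthogonal projection. `decorrelate_trait` exposes the whitened
residuals as the "conditionally independent surrogate" trait used by the
gene-level tests; because the matrix square root is symmetric and
deterministic, the surrogate is reproducible bit-for-bit.

## Dosage conventions

Dosages are stored exactly as read (the `DS` field of a VCF, the ALT-allele
count from `GT`, or a dosage TSV), with missing entries imputed to twice
the allele frequency of the non-missing entries — imputation rather than
subject dropping maximizes sample size and is logged. `compute_maf` folds
frequencies above 0.5 and flags the fold; the weight formulas always
receive the folded (minor-allele) frequency. Burdens and kernels use the
stored dosages directly, trusting the minor-allele coding convention of the
input; the fold flags are the audit trail for inputs that violate it.

## Chi-square mixture tails

SKAT-type statistics are quadratic forms whose null law is
`Σ_j λ_j χ²_{1,j}` with `λ_j` the eigenvalues of the projected kernel.
Tail probabilities are computed by numerical inversion of the
characteristic function in the Imhof form

    P(Q > q) = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,

with `θ(u) = ½ Σ arctan(λ_j u) − qu/2` and
`ρ(u) = Π (1+λ_j²u²)^{1/4}`. The integrand's phase velocity is bounded by
`max(Σλ, q)/2`, so the integral is evaluated on fixed panels of at most
about one oscillation each with 24-point Gauss–Legendre quadrature; the
truncation point is chosen where the phase is guaranteed decreasing at rate
≥ q/4 and one half-oscillation of the monotone envelope bounds the
remaining tail below 1e-8. A single eigenvalue is handled exactly as a
scaled 1-df chi-square. If the inversion cannot meet its error target the
moment-matched noncentral-chi-square approximation (Liu–Tang–Zhang) is
used instead and the fallback is recorded in the result's `method` field,
so the provenance of every p-value is visible in the output.

The p-values are asymptotic in the sample size because the null variance
enters as a plug-in estimate (the same convention as the standard SKAT
implementations). In our simulations the tests are mildly conservative at
a few hundred subjects (empirical size ≈ 0.035–0.045 at nominal 0.05 for
n ≈ 250) and accurately calibrated from n ≈ 500–600 upward; calibration
checks in the test suite therefore run at n ≥ 400.

## Weights

Three MAF schemes (Madsen–Browning `1/(MAF(1−MAF))`, inverse MAF, and the
beta(1,25) density) are strictly decreasing in MAF; monomorphic variants
get weight 0 under the two unbounded schemes since they carry no signal.
Functional scores are harmonized so that higher always means more
putatively damaging: PolyPhen2 passes through, SIFT maps to `1−sift`, and
RegulomeDB categories 1..6 map to the ordinal `s = 7−c` (sub-categories
like 1a–1f are collapsed to their integer major category first). The
ordinal is weighted `s²` in burdens and `s` inside kernels, so the kernel
weight squared equals the burden weight. Binding-site weights are signed
with magnitudes 10/5/1; a missing direction defaults to +1 and a missing
flag to "nonfunctional", both logged. Variants lacking any annotation keep
the scheme's minimum weight rather than being excluded; an explicit filter
step is available for users who prefer annotation-based reduction. An
optional combined multi-source prior (max over harmonized sources rescaled
to [1, 6]) is provided but off by default, since no canonical combination
rule exists.

## Aggregation tests

The T5 burden test filters to variants with MAF ≤ 0.05 (configurable),
forms the weighted burden, and reports the two-sided normal p of the score
statistic `U/√Var(U)` in whitened coordinates. A burden with zero variance
is flagged degenerate, and a region emptied by the MAF filter is flagged
empty — neither produces a p-value.

SKAT supports three kernels: weighted linear `GWG'` (no variant
interactions; the statistic and eigenvalues are computed from the n×m
half-kernel so regions are cheap), weighted quadratic `(1+x'Wx)²`, and
weighted IBS allele sharing. With one variant the linear-kernel p equals
the single-variant score-test p exactly.

The weighted-threshold LRT dichotomizes the signed burden at a threshold τ
(default: the median burden — the reference describes "a given threshold"
without a rule, so the default is a documented choice) and compares the
exceedance proportions of cases and controls with a binomial LRT, which
equals the G statistic of the 2×2 table. P-values come from permuting
status labels with the add-one estimator `(1+#{perm ≥ obs})/(1+n_perm)`,
so they are never exactly zero; when sibship blocks are supplied the
permutation is restricted to within-block swaps so familial dependence
cannot inflate the type I error.

## Combination

`weighted_sum_test` forms `Qws = (1−λ)Q_rare + λQ_common`. When both
components carry their projected half-kernels the null eigenvalues come
from the joint decomposition of `(1−λ)K_rare + λK_common`, which handles
LD between the rare and common sets exactly; otherwise the two scaled
eigenvalue lists are concatenated (an independence approximation) and the
result is flagged. λ is a free parameter with presets (fixed 0.5,
MAF-proportional splits) left to configuration.

`fisher_brown` pools k correlated p-values: `T = −2Σ log p` with mean 2k
and variance `4k + 2Σ_{i<j} cov_ij`, where the covariance of the log terms
is mapped from the statistic correlation by the standard cubic
approximation `ρ(3.263 + ρ(0.710 + 0.027ρ))`; T is referred to the scaled
chi-square `c·χ²_f` with `c = Var/(2E)`, `f = 2E²/Var`. Zero correlation
reduces exactly to Fisher's method. The correlation itself is estimated by
`estimate_null_correlation`: parametric draws from the fitted null
covariance, recomputation of both statistics per draw, and the empirical
correlation of `−2 log p` (at least 200 draws enforced).

`rho_grid_combine` evaluates `Q(ρ) = (1−ρ)Q_SKAT + ρQ_burden` on a grid,
reporting a Davies p per grid point. The overall statistic is the minimum
per-ρ p; its null is calibrated by parametric resampling. For the
calibration the per-ρ Q→p map must be identical for the observed data and
the draws, and it must be cheap over hundreds of draws, so the monotone
moment-matched (Liu) transform is used on both sides; the add-one
estimator makes the overall p valid and never zero. The reported per-ρ
p-values still use the Davies inversion.

## Effective number of tests

Replicate null traits (no variant effects, familial covariance preserved
parametrically) are scanned with per-variant tests; in whitened
coordinates the per-variant statistic is the exact regression t given the
covariates, so null p-values are exactly uniform for Gaussian traits and
the minimum over n independent variants is beta(1, n). The beta(1, n_e)
shape parameter is fitted by its closed-form MLE
`n̂_e = −m / Σ log(1−p_min,i)` (the estimator choice is ours; the
alternative of histogram curve-fitting is less reproducible), with a
Kolmogorov–Smirnov statistic reported as the goodness-of-fit diagnostic.
`α* = α/n̂_e` with α configurable (default 0.05). Duplicated variants
halve `n̂_e`, the desk-scale analogue of LD reducing the multiple-testing
burden on real sequence data.

## Expression-informed weighted FDR

Genes with more than 1 and fewer than 50 rare variants (0 < MAF < 0.01;
monomorphic sites do not count) are tested by the sequential-sum burden
test: variants are scanned in MAF-descending order, each weight chosen
from {+1, −1} to maximize the burden-regression score statistic given the
weights already fixed, then zeroed if exclusion improves the statistic.
Because the weights are data-adaptive the p-value reruns the entire
selection on label-permuted surrogate traits (add-one estimator). The scan
order and selection rule are our documented reading of "sequential with
variable selection"; the permutation calibration is what validates them.

Independently, each gene's *unit-weight* burden `s*` enters two
conditionally independent regressions on the expression subsample:
expression on burden adjusting for trait, and trait on expression
adjusting for burden (covariates, when supplied, enter both). The raw
weight is `ν* = max over the gene's probes of t_E² · t_T²` (max of the
product, reading the defining formula left to right); genes without probes
or with constant burden get the neutral weight 1, flagged. Weights are
normalized to mean 1 over the tested genes — the condition under which
weighted FDR control is guaranteed for weights independent of the null
p-values — and two decision rules are reported: the fixed threshold
`p_g/ν_g ≤ α_FDR` and (the default) Benjamini–Hochberg step-up on the
weighted p-values.

## IBD regression mapping

For pairs of unrelated subjects (a kinship cutoff of 0.044 — below
third-degree relatives — is available to select them), the squared trait
difference D and squared trait sum S are regressed separately on IBD
sharing status per locus. Traits must be covariate-adjusted residuals;
mean removal happens in that upstream adjustment, which is what makes the
test invariant to constant trait shifts (S itself is not shift-invariant).
The slopes are combined by reciprocal-variance cross-weighting
`β̂ = w_S β̂_S + w_D β̂_D` with `w_S = σ_D²/(σ_S²+σ_D²)`,
`SE = √(w_S²σ_S² + w_D²σ_D²)` treating the two fits as independent, and
`t = β̂/SE`. Under linkage, sharing decreases D and increases S, so the
two slopes carry opposite signs; the default `flip_D` policy negates β̂_D
before combining so the signals add instead of cancelling, and the
`literal` policy applies the formula exactly as written. Both are
configurable because the convention is genuinely open; the default is our
choice, justified by the sign argument above, not asserted as anyone
else's intent. Because pairs sharing a subject are dependent, genome-wide
significance uses the permutation distribution of max |t| under
subject-level trait permutation, which preserves the pair dependence.

## Synthetic data

Genotypes come from a Gaussian copula: two latent standard-normal draws
per subject (block-exchangeable correlation r within LD blocks) are
thresholded at Φ⁻¹(MAF), giving Binomial(2, MAF) marginals and positive
dosage LD within blocks. This is adequate for exercising LD-aware
statistics at desk scale but does not reproduce haplotype mosaics,
recombination gradients, negative LD, or realistic allele-frequency
spectra — so passing tests demonstrate correct statistical behavior under
the stated model, not robustness to every feature of real sequence data.
Tests assert against *realized* (not target) MAF and LD. Family genotypes
gene-drop founder haplotypes through the pedigree; traits are
`T = Σβ_i x_i + g + e` with polygenic `g ~ N(0, σ_g²·2K)`, and effect
sizes can be driven linearly by harmonized functional scores
(`β_i = β_max·score_i`), emulating generating models in which effects
grow with predicted functionality without claiming any particular
constants. Expression probes follow `E = b_E·s* + c·T + noise`. The IBD
generator gives each subject a latent causal allele; at the linked locus a
pair shares iff the carrier states match, so sharing pairs have similar
traits, while null loci get independent Bernoulli sharing at the same
marginal rate. Every generator is a pure function of its spec and seed.

## Simulation-study problem sizes

The packaged acceptance study (`scripts/acceptance.py`) uses sizes chosen
to finish in minutes while keeping assertions statistically meaningful:
type-I-error runs of 300–500 null datasets per test at n = 300–600
subjects; 10–20 seeds of m = 1000 minimum-p replicates over 500 variants
for the effective-test-count recovery; and a weighted-FDR study of 600
genes (30 with mediated effects) × 259 subjects × 20–40 replicates with
499 permutations per gene. The FDR study's mediation parameters
(b_E = 1.5 expression units per rare allele, b_T = 0.5, a direct variant
effect of 0.5, one probe per gene) were fixed a priori as a plausible
eQTL-mediated architecture; with ~1.6% permutation-p granularity and
600-gene BH thresholds, unweighted BH has essentially no power there,
which is precisely the regime in which expression-informed weighting is
worth its cost.

## Known limitations

- Binary-trait SKAT/T5 are not implemented; the permutation LRT is the
  case/control path.
- REML uses a single-component kinship model; dominance, shared
  environment, and longitudinal structure are out of scope.
- Kernel p-values are asymptotic (see above); no exact small-sample
  resampling SKAT.
- The analytic SKAT-O overall p-value machinery is not implemented; the
  ρ-grid overall p is resampling-calibrated instead.
- The BP-medication encoding question for real covariate tables is left to
  the user: medication flags can enter as covariates or be used to exclude
  subjects, both supported through the trait table.
- `estimate_null_correlation` and the ρ-grid calibration use the Liu
  transform per draw for speed; only the reported per-point p-values use
  the full inversion.
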