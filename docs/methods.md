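# Methods

## Model

Disease liability is standard normal: an individual is a case when
liability = g + e exceeds T = Φ⁻¹(1−K), with genetic score g of variance h²
(liability-scale heritability) and independent Gaussian noise e of variance
1−h². Per-variant effects are on the standardized genotype scale, so
h² = Σ βᵢ² and the per-allele effect is βᵢ/√(2pᵢqᵢ). This standardized reading
is the only one under which the capture metrics below are exact identities,
and it is the convention adopted throughout.

The alpha model draws βᵢ | pᵢ ~ N(0, σ²_{g,α}·[2pᵢ(1−pᵢ)]^α) with α ∈ [−1.5, 0]
by default (values outside the grid are allowed with a warning). σ²_{g,α} is
drawn uniformly on [0, 1] and the realized Σβᵢ² is then rescaled to the target
h² *exactly* — not in expectation — which makes identities such as
"S = M ⇒ h²_G = h²" machine-precision testable; the recorded σ²_{g,α} is the
post-rescaling value. The attenuated variant multiplies prior variances by
w_i = min(1, (pᵢ/p₀)^τ) and renormalizes by fixed-point iteration
(tolerance 1e-10, cap 100 iterations; τ = 0 recovers the plain model). This
attenuation scheme is an explicit design choice of this package — a simple,
documented cap that delivers "reduced rare-variant contribution" — not a
reconstruction of any particular published weighting.

## Capture metrics

`imputation_r2` is the squared Pearson correlation between true and imputed
dosages (equivalently univariate-regression R²), clamped to [0, 1]; a constant
true dosage raises `ConstantInputError`. `tagging_rho2` is the **adjusted** R²
of the regression of an untyped variant on all genotyped variants within
±1.5 Mb (configurable), with negative adjusted values clamped to 0 — whether
to clamp is not externally specified and clamping is chosen here because it
keeps h²_G non-negative. Genotyped variants carry ρ² = r²_imput = 1 by
convention (each is its own perfect imputation), which makes h²_G and h²_I
coincide with h² when S = M. If a window holds ≥ n−2 genotyped predictors the
regression is ill-posed and predictors are screened to the n/10 largest
marginal correlations (flagged); this cannot occur at biobank scale but needs
a rule on desk-scale panels.

Capture proportion curves prop_G(α), prop_I(α) come in two forms: a
Monte-Carlo average over effect draws (`capture_proportion_curve`) and a
deterministic large-M expectation (`expected_capture_curve`) that weights each
variant's capture quality by its normalized prior variance. The deterministic
curve is what the best-fit-α solver bisects — decoupling the solver from
simulation noise — with monotone linear interpolation between grid points and
a clear error naming the attainable interval when the median GWAS heritability
cannot be matched on [−1.5, 0].

## AUC ceiling

`auc_max(h², K)` implements the liability-threshold approximation
Φ((i−v)h² / √(h²[(1−h²i(i−T)) + (1−h²v(v−T))])) with i = z/K, v = −z/(1−K);
the square root in the denominator is required for dimensional consistency and
is validated against the simulation oracle: over h² ∈ {0.2, 0.45, 0.7} ×
K ∈ {0.01, 0.1, 0.25} at 500,000 individuals per cell the maximum absolute
formula-vs-simulation difference is ≤ 0.01 (typically ~0.005). h² = 0 returns
0.5 by continuity; a non-positive denominator (pathological h², K) raises
rather than returning a number. The per-disease report consumes a config of
(label, prevalence, twin h², five GWAS-based h² estimates); the packaged
`data/diseases.yaml` carries the six twin-study heritabilities and *clearly
flagged placeholder* prevalence and GWAS-heritability values that users should
replace with sourced estimates.

## GWAS machinery

N_eff = 4/(1/N_case + 1/N_controls); reporting rounds to the nearest integer
(validated against six published study values), the raw float is retained.
AUC uses the Mann–Whitney rank statistic with midrank ties; its variance uses
Hanley–McNeil by default because the upstream estimator choice is typically
unreported, with DeLong behind a flag. Meta-analysis is standard
inverse-variance pooling. Top-strata odds ratios use a 2×2 table with a Woolf
CI and seeded random tie-breaking at the cutoff.

The convergence curves replace full PRS training with its independent-variant
limit: marginal estimates β̂ᵢ = βᵢ + N(0, 1/N) shrunk by the infinitesimal
posterior-mean factor b = h²/(h² + M/N). This is an *emulation* of
LD-aware PRS training valid only for independent variants — it is what makes
desk-scale convergence demonstrations possible, and the test cohort is reused
across N within a replicate so monotone convergence is visible at 20
replicates. Default problem size: M = 2,000 variants, 4,000 test individuals,
terminal N = 100·M/h².

## Synthetic generator

Haplotypes are a latent Gaussian AR(1) process over variants, with step
correlation `ld_strength^(gap/mean_spacing)`, thresholded at the MAF-matched
quantile; two haplotypes sum to the dosage. This gives cheap, controllable LD
decay; it does not produce coalescent-realistic haplotype structure, mutation
age–frequency coupling, or population structure, so passing tests demonstrate
correctness of the estimators under the stated model, not robustness to real
genotype pathologies. The default MAF spectrum has density ∝ 1/p on
[1e-4, 0.5] (rare-skewed, as in sequencing data); a uniform option exists.
The genotyped subset is drawn with probability 0.9 for MAF ≥ 5% and
proportionally less below, mimicking array design.

Imputed dosages are r·(standardized true dosage) + √(1−r²)·noise mapped back
to dosage units, with target r² from a logistic function of log₁₀(MAF)
(bounds 0.02–0.98, midpoint 10^−2.15, slope 1.8 — chosen so the mean target r²
on the default spectrum is ≈ 0.5 and quality rises steeply with MAF). Naive
clipping to [0, 2] would inflate rare-variant mean dosages and realized r²;
instead each variant's deviations around its expected dosage are shrunk by a
per-variant factor λ (bisected, 40 iterations) until the clip-induced mean
bias vanishes. Scaling signal and noise alike leaves the correlation at its
target while preserving allele frequency; residual truncation still biases
realized r² upward by ~0.05 for very rare variants at n = 1,000. The default
calibrated panel (n = 1,000, m = 1,200, LD 0.97, 8 Mb span) reproduces the
qualitative structure the capture analysis needs: mean r²_imput ≈ 0.37 above
mean ρ² ≈ 0.20 on untyped variants, correlation between them ≈ 0.7.

Annotation tracks are interval sets anchored on variant positions (so every
track intersects ≥ 1 variant even at 10⁻⁵ coverage), with target coverages
log-spaced across the requested range and categories cycling through eight
standard classes. Coordinates are 1-based inclusive internally; BED files are
read/written as 0-based half-open with explicit conversion.

Phenotypes: the realized genetic score is rescaled to variance exactly h²
before adding N(0, 1−h²) noise — LD between causal variants otherwise makes
Var(g) ≠ Σβ², breaking the prevalence calibration. The liability threshold's
normal-tail translation additionally presumes an approximately Gaussian score;
with few, very rare causal variants the score is skewed and realized
prevalence falls below K, which is a property of the model, not a bug.

A single top-level seed fans out to fixed named substreams (panel, subset,
imputation, annotations, phenotype), so each component is reproducible
independently of call order.

## Enrichment

For a binary indicator the univariate OLS slope equals the in/out group-mean
difference exactly (asserted on every fit); the standardized coefficient
z-scores both response and predictor, i.e. it is the Pearson correlation.
`enrichment_scan` vectorizes the same fit across a whole indicator table. The
GENCODE-adjusted model drops internally collinear adjusters (reported) and
raises when the focal indicator is collinear with them. Multiple testing is
Bonferroni at 0.05/K — chosen as the most conservative standard option.
Rare-variant comparisons use a two-proportion z-test at a configurable cutoff
(default MAF < 0.01); both the cutoff and the test are this package's declared
choices.

## Problem sizes and tolerances

Defaults are sized for a single CPU: capture tables on ~1,200-variant panels
(seconds), ceiling validation at 500,000 individuals per grid cell,
convergence at 20 replicates × 4,000 test individuals, null calibration at
400–500 replicate scans of 1,099 tracks. Bisections (best-fit α, clip factor)
run to 1e-4 or 40 fixed iterations; capture-metric identities are asserted to
machine precision; Monte-Carlo assertions use explicit standard-error bands.

## Known limitations

- ρ² and r²_imput at n = 1,000 carry finite-sample noise absent at biobank
  scale; adjusted R² mitigates but does not remove it.
- The shrinkage-PRS emulation ignores LD, so convergence curves speak to the
  independent-variant theory, not to any specific trained PRS.
- The per-disease report's prevalence and GWAS-heritability inputs are
  placeholders; its numbers illustrate the pipeline, not published estimates.
- Real annotation compendia (cell-type-resolved, genome-wide) are out of
  scope; tracks here exist to exercise the interval and regression machinery.
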