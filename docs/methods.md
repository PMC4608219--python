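# Methods

`btwas` implements a two-cohort transcriptome-wide association analysis of
body mass index (BMI) in whole blood, together with a synthetic-study
generator that makes every stage testable against known planted truth.

## Statistical model

For each transcript *j* and cohort *c*, log2 expression is modelled by
ordinary least squares:

    y_jc = alpha + beta_jc * BMI + gamma' * covariates + e,   e ~ N(0, s^2)

with adjustment for age, sex, red and white blood cell counts, hematocrit,
platelet count, RNA integrity number (RIN), amplification plate (indicator
contrasts against a reference plate) and sample storage time. Storage time
enters linearly. The BMI coefficient `beta_jc` (log2 units per kg/m^2), its
standard error and the two-sided t-test p-value (n − k residual degrees of
freedom) are retained. p-values are floored at 1e-300 so the z-conversion
below never returns infinity; a residual variance of exactly zero (possible
only on noiseless synthetic data) is flagged and reported at the floor.

Cohorts are combined by sample-size-weighted z-score meta-analysis. Each
cohort's two-sided p is converted to a signed z-score,
`z = sign(beta) * Phi^-1(1 - p/2)`, and combined as

    z_meta = sum_c sqrt(n_c) z_c / sqrt(sum_c n_c)

with a two-sided meta p-value from the normal tail. Note that two cohorts at
the same z combine to sqrt(2)·z — evidence accumulates; the combination is
not an average. Benjamini–Hochberg step-up q-values are computed across the
filtered probe set, and probes with q < 0.01 are called significant.

Probes collapse to genes by minimum meta p-value (ties broken by smallest
probe id). A gene's direction class is **positive** or **negative** if all
its significant probes share that sign and **inconsistent** otherwise;
summaries report counts and percentages rounded half-up to one decimal.

## Preprocessing

Samples with RIN < 7 (strict) or any missing BMI/covariate value are dropped
before normalization; exclusion counts per reason are logged. Quantile
normalization then forces every retained sample's intensity distribution
onto the across-sample mean of order statistics; tied values within a sample
receive the mean of the reference quantiles of their tied ranks (the limma
`normalizeQuantiles(ties=TRUE)` convention), which makes the operation
idempotent. Cohorts are normalized separately, as they were profiled
independently. Expression is then log2-transformed (nonpositive entries,
which cannot arise from the generator, are clipped to a configurable floor).
Transcripts are retained only if their detection rate — the fraction of
samples with detection p-value < 0.05 (strict) — exceeds 50% (strict) in
*every* cohort.

## Over-representation analysis

Significant genes, stratified as all / positively / negatively associated,
are tested against each gene set of a user-supplied GMT collection with a
right-tailed Fisher's exact (hypergeometric) test. The reference universe is
the intersection of array-represented genes and collection genes; input
lists are intersected with the universe first. BH q-values are computed
within each stratum across sets; the enrichment ratio is overlap/set-size.
Strata with no genes are reported as not applicable ("N. A."), and an input
list equal to the whole universe is flagged degenerate (the overlap is
forced, p = 1).

The permutation analysis resamples, B times (default 5000), a uniform random
gene list of the observed size from the universe and recomputes each set's
Fisher p; the per-set empirical FDR is `(1 + #{p_b <= p_obs}) / (B + 1)`.
The add-one correction keeps the estimate away from zero. This random
input-list scheme is one admissible reconstruction of a permutation
robustness analysis; the scheme is isolated in one function and pluggable.

## Overlap graph

Each selected set becomes a node sized by its count of significantly
associated transcripts; pairwise similarity is the Jaccard coefficient of
the sets' associated-transcript memberships. An edge requires at least one
shared transcript and a coefficient at or above the graph threshold: the
smallest observed coefficient such that at most (100 − q)% of all pairs
(zero-overlap pairs included by default) lie at or above it, with q = 90 by
default. On tie-free data this coincides with the round-up nearest-rank
percentile; with the heavily tied coefficient distributions produced by
small integer set sizes, a plain order statistic would let every tied pair
through and the retained fraction could far exceed 10%, so the bounded
variant is used. Raising the percentile can therefore never add edges, and
at q = 90 at most ceil(0.1 · #pairs) edges exist.

## Sensitivity analysis

The association and meta stages are re-run with added covariates (e.g. the
five relative differential blood-count fractions, or HOMA-IR) and compared
with the base model by squared Pearson correlations, in percent, of three
probe-level vectors: the meta effect size, its standard error and
−log10 p. Because the z-based meta-analysis has no native effect size, the
meta-level beta and SE are defined as the n_c-weighted means of the
per-cohort estimates; both definitions are isolated in `meta_effect` and can
be swapped.

## Synthetic-data generator

The generator emulates the analysis' assumed structure, not microarray
physics. Per cohort, BMI ~ N(mean, sd^2) with defaults 28.9 ± 4.5 and
27.3 ± 4.6 kg/m^2 and analyzed sample sizes 988/989; covariates are drawn
around realistic blood-count and demographic moments (two cohort profiles:
one older, one younger). All generated samples pass QC (RIN uniform on
[7, 10], complete covariates) because the default cohort sizes are analyzed
sizes; QC code paths are exercised by injecting low-RIN/missing values in
tests. Log2 expression is

    baseline + beta_true * BMI + Gamma' z_covariates + lambda * F + noise

and raw intensities are `2^x`, so the preprocessing log2 inverts the map.

Key choices, fixed once:

- **Planted effects.** A fraction of probes (defaults 3% positive, 5%
  negative — more negative than positive associations) carries a *fixed*
  standardized effect: `effect_size_sd` residual SDs per BMI SD (referred to
  the mean cohort BMI SD), default 0.3. A fixed magnitude makes recovery
  statements about the stated effect size rather than about the lower tail
  of a random-effect draw. Signs are assigned gene-wise (whole genes are
  planted), so no gene is inconsistent by construction and direction
  recovery can be scored exactly.
- **Reticulocyte block.** A latent per-sample factor with correlation 0.3 to
  standardized BMI loads (0.5–1 residual SDs) on a block of otherwise
  unplanted genes, mimicking an erythrocyte-to-reticulocyte ratio shift that
  produces genuinely BMI-associated transcripts without per-gene regulation.
  Block probes' marginal slopes are recorded in the truth table. The factor
  magnitude is a package choice; no empirical calibration exists for it.
- **Detection p-values.** Expressed probes draw Beta(0.2, 5) (concentrated
  near zero, detection rate ≈ 0.79); failing probes (default 30–50% of the
  universe) draw Uniform(0, 1) (rate ≈ 0.05), far on either side of the 50%
  filter. Planted genes are placed only on detectable probes — signal at
  background intensity would be unmeasurable anyway.
- **Nuisance structure.** Per-probe covariate coefficients ~ N(0, 0.1) on
  standardized covariates, shared across cohorts (biology travels); plate
  batch offsets are cohort-specific; samples are assigned round-robin to
  96-well plates. HOMA-IR is right-skewed and mildly BMI-coupled.
- **Scale.** The default probe universe is 8,000 probes on 6,000 genes — a
  scaled-down array. The test and acceptance simulations use 2 × 300
  samples and 2,000 probes on 1,500 genes, sizes at which the planted
  standardized effect of 0.3 yields meta z ≈ 7 for planted probes and the
  whole pipeline runs in about a second.

What the generator does *not* emulate: bead-level noise, scanner artifacts,
probe cross-hybridization, realistic gene-gene correlation beyond the single
latent factor, population stratification, or missing intensities (matrices
must be complete; imputation is out of scope). Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to real-array pathologies.

## Numerical and policy details

- BH step-up is implemented directly (sorted cumulative minimum) and checked
  against `statsmodels.stats.multitest.multipletests` to 1e-12.
- `fisher_right_tail` delegates to `scipy.stats.hypergeom.sf`; tests compare
  it against exhaustive enumeration for every universe size N ≤ 25 to 1e-10.
- The single-probe fit uses statsmodels OLS; the cohort sweep solves the
  shared design once by QR and is tested to agree with the per-probe route
  to 1e-8.
- Rank-deficient designs raise an error naming the collinear columns; a
  constant BMI vector is the canonical case.
- All randomness flows from explicit integer seeds (`numpy.random
  .default_rng`); the CLI derives stage streams as fixed offsets from the
  single config seed, and reruns are byte-identical.

## Known limitations

- The permutation scheme is a reconstruction (random input-list resampling);
  other schemes (gene-label or phenotype permutation) would give different
  absolute FDRs, though rank agreement with Fisher p is expected under all.
- Whether FDR correction should run over probes or genes is a modelling
  choice; it runs over the filtered probe set here.
- The direction composition of a gene set counts inconsistent genes as not
  significant.
- The concordance R² compares all filtered probes, not only significant
  ones.
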