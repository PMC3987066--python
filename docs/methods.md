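# Methods

## The variability caller

The analysis targets experiments with exactly two biological replicates per
condition.  Its unit statistic is the per-gene between-replicate divergence
on the pseudocounted log scale, `d_g = |log2(F_R1 + c) − log2(F_R2 + c)|`
with pseudocount `c = 1`, computed only for genes whose FPKM strictly
exceeds a floor (default 0.5) in *both* replicates.  The floor removes the
regime where Poisson counting noise and the pseudocount dominate; genes
failing it are absent from a sample's divergence map entirely (not recorded
as `d = 0`), so they can never be called variable in that sample.

FPKM is computed by the literal normalisation formula
`counts · 10⁹ / (exon_model_length · total_mapped_fragments)` with
paired-end fragments as the counting unit.  Aligner-specific library-size
adjustments (e.g. hit-weighted totals) are deliberately not modelled; users
with externally computed FPKM tables feed them in directly.

**Cutoff convention.**  With `N` passing genes in the reference sample and
top fraction `f`, we take `k = ceil(f·N)` and set the cutoff to the
`(k+1)`-th largest divergence (`−inf` when `k = N`).  Calling uses a strict
inequality, so absent ties exactly `k` reference genes are called — the
calibration property the test suite asserts exactly.  Ties at the cutoff
value deflate the called set, never inflate it; the tie count is logged and
reported.  Both the floor and the cutoff use strict inequalities.

**Fold gloss.**  For FPKM ≫ 1 the pseudocount is negligible and
`d > log2(1.5)` coincides with a raw expression ratio above
`1.5 + 0.5/FPKM` — between 1.5 and 1.51 for all FPKM > 50.  This is why a
top-1% cutoff in a tight reference sample can be read as "about 1.5-fold on
the natural scale".  The high-divergence subset uses `d ≥ log2(fold)`
(inclusive, default fold = 3) on the same pseudocounted scale; defining the
3-fold rule on raw FPKM ratios instead would decouple it from the statistic
the caller ranks, so the pseudocounted definition is used throughout.

**Correlations.**  Between-replicate Pearson correlations default to the
floor-passing genes; a config switch (`correlation_gene_set="all"`) uses
every gene, since either convention is defensible for the all-gene scatter
view.  Shared-gene R² is the squared Pearson correlation of the
least-squares fit of replicate 2 on replicate 1 log values over an explicit
gene subset (typically the variable genes shared by two samples of the same
photoperiod).

## Phenotype statistics

* `summarize_trait`: mean, unbiased variance (n−1), `CV = sd/mean`, median
  (midpoint rule).  Reported percentages round half-up only at reporting
  time; computation is full precision.
* `levene_test`: the classical W statistic on absolute deviations from the
  group mean, F-referred with (k−1, N−k) df; `center="median"` gives the
  Brown–Forsythe variant.  Mean centring is the default because the analysis
  this package reproduces cites Levene's test without naming a variant.
  When every group contributes zero within-group deviation spread the
  statistic is 0/0 and a `DegenerateVarianceError` is raised (this happens
  structurally whenever *all* groups have n = 2).
* `mann_whitney_u`: `U = min(U_a, U_b)` with mid-ranks; exact two-sided p by
  enumeration when `n_a + n_b ≤ 12` and the pooled data is tie-free,
  otherwise the tie- and continuity-corrected normal approximation.
  Identical pooled constants return p = 1 by symmetry.  The enumeration and
  approximation are delegated to scipy; an independent itertools-based
  enumeration oracle in the test suite verifies the exact path.
* `shapiro_wilk`: delegated to scipy's Royston approximation, 3 ≤ n ≤ 5000.
* `adjusted_rank_transform`: main effects are tested by two-way ANOVA on the
  mid-ranks of the raw observations.  For the interaction, both estimated
  main effects are removed first (`Y′ = Y − Ȳ_i· − Ȳ_·j + Ȳ`, observation
  marginal means), the adjusted values are ranked, and the interaction F is
  taken from the ANOVA on those ranks with ((a−1)(b−1), N−ab) df.  Perfectly
  additive data makes every adjusted value equal, so the interaction sum of
  squares is 0 and F is defined as 0 (p = 1).  Unbalanced designs use
  type-II sums of squares, computed by comparing residual sums of squares of
  nested least-squares fits; the in-package ANOVA is cross-checked against
  statsmodels `anova_lm` in the tests.  Every cell requires n ≥ 2.
* `qpcr_relative_scale`: per individual, divide by the reference-gene value;
  per gene (within a line), divide by the minimum so the lowest value is
  exactly 1.  Non-positive reference *or* expression values are hard errors:
  a zero expression value would make the min-scaling undefined.

Significance stars follow the *, **, *** convention at 0.05, 0.01, 0.001.

## Synthetic data

The expression generator works on the log2(FPKM + 1) scale so the caller's
statistic is exactly the simulated quantity.  Each gene draws a true level
`t_g ~ N(μ₀, σ₀²)` shared across samples (defaults μ₀ = 3, σ₀ = 2, chosen so
that with the 0.5 floor roughly 88% of 20,000 genes pass — the scale of a
typical Arabidopsis seedling experiment).  Each replicate observes
`t_g + ε`, with `ε ~ N(0, σ_rep²)` for stable genes (default σ_rep = 0.15, a
realistic between-biological-replicate spread for well-expressed genes) and
`N(0, (λ_s σ_rep)²)` for the planted hypervariable set of sample *s* (a
uniformly random subset of size `round(fraction_s · n_genes)`, optionally
overlapping another sample's set via the `overlap_with`/`overlap_fraction`
knob).  `FPKM = max(2^x − 1, 0)`; for genes passing the floor the clip never
binds, so stable-gene divergence is exactly HalfNormal(σ_rep√2).

The default four-sample configuration gives the wild-type long-day reference
a small (0.5%, λ = 2) hypervariable fraction — real reference samples also
contain some genuinely noisy genes — and the mutant long-day sample a large
one (10%, λ = 4, 70% shared with the reference's set), with mild (1.5–2%,
λ = 2) sets in the short-day samples.

**What the generator does not emulate:** count-level overdispersion
(negative-binomial structure), gene-length and GC biases, correlated noise
across genes, systematic replicate offsets (e.g. seed-stock age; available
as a config extension only in the sense that the user can perturb one
replicate's input), or any dependence of noise on expression level.
Passing tests therefore demonstrate the *statistical machinery* — exact
calibration, correct ranking, planted-set recovery at a known
signal-to-noise ratio — not performance on real library-preparation noise.

**High-separation benchmark.**  Against a top-1% cutoff, the cutoff sits
near the stable half-normal's z = 2.576 quantile, so the expected
sensitivity for planted genes is `2·(1 − Φ(2.576/λ))`: ≈ 0.52 at λ = 4,
≈ 0.80 at λ = 10, ≈ 0.83 at λ = 12.  The committed benchmark scenario
(`high_separation_config`) therefore uses λ = 12 with a clean reference,
10% planted fraction, σ_rep = 0.15 and 20,000 genes — the mildest regime in
which ≥ 80% recovery of the planted passing genes is analytically expected.
Sensitivity is measured against the planted genes that pass the floor, since
only those are callable.  The half-normal scale fitted to stable divergences
(median / Φ⁻¹(¾)) recovers σ_rep√2 within 5% at n ≥ 10,000.

Trait populations draw `N(mean, (cv·mean)²)` per individual with
redraw-on-nonpositive truncation (preserving the target mean essentially
exactly at realistic CV; at CV ≳ 0.5 the realised mean is biased upward —
documented, not corrected).  Defaults anchor to published root-length
populations (wild-type mean 40.53 mm, CV 0.052; over-expressor mean
31.89 mm, CV 0.164; n = 40 per line).  The factorial variant crosses
genotype with a control/stress treatment by adding a treatment effect and a
mutant×stress interaction effect to the cell means.

## Numerical choices and degenerate inputs

* TSV output uses 10-significant-digit floats (round-trips within 1e-9
  relative) and Unix newlines; reading rejects duplicate gene ids, missing
  cells, ragged rows and negative values with the offending line number.
  Sample factor levels live in a YAML sidecar, so sample labels may contain
  underscores.
* Fixture-bundle manifests record the expected caller report computed from
  the table *as re-read from disk*, so byte-level float truncation cannot
  desynchronise manifest and consumer.
* All simulation randomness flows through one `numpy` Generator seeded from
  the config; identical config + seed reproduces outputs bit-for-bit.
* Monte-Carlo problem sizes used by the test suite and acceptance script:
  5,000 replications for the Levene and ART type-I error checks (three
  groups / 2×2 cells of n = 40), 1,000 replications for Levene power at
  α = 0.001, 10 random ≤ 50-gene tables for the brute-force oracle
  comparison, and single 20,000-gene simulations for calibration and
  recovery — sizes at which the Monte-Carlo standard error is a few
  thousandths, small against the asserted margins.

## Known limitations

* The caller assumes exactly two replicates per sample; more replicates
  would want a different dispersion statistic entirely.
* The top-fraction rule is a ranking device, not a hypothesis test: it
  controls the *reference* call count, not any error rate in other samples.
* Mean-centred Levene on heavy-tailed data is liberal; use
  `center="median"` for robustness.
* The ART interaction test removes main effects estimated from marginal
  means; in strongly unbalanced designs those are not the least-squares
  effects, and the interaction test is best treated as approximate there.
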