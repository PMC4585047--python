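# Methods

## Input data model

The unit of analysis is a per-animal activation table: one row per animal,
two factors — treatment ∈ {MA, SAL} and phase ∈ {light, dark} — and one
nonnegative real count per brain region (averaged c-Fos-positive cells;
bilateral/section averaging makes non-integers normal). The reference
design is balanced: 10 animals per treatment × phase cell, 40 total, over
a 17-region panel (SCN, PVN, PVT, CEA, BLA, MEA, DG, CA1, CA3, ILC, ARC,
VMH, DMH, BNST, CIN, NACc, NACs).

## Factorial ANOVA and pattern classification

Each region is fitted with a two-way ANOVA (treatment × phase). The fit is
an OLS cell-means regression with sum-to-zero contrasts and Type-III-style
partial F tests (via statsmodels); on balanced data this equals the
classical balanced decomposition exactly (verified against an independent
hand-coded regression oracle to ~1e-14 relative error), and it remains
well defined when animals are dropped. For the balanced reference design
every F has (1, N−4) = (1, 36) degrees of freedom.

Significance flags at α (default 0.05, configurable) map to patterns by a
total truth table: treatment-only → 1, time-only → 2, treatment with
interaction (time either way) → 3, treatment and time without interaction
→ 4, nothing → 5. An interaction without a treatment main effect falls
outside the published taxonomy and is labelled `other` rather than forced.
Trend-level p values (0.05–0.10) are annotated in the output but never
influence classification.

Simple-effect post hocs compare the four cell-mean pairs (MA vs SAL within
each phase; light vs dark within each treatment) with t statistics on the
pooled ANOVA mean square error and its residual df. The Bonferroni family
is the four contrasts per region (the family actually reported per
interaction region); adjusted p = min(1, 4·raw).

## Connectivity and the permutation null

Within a group, region pairs are correlated across animals (Pearson by
default; the methodology never fixes the coefficient and operates on
activation magnitudes — Spearman is available as a flag to guard against
outliers). Correlations use pairwise-complete observations with a minimum
of 3 complete pairs; a pair below that, or a zero-variance region, is an
error naming the culprit, never a silent NaN.

Connectivity is the unthresholded node strength k_r = Σ_{s≠r} |r_{rs}|,
bounded by 0 ≤ k_r ≤ R−1. Edge-display thresholds (edge lists, GraphML,
plots) never feed back into k.

The null for "could k_r arise by chance?" randomizes the sample order:
each region column is shuffled independently per replicate. A joint
shuffle of whole rows would leave every correlation unchanged, so
independent per-column shuffles are the only randomization of sample order
that yields a nontrivial null; it destroys cross-region alignment while
preserving each region's marginal distribution. Z = (observed − null
mean)/null sd with the (n−1)-denominator sample sd of the null; Z > 2 is
the conventional cutoff. Default n_perm = 10,000. The Monte-Carlo null was
verified against exhaustive enumeration of all (4!)³ independent column
permutations on a 4-animal, 3-region instance.

By default the light and dark phases are collapsed within treatment before
correlating (two networks, 20 animals each in the reference design),
matching the source methodology and doubling per-network sample size. Note
the consequence: regions with strong shared phase effects acquire
mean-driven correlation even without animal-level coupling. An optional
within-phase centering flag (default off, to match the source procedure)
subtracts per-phase region means inside each group before correlating,
removing that inflation; it is the recommended sensitivity check whenever
time effects are widespread.

## Bootstrap comparison of group networks

Δk_r = k_r(A) − k_r(B) is tested against a group-relabeling null: pool the
animals, re-split without replacement into the original group sizes
(n_boot = 10,000 by default), and record Δk per region per re-split. A
with-replacement variant is deliberately not offered — the described
procedure is a re-partition of the combined data. Reported per region:
observed Δk, null mean/sd, Z, the add-one empirical two-sided
p = (1 + #{|Δk_null| ≥ |Δk_obs|})/(n_boot + 1) (never exactly 0), and
Benjamini–Hochberg-adjusted p across regions (raw p is primary; the
adjustment is reported because 17 regions are tested). Each replicate
draws its own RNG substream from the master seed, so results are
reproducible and order-independent under parallel execution. The
Monte-Carlo null was verified against exhaustive enumeration of all
C(8,4) = 70 equal splits on a 4 + 4 instance, and its type-I error is
calibrated (rejection rate ≈ 0.05 under exchangeable groups in the
acceptance suite).

## Synthetic-data generator

Counts are drawn from a latent Gaussian copula: per animal, a multivariate
normal vector with the treatment group's latent correlation matrix; per
region, a lognormal marginal with mean equal to the configured treatment ×
phase cell mean and coefficient of variation equal to `dispersion`;
rounded to the nearest integer. This produces right-skewed, nonnegative,
overdispersed counts under an arbitrary imposed correlation network. The
lognormal map attenuates latent correlation ρ to
(e^{ρ σₐσᵦ} − 1)/√((e^{σₐ²} − 1)(e^{σᵦ²} − 1)) with σ² = ln(1 + CV²);
`attenuated_correlation` exposes this closed form, and recovery tests
target it rather than the raw ρ (rounding is neglected — second order for
means ≫ 1). Zero dispersion degenerates to exact rounded cell means.

Defaults, chosen once as a realistic emulation of the reference study:

- `n_per_cell = 10` — the study design.
- `dispersion = 0.3` — a 30% CV, typical of regional immunohistochemical
  counts; the study reports no count variances, so this is necessarily a
  package choice and is exposed in config, never hard-coded.
- cell-mean presets per pattern (e.g. treatment-only: MA 100 vs SAL 40 in
  both phases; time-only: 120 light vs 40 dark; interaction: MA 150/60 vs
  SAL 40/40), scaled so every configured effect is detectable at n = 10 per
  cell with CV 0.3. The `interaction_no_time` preset (MA 120/60, SAL
  30/90) has exactly cancelling phase marginals, giving treatment +
  interaction without a time effect — including the saline dark > light
  arm seen in ARC.
- latent baseline r = 0.2 in both groups; optional hub VMH→{PVN, BLA, MEA}
  at r = 0.7 in the MA group only.

Hub injection can push the target matrix outside the PSD cone (a 3-partner
star at r needs r√3 ≤ 1 at base 0). The repair projects to the nearest PSD
matrix (eigenvalue clipping plus diagonal renormalization) and *reports*
the maximum entry change; by default any change above 0.05 is an error, so
large repairs cannot silently rewrite the simulation's ground truth. The
cap is an explicit parameter: the strong-hub fixture used in the power
experiments (0.7 star at base 0) is built with the cap relaxed, and its
post-repair truth — hub edges 0.597, partner–partner 0.034 — is what
recovery is measured against.

Seeding: one master seed spawns independent substreams per treatment group
and per animal (numpy `SeedSequence`), so tables are byte-identical across
runs and stable under changes elsewhere in the pipeline.

What the generator does *not* emulate: image-level data, ROI geometry and
bilateral averaging, count-specific noise (Poisson at low means), region-
specific dispersion, or non-copula dependence (e.g. tail dependence).
Passing recovery tests therefore shows the pipeline is correct and
calibrated under a plausible noise model, not that real c-Fos data meet
these assumptions.

## Numerical choices

- Correlations are computed by standardized matrix products, clipped into
  [−1, 1]; Spearman is Pearson on ranks (midranks for ties).
- Permutation/bootstrap null sds use ddof = 1; a zero null sd leaves Z
  undefined and raises rather than returning ±inf.
- Zero residual variance in ANOVA is detected relative to the centered
  total sum of squares (SSR ≤ 1e−12 × TSS), since noiseless data leaves
  SSR at ~1e−27 rather than exactly 0.
- Exhaustive-vs-Monte-Carlo agreement tests use 3 Monte-Carlo standard
  errors (fourth-moment delta-method SE for the sd).

## Problem sizes in the test and acceptance suites

ANOVA oracle equivalence uses 50 random balanced fixtures (n = 5/cell);
permutation-null exactness a 4 × 3 instance with 50,000 Monte-Carlo
replicates; bootstrap calibration 200 null datasets (17 regions, 20
animals/group, n_boot = 1,000), with the rejection rate estimated pooled
over the 3,400 per-region tests; hub-recovery power 100 simulated studies
at the same size; generator fidelity n = 2,000 animals for correlations
and n = 10,000 per cell for means. These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances.

## Known limitations

- Hub-recovery power at the reference sample size is intrinsically low:
  with 20 animals per group the null |r| per edge averages ≈ 0.18
  (sd ≈ 0.15), so a region's k sums substantial noise over 16 edges, while
  a 3-edge hub at post-repair r ≈ 0.6 adds only ≈ 1.3 to Δk against a
  relabeling-null sd near 1. At n = 20/group the hub attains the maximal
  Δk in only ~37% of simulations and bootstrap Z ≥ 2 in ~27%; reliable
  (>90%) recovery of such a hub needs on the order of 80 animals per
  group. Single-study hub findings at n = 20 should be treated as
  hypothesis-generating.
- With phases collapsed (the default), widespread time effects create
  mean-driven correlations that can dominate latent animal-level coupling;
  use the within-phase centering flag as a sensitivity check.
- The permutation and bootstrap nulls assume exchangeable animals within
  group; batch/cohort structure is not modelled.
- Connectivity sums absolute correlations, so it does not distinguish
  coherent positive coupling from mixed-sign coupling.
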