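# Methods

## Data model

The unit of analysis is one assay measurement of one well. A screen is a
long-format table keyed by (plate, row, column, assay) with donor,
control-role, treatment and dose metadata; rows are letters A–P in files
and 1-based integers in memory. Raw values must be strictly positive
because every downstream statistic lives on the log10 scale. Missing
values are explicit (NaN in grids, flagged rows in tables) and are never
imputed; each operation states whether missing entries are excluded or
merely not fitted.

Vehicle (DMSO) wells come in four roles reflecting the order in which a
well is stimulated across the two lysozyme assay phases. The package
fixes the scheme as: A = basal during the non-stimulated (NS) phase, then
stimulated in the S phase (the same protocol compound wells see); B =
never stimulated; C = stimulated in both phases; D = stimulated then
basal. This assignment makes the informative quality-control contrasts
exactly the ones the analysis reports (A+B vs C+D in LYZ.NS; A vs B in
LYZ.S) and drives the per-assay control selection for control-based fold
changes: ATP uses all vehicle wells, LYZ.NS uses A and B, LYZ.S uses A
only. The scheme is carried as metadata so an alternative ordering can be
configured.

## Spatial normalization

Plate artifacts (row, column and edge effects) are removed per plate and
assay by local polynomial regression over the integer (row, column)
coordinates: tricube weights (1 − (d/d_max)³)³ on Euclidean distance,
span expressed as the fraction of wells entering each local fit (default
1.0), polynomial degree 2, no robustness iterations. Predictors are not
rescaled; at the default span the kernel is broad enough that the row/
column unit asymmetry of a 16×24 plate is immaterial. Each well is
corrected by subtracting the surface re-centred at its median over fitted
wells, which makes the correction exactly identity-preserving on constant
plates and equivariant under adding a constant. No-cell wells are
excluded from the surface fit and from the plate median — their
background signal would drag both — but still receive corrected values by
evaluating the surface at their coordinates. The surface solve is a
batched weighted least squares (one 6-parameter system per well); a
singular system falls back to a pseudoinverse solve.

Fold changes stay on the log10 scale throughout (they are differences of
logs); linear-scale ratios are a presentation choice (10^FC), not part of
the statistics.

## SSMD scoring

Groups are treatment × dose × assay. In the primary screen the replicate
unit is the donor: each donor contributes one fold change (the mean if a
donor has several wells), giving n = 3. In the confirmatory screen wells
are the replicates (n = 8). The UMVUE SSMD multiplies the naive
mean-over-SD ratio by c_n = Γ((n−1)/2)/Γ((n−2)/2)·√(2/(n−1)); this factor
has a Γ(0) pole at n = 2, so groups with fewer than three replicates are
flagged and left unscored rather than given a degenerate estimate. The
denominator shrinks each group variance halfway toward s₀², the median of
all group variances within the same assay across the whole screen
(weights 0.5/0.5, configurable). The z-score population is all group mean
fold changes within one assay, with the sample (n−1) standard deviation.

Two properties matter and are verified by simulation: with unit group
weights the estimator is exactly unbiased for the true standardized
effect at any n ≥ 3, and its scale invariance means the decision theory
below transfers unchanged to any units.

## Decision thresholds

For a threshold β on the UMVUE scale, `t* = β/(c_n·k)` with k = √(1/n) is
the corresponding cut on the classical one-sample t statistic
√n·d̄/s, whose sampling distribution at true standardized effect β' is
noncentral t with n−1 degrees of freedom and noncentrality √n·β'. The
false-positive level against the weak-effect bound β₂ = 0.25 and the
false-negative level against the strong-effect bound β₁ = 3 are therefore

    FPL(β) = 1 − F_t(n−1, √n β₂)(t*),   FNL(β) = F_t(n−1, √n β₁)(t*).

FPL is strictly decreasing and FNL strictly increasing in β, so their
intersection is unique; it is found by bisection on a bracket with a
verified sign change, to 1e−6 in β. The primary design (n = 3) balances
the two errors; the confirmatory design (n = 8) solves FPL(β) = 0.05 and
ignores FNL. Mapping the threshold through c_n (the `umvue` scale) is the
reading that reproduces both published critical values from these design
parameters — 0.997 with balanced error 0.084 at n = 3, and 0.889 at
n = 8; the variant without the c_n factor remains available
(`scale="raw"`) for comparison.

Two deliberate mismatches between estimator and theory are inherited from
the screen's design and documented rather than "fixed": the pipeline's
default denominator shrinks toward s₀² while the error curves describe
the plain per-group SD (calibration simulations therefore use unit
weights), and c_n both corrects bias and inflates variance relative to
the naive ratio. The noncentral-t CDF delegates to scipy's
implementation and is validated in the tests against a Monte-Carlo
simulation oracle.

## Hit rules

Gates use strict inequalities. A primary hit exceeds the critical value
in both lysozyme assays; a refined hit additionally has z > 1.282 (the
standard-normal 90th percentile) in both. ATP effects are always
computed and reported but never gate by default, because viability
increases co-occur with genuine lineage effects; an optional viability
gate exists. Optimal-dose selection ranks doses by min(SSMD_LYZ.NS,
SSMD_LYZ.S) in the primary screen — the conservative both-assay reading —
and by the mean of the two lysozyme mean fold changes in the confirmatory
screen; exact ties go to the lower dose. Per-target deduplication keeps
the most potent treatment–dose, breaking ties lexicographically so
results are order-independent.

## Synthetic screens

The generator is the package's ground-truth instrument, not a fixture.
Per well and assay the log10 signal is

    baseline + plate offset + spatial surface + stimulation effect
    + treatment effect · Hill(dose) + toxicity + Normal(0, σ),

with a single seeded random stream drawn in a fixed order (placement,
then per plate × assay surface, offset and noise), so identical configs
give byte-identical tables. Choices and defaults:

- Geometry and scale: 3 donors × 5 plates × 384 wells, 433 compounds at
  doses 0.08/0.4/2/10 µM annotated to 184 targets round-robin; 24
  vehicle (6 per role) and 8 no-cell wells per plate, with leftover wells
  filled as additional vehicles so every plate is complete.
- Signal levels: baselines 10⁵ (ATP) and 10⁴ (LYZ) with no-cell
  background ~30-fold lower; per-well noise σ = 0.08–0.10 log10 units
  (a realistic ~20–25% CV for plate-reader assays); plate offsets
  σ = 0.05; spatial amplitude 0.05 (a low-order polynomial ramp plus an
  edge offset — the artifact classes the LOESS stage must remove without
  committing to one shape); stimulation adds 0.3 log10 units in the
  stimulated phase.
- Effects are specified on the SSMD scale: a hit at true SSMD β shifts
  its wells by β·σ·Hill(dose), so scored effects are directly comparable
  to the decision bounds. Abundance-type hits share one latent effect
  between LYZ.NS and LYZ.S (correlation 1); secretion-only hits perturb
  LYZ.S alone; toxic compounds lose ATP signal above a dose threshold.
  The default truth spikes ten abundance and five secretion-only hits at
  β = 3 and five toxic compounds.
- The confirmatory generator re-tests each hit at {2×, 1×, ½×, ¼×} its
  optimal dose with 2 wells on each of 4 replicate plates (n = 8) and
  large vehicle blocks (25 wells per role, so 100 vehicle wells back the
  ATP control median and 25 role-A wells the LYZ.S one).

The composition generator tilts control fractions p multiplicatively,
q_t = OR_t·p_t / Σ_u OR_u·p_u, and draws multinomial counts. This
construction always yields a proper probability vector, and with a single
non-unit OR it reproduces the (type vs rest) odds transform exactly
(p = 0.2 at OR 2 gives q = 1/3). With several simultaneous non-unit ORs
the realized type-vs-rest odds ratios differ from the designed inputs, so
the truth table reports both.

What the generator does not emulate: plate-reader saturation and
floor effects, washing/pinning failure modes, spatially correlated noise
beyond the smooth surface, donor-specific effect heterogeneity, and
compound cross-contamination. Passing recovery tests therefore shows the
statistics behave as designed under the modelled error structure, not
that any particular real screen is free of unmodelled artifacts.

## Composition statistics

Enrichment uses the cross-product odds ratio of the (type vs rest) ×
(treated vs control) table with a Haldane–Anscombe +0.5 on every cell
only when a zero cell occurs, a Woolf log-normal 95% CI, and a two-sided
Fisher exact p (sum of hypergeometric outcomes no more probable than the
observed table); the conditional-MLE odds ratio was considered and left
out as the cross-product form matches the CI construction. Abundance
gating is inclusive ("at least") and must hold in both conditions.
FDR adjustment defaults to Benjamini–Hochberg, with Bonferroni available.
Cohen's d pools variances with n−1 weights and bins |d| at 0.5/0.8/1.2/2.
The exceedance statistic uses the inverse-ECDF percentile (smallest
observed value with at least the target fraction of the reference at or
below it), which keeps integer cutoffs on count data, and counts test
values strictly above the cutoff.

## Numerical and testing notes

Tolerances: LOESS identities hold to 1e−9 (float accumulation only), the
linear-trend reproduction to 1e−6, root finding to 1e−6 in β. Test
problem sizes were chosen to keep the suite quick while leaving
comfortable statistical margins: 1e5 groups for unbiasedness (bound
|bias| < 0.05), 1e4 groups for error-rate calibration (±3 binomial SE),
2e5–1e6 draws for the noncentral-t oracle, 150–200 seeded tables for CI
coverage, and a reduced screen (120–150 compounds, 2 plates per donor)
for end-to-end recovery. Statistical assertions use fixed seeds and
3-SE-style bounds so they are deterministic yet principled.

## Known limitations

- The LOESS dialect is a faithful 2D tricube local regression but not a
  bug-for-bug reimplementation of any particular reference smoother;
  differences (predictor normalization, interpolation cells) are below
  the noise floor at span 1 on full plates but could matter at small
  spans on sparse plates.
- The error-rate theory assumes normal replicate fold changes and
  ignores the variance pooling used by the default estimator; achieved
  error rates on heavy-tailed data will deviate.
- Group scoring requires n ≥ 3; two-replicate designs are flagged, not
  scored.
- The composition module tests one cell type against the rest per
  stratum; it does not model compositional covariance between types
  (log-ratio approaches would, at the cost of the simple OR
  interpretation).
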