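# Methods

This note documents the models and procedures implemented in `urbanaudit`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not establish about field data.

## Instrument weighting

Item weights are derived from positive reciprocal pairwise comparison
matrices, one per auditor, in the analytic-hierarchy-process tradition. The
default estimator is the normalized principal right eigenvector; the
geometric mean of rows is available as an alternative and coincides with it
exactly on consistent matrices. Consistency is reported as Saaty's ratio
CR = ((λ_max − k)/(k − 1))/RI(k) against the standard random-index table; a
warning (not an error) is emitted at CR > 0.1, because inconsistent
judgements still yield usable weights and the cut-off is conventional, not
statistical. Matrices of order 1–2 are always consistent (CR = 0).

Auditor weight vectors are combined by elementwise arithmetic mean. Printed
weight tables are rounded to three decimals and their columns typically do
not sum exactly to 1 (the bundled table's auditor columns sum to 1.001, the
mean column to 0.998); the averaging operation therefore renormalizes by
default so downstream code can rely on Σw = 1. The raw (unrenormalized)
mean is retained for comparisons against printed tables, and
`WeightVector` accepts an explicit `sum_tolerance` for wrapping rounded
published columns.

## Scoring

The literal score s_i· = (C/N_i) Σ w_j x_j rescales by the applicable-item
count so that locations are not penalized for inapplicable items. With
unequal weights this correction overshoots whenever the missing items carry
less than average weight: dropping the two lightest items of the bundled
10-item weight table and answering 5 everywhere yields
(10/8)·5·0.922 = 5.7625 > 5. Both behaviours are implemented: `literal`
(default, faithful to the published equation, warns outside [1, 5]) and
`renormalized` (weights rescaled within the applicable set), which is a
convex combination of responses and therefore bounded by them. When all
items are applicable the two modes agree to machine precision whenever
Σw = 1.

Two auditors are combined by averaging their item responses per location
before scoring (an item is not-applicable only if all auditors marked it
so). Since scoring is linear in the responses, averaging responses or
averaging per-auditor scores differ only at locations with discordant
applicability marks. Per-auditor matrices are kept for reliability analysis.
Scores are carried at full precision; rounding to two decimals happens only
at serialization.

Neighbourhood ranking sorts ascending (lowest aesthetics first), breaking
exact ties lexicographically by neighbourhood id and flagging them.

## Sampling design

Within a neighbourhood, a zone *type* is drawn per point with probability
equal to the type's share of residential area (types pooled across their
polygons — equivalent to drawing individual polygons by area), then a
uniform location is drawn inside the type's polygons by area-weighted
bounding-box rejection sampling. Each point is drawn independently; the
point count per type is therefore multinomial. Observation buffers (default
radius 100 m) are not clipped to zone or neighbourhood boundaries.

`min_separation` defaults to twice the buffer radius so that observation
buffers do not overlap; violating points are redrawn up to a bounded budget,
after which the neighbourhood and achieved count are reported. Separation
redraws slightly favour spread-out configurations; for unbiased design
studies set `min_separation=0` or keep the radius small relative to the
neighbourhood.

Coordinates must be projected, in meters. There is no CRS metadata in plain
GeoJSON, so a heuristic refuses inputs whose coordinates all fit within
lon/lat bounds — buffering by "100" in degrees would be meaningless. Metric
data genuinely confined to a ±180/±90 window must be shifted or re-projected
first.

## Reliability

Cronbach's α uses the variance decomposition α = k/(k−1)·(1 − Σ var_j /
var_total) with sample variances (n−1). Rows with any not-applicable item
are dropped for α (complete-case; the count used is reported), while the
per-item ICC uses pairwise deletion, which is why each item reports its own
n. The α confidence interval is a percentile bootstrap over units (default
2000 iterations, seeded). Ordinal responses are treated as interval-scaled
reals throughout — the field's standard practice, adequate for 5-point
scales with these uses.

Item-total correlations come in two variants: plain item-rest (Pearson of
the item against the sum of the other items) and a corrected variant,
item-rest divided by √(α_without_item · SMC_item), where SMC is the item's
squared multiple correlation on the remaining items. Corrections "for item
overlap and scale reliability" vary between packages; both variants are
always reported so results can be compared against either convention. The
corrected variant can exceed 1 when an item correlates with the rest more
strongly than the reliability proxies suggest; values are reported as
computed.

Interrater agreement is ICC(A,k): two-way layout, absolute agreement,
average of k raters, (MSR − MSE)/(MSR + (MSC − MSE)/n). With raters as a
fixed panel (the "two-way mixed" reading) the estimator is the same as in
the random-raters case. The CI follows the McGraw–Wong F-based construction
for single measures, stepped up with Spearman–Brown; p comes from the F test
of ICC = 0 (MSR/MSE on (n−1), (n−1)(k−1) df), and a significance flag
mirrors the usual table convention. When MSE = 0 (perfect agreement) the CI
degenerates to the point estimate. The implementation is cross-checked in
the tests against `pingouin.intraclass_corr`'s ICC(A,k) row and
`pingouin.cronbach_alpha`.

## Subsample validation

The estimand is the census mean score of a fully audited neighbourhood; the
estimator is the mean of k blocks drawn by simple random sampling without
replacement. The draw-mean distribution is simulated with seeded Monte
Carlo (default 100,000 draws, vectorized via random-key partial sorting,
chunked to bound memory) or enumerated exactly when C(N, k) ≤ 10⁷.
Exceedance probabilities are one-sided and inclusive (≥ by default,
direction configurable), matching the "would occur at least X% of the time"
reading. Reported summaries: min, max, mean, sd and the central interval at
the requested level. The sd of draw means follows the finite-population
formula σ·√((N−k)/(k(N−1))) (population σ), which the tests verify.

Bimodality is summarized three ways: a histogram over the [1, 5] score
range; the number of modes of a fixed-bandwidth Gaussian kernel density
(Scott's factor unless overridden), counting peaks with at least 5%
prominence relative to the highest so tail wiggles are ignored; and
Hartigan's dip statistic with a Monte-Carlo p-value against uniform samples
of the same size (the conventional least-favourable unimodal null). The dip
is implemented from the classic greatest-convex-minorant /
least-concave-majorant algorithm, since no installed package provides it;
it is validated against known limiting values (equally spaced sample →
1/(2n), two equal point masses → 1/4).

## Pycnophylactic surfaces

Block scores are an intensity, not a mass, so the preserved quantity is the
zone *mean* (equivalent to volume preservation after multiplying by zone
area, for equal-area cells). Cells are assigned to zones by cell-center
containment. Each iteration smooths every cell to the mean of its von
Neumann (default) or Moore neighbours with edge replication (no-flow
boundary), then additively restores each zone's mean; iteration stops when
the maximum absolute change falls below `tol` (default 1e-4) or after
`max_iter` (default 1000). A convergence log of (iteration, max change) is
kept; on the test fixtures the max change is non-increasing after the first
iteration.

The optional clamp keeps the surface inside a stated range: after clipping,
each zone's residual is redistributed only over cells that can still move in
the needed direction (repeated up to 20 times), so both the bounds and the
zone means hold to tolerance. Grid resolution, iteration counts and boundary
handling are validated by these invariants, not against any published map.

## Ecological correlation

The SES index z-scores each component with polarity aligned so larger means
higher SES (average household income positive; % low income, % unemployed,
% less-than-high-school, % single-parent negative), averages the aligned
z-scores un-weighted, and rescales to mean 50, sd 10 (sample sd). Rank 1 is
the highest-SES neighbourhood. The polarity/weighting convention is a
package decision — source registries do not publish theirs — and affects
only this constructor.

Spearman's ρ is the Pearson correlation of average ranks. With ~15
neighbourhoods, inference is finite-sample: an empirical p from seeded
permutations of the independent variable, p = (1 + #as-extreme)/(n_perm+1),
one-sided in the direction of the observed sign by default (the published
p = 0.0241 for ρ = 0.51 at n = 15 is consistent with a one-sided test;
two-sided is a flag away). BCa intervals resample units with replacement,
estimate bias z₀ from the midrank proportion of bootstrap statistics below
the point estimate and acceleration from jackknife skewness, and read the
interval at the adjusted percentiles. BCa endpoints are not guaranteed to
bracket the point estimate; a degenerate bootstrap distribution falls back
to the percentile interval with a warning. Missing determinant values are
handled by pairwise deletion, so each determinant reports its own n.

## Synthetic study regions

The generator emulates the structure the analysis assumes, at desk scale:

* **Geometry.** Rectangular neighbourhoods of blocks_x × blocks_y square
  blocks (default 13 × 13 = 169, the scale of a real full-neighbourhood
  census) in a projected pseudo-CRS in meters; zone types occupy contiguous
  column strips apportioned by largest remainder from the configured mix.
  A type that would receive zero blocks raises an infeasible-mix error.
* **Latent field.** L_b = μ_zone + field_sd · AR-field + shift, where the
  AR field is a separable first-order autoregression over the lattice
  (coefficient φ per axis, unit marginal variance) — chosen over a full
  Gaussian process for dependency-free, seedable generation; exchangeable
  for testing purposes. The optional gentrification shift adds Δ to a
  contiguous western fraction of columns, reproducing bimodal census
  distributions with spatial structure.
* **Ratings.** Auditor a's continuous judgement of item j at block b is
  λ_j·L̃_b + (1 − λ_j)·e_bj + bias_a + N(0, σ_a²), with L̃ the standardized
  field and e_bj item noise shared between auditors (applicability and
  item idiosyncrasy belong to the site). Discretization uses fixed
  thresholds, by default the equal-probability standard-normal cut points;
  skewed response styles can be emulated by moving them. Not-applicable
  flags are drawn per site × item (furniture items 0.2, pedestrian
  infrastructure 0.03, others 0.01), mirroring the varying per-item n of
  field reliability tables; a site never loses all items.
* **Defaults.** Two auditors with biases (0, −0.1) and noise sd 0.5; item
  loadings 0.5 (furniture 0.4, pedestrian infrastructure 0.25 — the weak
  item); φ = 0.6. These place downstream α near 0.8–0.9 and per-item
  ICC(A,k) near 0.6–0.85, inside the range reported for trained auditors
  with this kind of instrument.

The "true census mean" of a synthetic neighbourhood is defined as the mean
of its census scores when *every* block is audited and scored — the estimand
of the subsample design — not a noise-free latent quantity; auditor bias and
discretization move both the census and any subsample identically, which is
exactly the property the design validation relies on.

What passing tests show: the pipeline's estimators behave as the theory
says on data with the assumed structure (unbiasedness, finite-population
spread, reliability recovery, mode detection). What they do not show: that
real streetscapes follow a lattice autoregression, that real auditors have
Gaussian noise, or that the default rates match any particular city.

## Problem sizes

Test and validation runs use desk-scale sizes chosen to make the Monte-Carlo
error negligible relative to each tolerance: 10,000 draws for zone-frequency
goodness of fit, 2000 end-to-end replicates for the bias check (|bias| <
0.02 at Monte-Carlo se ≈ 0.008), 1000 replicates for interval coverage,
100,000 draws for headline subsample distributions, 9999 permutations and
10,000 bootstrap iterations for the correlation inference.

## Known limitations

* Points are placed uniformly within zone polygons, not snapped to street
  centerlines; street-network snapping is a natural extension.
* The exact correction behind published "corrected" item-total columns is
  uncertain; both ITC variants are reported instead of guessing one.
* Weight derivation cannot be checked against published weight tables
  beyond the auditor→mean step, because the underlying comparison matrices
  were never printed.
* The dip test's p-value is calibrated against the uniform null; for small
  n it is conservative for peaked unimodal alternatives.
* No uncertainty is attached to the pycnophylactic surface; it is a
  visualization tool, not an estimator.
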