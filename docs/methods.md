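# Methods

This note documents the models, rules and numerical choices behind
`behavclust`, and what the synthetic validation does and does not show.

## Trajectories

A man's *behavioral status* at month τ is his latest self-reported value for
each longitudinal indicator at or before τ (last observation carried
forward on a monthly grid). Within a calendar month, an indicator is set to 1
if **any** valid record that month reports it — a behavior reported at any
point in a month defines that month — and to 0 only if every valid record
reports 0; the monthly value is then carried forward. Statuses before a man's
first valid record are missing; no other imputation is performed.

Indicators are binary. Multi-level items (online partner acquisition:
none / up to half / more than half) are expanded into one indicator per
retained level, because both the distance's Jaccard term and the subgroup
criteria operate on binary entries. Two composites are derived from raw
codes before binarization: **Chemsex** (any of crystal methamphetamine,
ketamine, GHB/GBL, mephedrone used often or always during sex; 0 when every
*observed* drug item is below that; missing only when all four are missing)
and **negotiated safety** (consistent condom use with non-steady but not
steady partners; missing if either condom item is missing).

### Inclusion rules

Applied in this order (the order matters and is fixed): records on/after a
man's first registered HIV diagnosis are censored; men with fewer than 2
visits are dropped; indicators qualify as *longitudinal* when their valid
records span strictly more than 3 years, their monthly population frequency
strictly exceeds 20% in some month, and they carry strictly more than a
configurable count of valid records (10,000 at full surveillance scale;
scaled to cohort size in the demonstration configs). All three comparisons
are strict ("exceeding").

The *dense period* is the longest contiguous run of months in which the
number of men with any valid status strictly exceeds the median monthly
count (ties broken by earliest start; an all-equal profile is an error). The
count uses carried-forward validity by default — the trajectory, not the
visit log, is the clustering object — with a raw same-month-record mode
available. Because carried-forward validity never expires, the count is
nondecreasing and the dense period is a suffix of the grid; it is
informative only under staggered enrollment, which both the real-world
setting (gradual uptake of person-specific codes) and the generator provide.
Men whose coverage of the dense period (fraction of months with any valid
status) is strictly below the median coverage are excluded; men exactly at
the median are kept. Medians use the midpoint-of-order-statistics convention.

## Distance

d(j,k) = Σ_v ω_v(j,k) · (1 − J_v(j,k)), with J_v the Jaccard similarity of
the two men's active-month sets restricted to months valid for both, and
ω_v(j,k) the pair's shared valid months for v divided by the pair's maximum
shared months over all indicators (pair-specific denominator). Conventions:

- Empty union (neither man active on any shared month): J = 1. Shared
  absence of a behavior is shared behavior; without this convention all
  low-frequency indicators would make everyone maximally distant.
- No shared valid months for v: ω_v = 0 and the Jaccard value is irrelevant
  (defined as 1).
- Pairs sharing no valid month on any indicator receive the maximal distance
  (the number of indicators) with a logged warning, keeping the matrix
  complete for clustering.
- The sum is a dissimilarity, not a metric; the triangle inequality is
  neither asserted nor used.

The implementation is exact (boolean-mask linear algebra, no approximation)
and is tested for exact agreement with an independent brute-force
set-enumeration oracle.

## Clustering and subgroup screening

Agglomerative hierarchical clustering, average linkage by default (the
linkage is configurable; the validation properties are required to hold
under average and complete). Merge order is deterministic: ties resolve by
cluster index over the fixed, sorted man-id leaf order, so reruns and
platforms agree; seeds never influence clustering.

Hierarchy *level* ℓ is the partition into ℓ clusters obtained by cutting the
ℓ−1 highest merges (root = level 1). Scanning levels 1..6 exposes the
children of the five highest merges: exactly 2(L−1) = 10 distinct non-root
candidate clusters on any binary tree — the level convention is chosen
precisely because it makes the candidate count a tree-shape-free constant.

For each candidate and indicator, the within-cluster monthly frequency
series is computed (denominator = members with a valid status), months whose
denominator falls below the first quartile of the denominator sequence
(linear-interpolation quartile) are discarded to avoid small-denominator
jumps, and the criteria are evaluated on the retained months:

1. **Reach**: maximum frequency ≥ 25%.
2. **Hegemonic**: frequency > 75% in ≥ 95% of retained months; or
   **rising**: relative change between the first and last retained months,
   (last − first)/first, ≥ 75% in the indicator's direction of increased STI
   exposure (declines count for indicators whose *decrease* raises
   exposure; indicators with no declared direction are skipped for this
   mode; a rise from an exactly-zero first month counts as rising). An
   absolute-percentage-point mode is available by configuration.

A candidate is a subgroup if some single indicator satisfies criterion 1 and
criterion 2. Nested subgroups are pruned top-down: a subgroup whose nearest
retained-subgroup ancestor among the candidates has an identical criterion-2
mode set (as a set of (indicator, mode) pairs; magnitudes are not compared)
is discarded. No minimum cluster size is imposed, so small cohorts can
surface singleton subgroups; at surveillance scale (thousands of men) the
top-level candidates are large.

Subgroup labels are presentational: letters in size order for subgroups with
no subgroup ancestor, dotted suffixes (D.1) for nested ones.

## Trends

Monthly frequency series (overall and per subgroup) are raw proportions with
95% binomial confidence intervals — Wald by default, matching the symmetric
intervals conventional in surveillance reporting, with Wilson as an option;
months with a zero denominator are kept as undefined points. No smoothing.
The overall series is exactly the member-weighted average of any partition's
cluster series wherever all denominators are positive (tested).

## Early identification

Because subgroup membership is defined from longitudinal data that a new
client does not yet have, one binary member/non-member random forest is
trained per subgroup (subgroups are nested, so a multiclass model would be
ill-posed) on first-visit features: demographics plus the behaviors recorded
at the earliest visit. Features with fewer than a configurable number of
valid first-visit records (2,000 at surveillance scale) are dropped, then
complete cases are kept; categoricals are one-hot encoded in sorted level
order. Accuracy is stratified k-fold cross-validation (5 folds, 500 trees
by default, unlimited depth, fixed per-subgroup seeds derived from the run
seed; 200 trees in the packaged simulation studies for speed). Importances
are impurity-decrease values averaged over fold models, normalized to sum 1,
ties broken by feature name. Subgroups with fewer than 2k members (or
non-members) are skipped with a warning. Reports are plain JSON and
byte-reproducible under a fixed seed.

## Synthetic cohorts

The generator emulates the features of VCT panel data that the pipeline's
rules exist for, with every quantity driven by one root seed through a
counter-based stream per man (enlarging a cohort never changes earlier men):

- **Enrollment**: each man's entry month is uniform over the first
  `entry_spread` fraction of the grid (0.6 in the demonstration cohort).
  Staggered enrollment mirrors the gradual adoption of person-specific
  codes and is what gives the dense-period rule a non-degenerate profile:
  with everyone enrolled from month 0, the carried-forward validity count
  plateaus at n and no month exceeds the median.
- **Visits**: per-man independent Bernoulli per month within the enrollment
  window at rate `mean_visits_per_year/12`, resampled until ≥ 2 visits.
- **Trajectories**: the probability of reporting indicator v at month t is
  logistic(baseline_v + slope_v·t) for the man's subgroup profile
  (softmax-linear across levels for categorical items). Reports are driven
  by a latent per-man-per-item uniform that persists across visits with
  probability `persistence` (default 0.8) and is pushed through the inverse
  CDF of the current month's distribution. This keeps the *marginal*
  frequency at every month exactly equal to the trend model — whatever the
  persistence — while making successive reports autocorrelated, as
  questionnaire items with 12-month recall windows are by construction
  (successive visits literally share most of the recall window).
  `persistence=0` recovers independent per-visit draws; under those, two
  men of the same low-frequency profile are as Jaccard-distant as men of
  different profiles (their sporadic active months rarely overlap), which
  no clustering method can undo — the persistence term is the realism the
  distance relies on.
- **Raw codes**: chemsex is emitted as four per-drug use-frequency columns
  and negotiated safety as two condom-use columns, so the ingest
  derivations are exercised end to end; online partner acquisition is a
  three-level categorical. Item-level missingness masks each report
  independently; a configurable fraction of men receive an HIV diagnosis
  date inside the period to exercise censoring.
- **First-visit features**: subgroup-conditional demographics (normal ages,
  categorical region/origin) from a dedicated substream, plus the behaviors
  actually recorded at the man's earliest visit.

What the generator does *not* emulate: real questionnaire export formats,
center-level heterogeneity, informative (behavior-dependent) visiting or
missingness, within-man demographic drift, and real Swiss geography. Passing
validation therefore shows that the pipeline recovers structure of the kind
it models under honest noise — not that it would recover the structure of
any particular real cohort.

### Study designs used in validation

- **Criteria detection** (cluster size 150): one homogeneous cluster with a
  flat 0.85 indicator (hegemonic), a 0.20→0.40 indicator (+100% relative,
  anchored so the marginal is 0.20 at the first post-enrollment-ramp month)
  and a flat 0.10 indicator (must never be flagged). The hegemonic and
  never-flag checks have overwhelming margins. The rising check does not:
  the pass condition compares two single-month proportions at n = 150, and
  even with fully persistent traits the margin (≈ 7.5 men) is only ≈ 1.1
  binomial SDs (≈ 6.8 men), capping per-seed detection near 86%; measured
  rates fall between 65% and 90% depending on seeds. This ceiling is a
  property of endpoint-based relative change at this cluster size, not of
  the implementation.
- **Three-profile recovery** (n = 300, 30% missingness): each profile is
  high (0.9) on its own pair of six indicators and low (0.1) elsewhere, so
  every pair of profiles differs on four indicators. Four is deliberate:
  with near-static reports and symmetric probabilities, profiles differing
  on only two indicators leave single-discordance men exactly
  likelihood-tied between the groups, bounding any method's ARI near 0.4.
  The pipeline's coverage filter is applied before clustering, as the
  method defines; the 3-cluster cut is compared with truth by adjusted Rand
  index (median ≈ 0.85–0.93 under average and complete linkage).
- **Classifier recovery** (n = 1000): membership signal planted in
  first-visit age (means 2.0 pooled SDs apart) and online-dating rate
  (0.70 vs 0.25); region and the remaining behaviors are noise. The null
  variant uses identically distributed profiles with equal 50/50 shares so
  the majority rate equals chance — with unequal shares, a default-depth
  forest on pure noise converges to p² + q², which sits far *below* the
  majority rate and would make "tracks the majority baseline" untestable.

## Numerical conventions

- Months are half-open calendar months, 0-indexed from the grid start.
- Quartiles/medians: numpy linear interpolation / midpoint conventions.
- Wald intervals clipped to [0, 1]; z from the normal quantile, not 1.96.
- JSON outputs are written with sorted keys and no timestamps; reruns with
  the same configuration and seed are byte-identical (tested).
- Distance matrices are symmetrized exactly ((d + dᵀ)/2) to remove float
  noise before linkage.
- The full per-pair weight tensor is retained on the distance object only
  for cohorts of ≤ 1000 men; `pair_terms` recomputes any single pair's
  audit table at any size.

## Known limitations

- Endpoint-based relative change (criterion 2, rising mode) is noisy at
  small cluster sizes; a regression-slope variant would be more stable but
  would change the method.
- The screening imposes no minimum subgroup size; on small cohorts,
  singleton candidates can satisfy the criteria.
- Average linkage on this dissimilarity tends to peel sparse-data outliers
  at the top levels; the coverage filter mitigates but does not eliminate
  this on small cohorts.
- The distance is not a metric; methods requiring metricity (e.g., certain
  embeddings) should not consume it unchecked.
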