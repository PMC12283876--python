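# behavclust

Discovery of behavioral subgroups in longitudinal sexual-health surveillance
panels, and early identification of their members from first-visit data.

## The problem

Voluntary counseling and testing (VCT) centers collect repeated, anonymous
questionnaire data on the sexual behavior of men who have sex with men (MSM):
condomless anal intercourse with non-steady partners (nsCAI), group sex,
numbers of anal-intercourse partners, online partner acquisition, partnership
status, sexualized drug use. Population-level trend curves average over very
different trajectories: a rise in nsCAI can come from a small subgroup
changing fast while most men do not change at all. This package implements a
pipeline that

1. turns each man's visit records into a monthly-updated **behavioral
   trajectory** (last observation carried forward),
2. measures pairwise trajectory dissimilarity with a
   **comparability-weighted Jaccard distance**,
3. clusters men hierarchically and screens the top levels of the hierarchy
   with **heuristic subgroup criteria** (reach, hegemony, rise), and
4. trains per-subgroup random forests to **identify likely subgroup members
   from their first visit only**.

Because individual-level VCT data cannot be shared, the package ships a
synthetic cohort generator that plants known subgroups, trends, staggered
enrollment and item-level missingness; every stage is validated against that
planted truth.

## The distance

For men $j,k$ and longitudinal binary indicators $v$, monthly statuses
$M^i_{v,\tau} \in \{1, 0, \text{missing}\}$:

$$d(j,k) = \sum_v \omega_v^{j,k}\,\bigl(1 - \mathrm{jaccard}(M^j_{v,\cdot},\, M^k_{v,\cdot})\bigr)$$

where the Jaccard similarity compares the sets of months in which each man is
active (restricted to months observed for both; two men who never report the
behavior are maximally similar), and the weight

$$\omega_v^{j,k} = \frac{\#\{\text{months valid for } v \text{ in both}\}}{\max_{v'} \#\{\text{months valid for } v' \text{ in both}\}}$$

down-weights poorly shared indicators pair by pair. A cluster from the top
six hierarchy levels (ten candidate clusters on any binary tree) is a
**subgroup** if, for some indicator, its within-cluster frequency (a) ever
reaches 25% and (b) either stays above 75% for at least 95% of the retained
months (*hegemonic*) or changes by at least 75% relative toward increased STI
exposure (*rising*); a descendant of a subgroup survives only if its mode set
differs.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py --seed 1 --n-men 300
python analysis/02_prepare_trajectories.py
python analysis/03_compute_distances.py
python analysis/04_screen_subgroups.py
python analysis/05_trend_series.py
python analysis/06_early_identification.py
python analysis/07_validation_studies.py
```

Step 02 selects the indicators dense enough for longitudinal analysis, finds
the dense clustering period and drops men below median coverage:

```
longitudinal indicators: ['nscai', 'group_sex', 'partners_gt5', 'partnership_single',
                          'online_up_to_half', 'online_more_than_half', 'chemsex',
                          'negotiated_safety']
dense period: months 15..28 of the grid (starting 2018-04, 14 months)
coverage filter: 259 of 298 men retained (median coverage 1.00)
```

Step 04 prints the ten candidate clusters of the top six hierarchy levels and
the surviving subgroups with the criterion-2 modes that define them, e.g.

```
10 candidate clusters in the top 6 levels
  level 4 size   76 -> A       [partners_gt5:hegemonic]
  level 5 size   71 -> A.1     [group_sex:hegemonic, partners_gt5:hegemonic]
  ...
final subgroups: ['A', 'A.1', 'A.2', 'B']
```

(size-1 candidates can satisfy the criteria — the screening imposes no
minimum cluster size, so small cohorts surface singleton "subgroups" that a
cohort of thousands would not). Step 06 then asks how well subgroup
membership can be predicted from the first visit alone:

```
subgroup A:   accuracy 0.83 (majority 0.71); top features: age (0.18),
              online_partners_up_to_half (0.15), partners_gt5 (0.14)
subgroup A.1: accuracy 0.85 (majority 0.73); top features: age (0.18), ...
```

and step 07 validates the machinery against planted truth:

```
hegemonic detected in 100% of seeds, rising in 70%, flat-low falsely flagged in 0%
3-profile recovery: median ARI 0.89 (average linkage), 0.89 (complete)
classifier: median accuracy 0.82, informative feature top-1 in 100% of seeds
```

The same pipeline is available as a CLI (`behavclust simulate | build-matrix
| distance | cluster | subgroups | trends | classify | run-all`), each stage
re-runnable from the previous stage's files in a shared workspace.

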