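"""Synthetic behavioral-surveillance cohorts with planted latent subgroups.

Generates visit-level records of the shape produced by anonymous sexual-health
counseling questionnaires: one row per counseling visit, with coded behavioral
items, item-level missingness, and a latent subgroup membership per man that
drives both his behavioral trajectory and his first-visit demographics.

Each man's trajectory follows a logistic-linear model: the probability of
reporting indicator ``v`` at month ``t`` is ``expit(baseline + slope * t)``
for his subgroup's profile. Chemsex and negotiated safety are emitted as raw
coded items (per-drug use frequencies, condom-use codes) so that the ingest
derivations are exercised end to end; online partner acquisition is emitted
as a three-level categorical.

All randomness flows from a single root seed through one counter-based stream
per man (``default_rng([seed, man_index, purpose])``), so enlarging the
cohort never perturbs the records of earlier men.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ingest import (
    CHEMSEX_DRUG_ITEMS,
    CONDOM_NONSTEADY_ITEM,
    CONDOM_STEADY_ITEM,
    CONSISTENT_CODE,
    FREQUENCY_CODES,
    derive_chemsex,
    derive_negotiated_safety,
)

__all__ = [
    "BinaryTrend",
    "CategoricalTrend",
    "Normal",
    "Categorical",
    "SubgroupProfile",
    "CohortSpec",
    "generate_cohort",
    "generate_first_visit_features",
    "demo_cohort_spec",
    "planted_recovery_spec",
    "classifier_cohort_spec",
    "criteria_cluster_spec",
]

#: items encoded as raw codes rather than 0/1 columns
RAW_ENCODED_ITEMS = ("chemsex", "negotiated_safety")

_BELOW_THRESHOLD_CODES = ("never", "rarely", "sometimes")
_AT_THRESHOLD_CODES = ("often", "always")


@dataclass(frozen=True)
class BinaryTrend:
    """Logistic-linear trajectory for a binary item: p(t) = expit(b + s*t)."""

    baseline_logit: float
    slope_logit: float = 0.0

    def prob(self, t: int | np.ndarray) -> float | np.ndarray:
        x = self.baseline_logit + self.slope_logit * np.asarray(t, dtype=float)
        return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CategoricalTrend:
    """Softmax-linear trajectory over levels: p_l(t) ∝ exp(b_l + s_l*t)."""

    levels: Mapping[str, tuple[float, float]]

    def probs(self, t: int) -> dict[str, float]:
        logits = {lv: b + s * t for lv, (b, s) in self.levels.items()}
        m = max(logits.values())
        w = {lv: math.exp(x - m) for lv, x in logits.items()}
        z = sum(w.values())
        return {lv: x / z for lv, x in w.items()}


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float


@dataclass(frozen=True)
class Categorical:
    weights: Mapping[str, float]


@dataclass(frozen=True)
class SubgroupProfile:
    """One latent subgroup: its share of the cohort, per-item trajectory
    models, and the distributions of its first-visit demographic features."""

    label: str
    proportion: float
    items: Mapping[str, BinaryTrend | CategoricalTrend]
    demographics: Mapping[str, Normal | Categorical] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``period_start``/``period_end`` are calendar months ("YYYY-MM") bounding a
    half-open month interval; ``item_missingness`` is either one probability
    applied to every item or a per-item mapping; ``hiv_diagnosis_rate`` is the
    fraction of men who acquire a registered HIV diagnosis at a uniform month
    inside the period (exercises pre-diagnosis censoring downstream).
    """

    n_men: int
    period_start: str
    period_end: str
    mean_visits_per_year: float
    item_missingness: float | Mapping[str, float]
    subgroup_profiles: tuple[SubgroupProfile, ...]
    seed: int
    hiv_diagnosis_rate: float = 0.0
    #: staggered enrollment: each man's entry month is uniform over the first
    #: ``entry_spread`` fraction of the grid (0 = everyone observed from the
    #: start). Gradual uptake of person-specific codes is what makes the
    #: downstream dense-period rule informative.
    entry_spread: float = 0.0
    #: within-person report persistence: at each visit the latent uniform
    #: driving an item's report is carried over from the previous visit with
    #: this probability and redrawn otherwise. The item value is the inverse-
    #: CDF transform of that uniform, so the *marginal* frequency at month t
    #: is exactly logistic(baseline + slope*t) for any persistence, while
    #: successive reports are autocorrelated — as questionnaire items with a
    #: 12-month recall window are. 0 recovers independent per-visit draws.
    persistence: float = 0.8

    def validate(self) -> None:
        if self.n_men <= 0:
            raise ValueError("n_men must be a positive integer")
        if self.mean_visits_per_year <= 0:
            raise ValueError("mean_visits_per_year must be positive")
        total = sum(p.proportion for p in self.subgroup_profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"subgroup proportions must sum to 1 (got {total!r})"
            )
        if self.n_months < 12:
            raise ValueError("period must span at least 12 months")
        for prob in self._missingness_map().values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("item_missingness probabilities must be in [0, 1]")
        if not 0.0 <= self.hiv_diagnosis_rate <= 1.0:
            raise ValueError("hiv_diagnosis_rate must be in [0, 1]")
        if not 0.0 <= self.entry_spread < 1.0:
            raise ValueError("entry_spread must be in [0, 1)")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        labels = [p.label for p in self.subgroup_profiles]
        if len(set(labels)) != len(labels):
            raise ValueError("subgroup labels must be unique")
        first_items = list(self.subgroup_profiles[0].items)
        for p in self.subgroup_profiles[1:]:
            if list(p.items) != first_items:
                raise ValueError("all profiles must define the same items")

    @property
    def start_period(self) -> pd.Period:
        return pd.Period(self.period_start, freq="M")

    @property
    def n_months(self) -> int:
        return (pd.Period(self.period_end, freq="M") - self.start_period).n

    @property
    def item_names(self) -> list[str]:
        return list(self.subgroup_profiles[0].items)

    def _missingness_map(self) -> dict[str, float]:
        if isinstance(self.item_missingness, Mapping):
            return {v: float(self.item_missingness.get(v, 0.0)) for v in self.item_names}
        return {v: float(self.item_missingness) for v in self.item_names}


def _man_rng(seed: int, man_index: int, purpose: int = 0) -> np.random.Generator:
    # counter-based stream: adding men never disturbs earlier men
    return np.random.default_rng([seed, man_index, purpose])


def _assign_subgroup(spec: CohortSpec, rng: np.random.Generator) -> SubgroupProfile:
    u = rng.random()
    acc = 0.0
    for prof in spec.subgroup_profiles:
        acc += prof.proportion
        if u < acc:
            return prof
    return spec.subgroup_profiles[-1]


def _visit_months(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-man homogeneous monthly Bernoulli visit process within the man's
    enrollment window, resampled until it yields >=2 visits."""
    T = spec.n_months
    entry = 0
    if spec.entry_spread > 0:
        entry = int(rng.integers(0, max(int(spec.entry_spread * (T - 3)), 0) + 1))
    p = min(spec.mean_visits_per_year / 12.0, 1.0)
    window = T - entry
    for _ in range(1000):
        mask = rng.random(window) < p
        if mask.sum() >= 2:
            return entry + np.flatnonzero(mask)
    # pathological rates only: force two distinct months
    return entry + np.sort(rng.choice(window, size=2, replace=False))


def _emit_chemsex(row: dict, value: float, rng: np.random.Generator) -> None:
    if np.isnan(value):
        for d in CHEMSEX_DRUG_ITEMS:
            row[d] = np.nan
        return
    codes = {d: rng.choice(_BELOW_THRESHOLD_CODES) for d in CHEMSEX_DRUG_ITEMS}
    if value == 1:
        hot = CHEMSEX_DRUG_ITEMS[rng.integers(len(CHEMSEX_DRUG_ITEMS))]
        codes[hot] = rng.choice(_AT_THRESHOLD_CODES)
    row.update(codes)


def _emit_negotiated_safety(row: dict, value: float, rng: np.random.Generator) -> None:
    if np.isnan(value):
        row[CONDOM_NONSTEADY_ITEM] = np.nan
        row[CONDOM_STEADY_ITEM] = np.nan
        return
    if value == 1:
        row[CONDOM_NONSTEADY_ITEM] = CONSISTENT_CODE
        row[CONDOM_STEADY_ITEM] = rng.choice(_BELOW_THRESHOLD_CODES)
    elif rng.random() < 0.5:
        # inconsistent with non-steady partners
        row[CONDOM_NONSTEADY_ITEM] = rng.choice(_BELOW_THRESHOLD_CODES)
        row[CONDOM_STEADY_ITEM] = rng.choice(FREQUENCY_CODES)
    else:
        # consistent with both kinds of partner
        row[CONDOM_NONSTEADY_ITEM] = CONSISTENT_CODE
        row[CONDOM_STEADY_ITEM] = CONSISTENT_CODE


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate the visit table and the ground-truth subgroup labels.

    Returns
    -------
    visits : DataFrame
        One row per visit: ``man_id``, ``visit_date`` (ISO-8601), optional
        ``hiv_diagnosis_date``, plus one column per coded item. Missing
        entries are NaN (empty cells on disk).
    truth : Series
        Subgroup label per ``man_id``.
    """
    spec.validate()
    start = spec.start_period
    rows: list[dict] = []
    truth: dict[str, str] = {}
    for i in range(spec.n_men):
        man_id = f"m{i:05d}"
        rng = _man_rng(spec.seed, i)
        prof = _assign_subgroup(spec, rng)
        truth[man_id] = prof.label
        months = _visit_months(spec, rng)
        diag_date = None
        if spec.hiv_diagnosis_rate and rng.random() < spec.hiv_diagnosis_rate:
            dm = int(rng.integers(spec.n_months))
            diag_date = (start + dm).to_timestamp().replace(
                day=int(rng.integers(1, 29))
            )
        miss = spec._missingness_map()
        latent: dict[str, float] = {}
        for t in months:
            period = start + int(t)
            day = int(rng.integers(1, 29))
            row: dict = {
                "man_id": man_id,
                "visit_date": period.to_timestamp().replace(day=day).date().isoformat(),
            }
            if diag_date is not None:
                row["hiv_diagnosis_date"] = diag_date.date().isoformat()
            for name, model in prof.items.items():
                # persistent latent uniform; value = inverse-CDF at month t,
                # so marginals follow the trend model exactly at every month
                u = latent.get(name)
                if u is None or rng.random() >= spec.persistence:
                    u = rng.random()
                latent[name] = u
                if isinstance(model, BinaryTrend):
                    value: float | str = float(u < model.prob(int(t)))
                else:
                    probs = model.probs(int(t))
                    acc = 0.0
                    value = list(probs)[-1]
                    for lv, p_lv in probs.items():
                        acc += p_lv
                        if u < acc:
                            value = lv
                            break
                if rng.random() < miss[name]:
                    value = np.nan
                if name == "chemsex":
                    _emit_chemsex(row, value if isinstance(value, float) else np.nan, rng)
                elif name == "negotiated_safety":
                    _emit_negotiated_safety(
                        row, value if isinstance(value, float) else np.nan, rng
                    )
                else:
                    row[name] = value
            rows.append(row)
    visits = pd.DataFrame(rows)
    if "hiv_diagnosis_date" not in visits.columns:
        visits["hiv_diagnosis_date"] = np.nan
    truth_s = pd.Series(truth, name="subgroup")
    truth_s.index.name = "man_id"
    return visits, truth_s


def generate_first_visit_features(
    spec: CohortSpec, truth: pd.Series, visits: pd.DataFrame
) -> pd.DataFrame:
    """One row per man: subgroup-conditional demographics plus the behavioral
    items actually recorded at his first visit.

    Demographic features are drawn from the man's subgroup profile using a
    dedicated substream; behavioral features are copied from the earliest
    visit row (chemsex and negotiated safety re-derived from their raw codes),
    so classifier inputs never peek beyond the first visit. Feature-level
    missingness follows ``spec.item_missingness`` for behavioral items only —
    demographics are complete unless a per-feature rate is given.
    """
    spec.validate()
    known = {p.label: p for p in spec.subgroup_profiles}
    first = (
        visits.sort_values(["man_id", "visit_date"], kind="mergesort")
        .groupby("man_id", sort=True)
        .first()
    )
    missing_ids = set(first.index) - set(truth.index)
    if missing_ids:
        raise ValueError(f"truth labels missing for men: {sorted(missing_ids)[:5]}")
    rows = []
    for man_id, label in truth.sort_index().items():
        if label not in known:
            raise ValueError(f"unknown subgroup label {label!r}")
        prof = known[label]
        i = int(str(man_id).lstrip("m"))
        rng = _man_rng(spec.seed, i, purpose=1)
        row: dict = {"man_id": man_id}
        for feat, dist in prof.demographics.items():
            if isinstance(dist, Normal):
                row[feat] = float(rng.normal(dist.mean, dist.sd))
            else:
                lv = list(dist.weights)
                w = np.array([dist.weights[x] for x in lv], dtype=float)
                row[feat] = lv[int(rng.choice(len(lv), p=w / w.sum()))]
        if man_id in first.index:
            rec = first.loc[man_id]
            for name in spec.item_names:
                if name == "chemsex":
                    row[name] = derive_chemsex(rec)
                elif name == "negotiated_safety":
                    row[name] = derive_negotiated_safety(rec)
                else:
                    row[name] = rec[name]
        rows.append(row)
    return pd.DataFrame(rows)


def demo_cohort_spec(
    n_men: int = 300,
    seed: int = 0,
    period_start: str = "2017-01",
    period_end: str = "2019-06",
    mean_visits_per_year: float = 4.0,
    item_missingness: float = 0.1,
    hiv_diagnosis_rate: float = 0.02,
    entry_spread: float = 0.6,
) -> CohortSpec:
    """A four-subgroup cohort echoing the qualitative phenomenology of
    behavioral-surveillance data: one subgroup with hegemonic high-exposure
    behavior, one with hegemonic online dating, one with rising condomless
    intercourse, and a large low-activity subgroup taking up online dating."""

    def online(none, up, more, s_none=0.0, s_up=0.0, s_more=0.0):
        return CategoricalTrend(
            {"none": (none, s_none), "up_to_half": (up, s_up), "more_than_half": (more, s_more)}
        )

    profiles = (
        SubgroupProfile(
            label="high_exposure",
            proportion=0.15,
            items={
                "nscai": BinaryTrend(2.0, 0.0),       # hegemonic ~0.88
                "group_sex": BinaryTrend(1.5, 0.01),
                "partners_gt5": BinaryTrend(2.0, 0.0),
                "partnership_single": BinaryTrend(1.0, 0.0),
                "online_partners": online(-1.5, 1.0, -0.5),
                "chemsex": BinaryTrend(-0.5, 0.02),
                "negotiated_safety": BinaryTrend(-2.0, 0.0),
            },
            demographics={
                "age": Normal(37.0, 9.0),
                "region": Categorical({"geneva": 0.7, "zurich": 0.1, "other": 0.2}),
                "origin": Categorical({"ch": 0.67, "neighbor": 0.13, "other": 0.2}),
            },
        ),
        SubgroupProfile(
            label="online_hegemonic",
            proportion=0.2,
            items={
                "nscai": BinaryTrend(-0.5, 0.0),
                "group_sex": BinaryTrend(-0.3, -0.03),
                "partners_gt5": BinaryTrend(0.5, -0.03),
                "partnership_single": BinaryTrend(0.5, 0.0),
                "online_partners": online(-3.0, -1.0, 2.0),  # >80% more_than_half
                "chemsex": BinaryTrend(-2.0, 0.0),
                "negotiated_safety": BinaryTrend(-1.0, 0.0),
            },
            demographics={
                "age": Normal(34.0, 8.0),
                "region": Categorical({"geneva": 0.5, "zurich": 0.25, "other": 0.25}),
                "origin": Categorical({"ch": 0.66, "neighbor": 0.15, "other": 0.19}),
            },
        ),
        SubgroupProfile(
            label="rising_nscai",
            proportion=0.25,
            items={
                "nscai": BinaryTrend(-1.6, 0.06),     # ~0.17 -> ~0.55 over 30 months
                "group_sex": BinaryTrend(0.3, 0.01),
                "partners_gt5": BinaryTrend(0.8, 0.0),
                "partnership_single": BinaryTrend(0.8, 0.0),
                "online_partners": online(-1.0, 0.5, 0.5),
                "chemsex": BinaryTrend(-1.5, 0.0),
                "negotiated_safety": BinaryTrend(-1.5, 0.0),
            },
            demographics={
                "age": Normal(34.0, 8.5),
                "region": Categorical({"geneva": 0.45, "zurich": 0.25, "other": 0.3}),
                "origin": Categorical({"ch": 0.65, "neighbor": 0.15, "other": 0.2}),
            },
        ),
        SubgroupProfile(
            label="low_activity",
            proportion=0.4,
            items={
                "nscai": BinaryTrend(-2.0, 0.0),
                "group_sex": BinaryTrend(-1.5, 0.0),
                "partners_gt5": BinaryTrend(-1.5, 0.01),
                "partnership_single": BinaryTrend(0.2, 0.0),
                "online_partners": online(1.0, -1.0, -2.0, s_up=0.06),
                "chemsex": BinaryTrend(-3.0, 0.0),
                "negotiated_safety": BinaryTrend(-0.5, 0.0),
            },
            demographics={
                "age": Normal(35.0, 10.0),
                "region": Categorical({"geneva": 0.5, "zurich": 0.18, "other": 0.32}),
                "origin": Categorical({"ch": 0.69, "neighbor": 0.14, "other": 0.17}),
            },
        ),
    )
    return CohortSpec(
        n_men=n_men,
        period_start=period_start,
        period_end=period_end,
        mean_visits_per_year=mean_visits_per_year,
        item_missingness=item_missingness,
        subgroup_profiles=profiles,
        seed=seed,
        hiv_diagnosis_rate=hiv_diagnosis_rate,
        entry_spread=entry_spread,
    )


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def planted_recovery_spec(
    seed: int,
    n_men: int = 300,
    item_missingness: float = 0.3,
    hi: float = 0.9,
    lo: float = 0.1,
) -> CohortSpec:
    """Three equal subgroups on six flat indicators, each subgroup high
    (``hi``) on its own signature pair and low (``lo``) elsewhere.

    Every pair of subgroups is separated by ``hi - lo`` on four indicators —
    comfortably past the well-separated regime (difference >= 0.5 on >= 2
    indicators). Four differing indicators matter: with near-static reports
    and symmetric activity probabilities, two groups differing on only two
    indicators leave the single-discordance patterns exactly likelihood-tied,
    which caps any clustering method's agreement with the truth.
    """
    def prof(label: str, hot: set[int]) -> SubgroupProfile:
        return SubgroupProfile(
            label,
            1 / 3,
            {f"v{i}": BinaryTrend(_logit(hi if i in hot else lo)) for i in range(6)},
        )

    return CohortSpec(
        n_men=n_men,
        period_start="2017-01",
        period_end="2019-01",
        mean_visits_per_year=4.0,
        item_missingness=item_missingness,
        subgroup_profiles=(
            prof("g1", {0, 1}), prof("g2", {2, 3}), prof("g3", {4, 5})
        ),
        seed=seed,
    )


def criteria_cluster_spec(seed: int, n_men: int = 150) -> CohortSpec:
    """A single homogeneous cluster carrying one hegemonic indicator (flat
    0.85), one rising indicator (0.20 -> 0.40, +100% relative) and one flat
    low indicator (0.10) that must never be flagged.

    The rising trend is anchored so the marginal frequency is 0.20 at month
    6 and 0.40 at the final month: at ~4 visits/year the first months of the
    grid are an enrollment ramp that the small-denominator discard removes,
    so the series the screening actually evaluates is the planted
    0.20 -> 0.40 rise.
    """
    T = 36
    anchor = 6
    rising_slope = (_logit(0.40) - _logit(0.20)) / (T - 1 - anchor)
    items = {
        "hegemonic": BinaryTrend(_logit(0.85)),
        "rising": BinaryTrend(_logit(0.20) - anchor * rising_slope, rising_slope),
        "flat_low": BinaryTrend(_logit(0.10)),
    }
    return CohortSpec(
        n_men=n_men,
        period_start="2016-07",
        period_end="2019-07",
        mean_visits_per_year=4.0,
        item_missingness=0.1,
        subgroup_profiles=(SubgroupProfile("only", 1.0, items),),
        seed=seed,
    )


def classifier_cohort_spec(
    seed: int, n_men: int = 1000, signal: bool = True
) -> CohortSpec:
    """Two equal subgroups for early-identification experiments.

    With ``signal=True`` the subgroups differ in first-visit age (means 2.0
    pooled SDs apart) and online-dating rate; with ``signal=False`` the two
    profiles are identically distributed and of equal size, so the majority
    rate equals chance and a classifier on featureless labels can only track
    it. Behavioral trajectories are identical in both cases — the signal
    lives purely in the first-visit features.
    """
    def prof(label: str, prop: float, age_mean: float, online_p: float) -> SubgroupProfile:
        return SubgroupProfile(
            label,
            prop,
            {
                "online_dating": BinaryTrend(_logit(online_p)),
                "group_sex": BinaryTrend(_logit(0.3)),
                "nscai": BinaryTrend(_logit(0.3)),
            },
            demographics={
                "age": Normal(age_mean, 5.0),
                "region": Categorical({"geneva": 0.5, "zurich": 0.25, "other": 0.25}),
            },
        )

    if signal:
        profiles = (prof("member", 0.4, 40.0, 0.7), prof("rest", 0.6, 30.0, 0.25))
    else:
        profiles = (prof("member", 0.5, 36.0, 0.4), prof("rest", 0.5, 36.0, 0.4))
    return CohortSpec(
        n_men=n_men,
        period_start="2017-01",
        period_end="2019-01",
        mean_visits_per_year=4.0,
        item_missingness=0.0,
        subgroup_profiles=profiles,
        seed=seed,
    )
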