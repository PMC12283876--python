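"""Visit-table ingestion: composite variables, record-level inclusion rules,
and selection of the longitudinal indicators.

The input shape is a long-format table with one row per counseling visit:
``man_id``, ``visit_date`` (ISO-8601), an optional ``hiv_diagnosis_date``, and
one column per coded item. Missing values are empty cells (NaN once parsed).

Two composite behaviors are derived from raw codes:

* **Chemsex** — any of crystal methamphetamine, ketamine, GHB/GBL or
  mephedrone used *often* or *always* during sex.
* **Negotiated safety** — consistent condom use with non-steady partners but
  not with steady partners.

Multi-level items (partner acquisition online) are expanded into one binary
indicator per retained level, because the trajectory distance and the
subgroup criteria operate on binary indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FREQUENCY_CODES",
    "CHEMSEX_DRUG_ITEMS",
    "CONDOM_STEADY_ITEM",
    "CONDOM_NONSTEADY_ITEM",
    "CONSISTENT_CODE",
    "IndicatorSpec",
    "default_indicator_specs",
    "derive_chemsex",
    "derive_negotiated_safety",
    "add_derived_items",
    "binarize",
    "censor_post_hiv",
    "filter_min_visits",
    "select_longitudinal_variables",
    "read_visits",
    "write_visits",
]

#: ordered use-frequency scale for sexualized drug use and condom use
FREQUENCY_CODES = ("never", "rarely", "sometimes", "often", "always")
_FREQ_RANK = {c: i for i, c in enumerate(FREQUENCY_CODES)}
_CHEMSEX_THRESHOLD = _FREQ_RANK["often"]

CHEMSEX_DRUG_ITEMS = ("drug_meth", "drug_ketamine", "drug_ghb_gbl", "drug_mephedrone")
CONDOM_STEADY_ITEM = "condom_steady"
CONDOM_NONSTEADY_ITEM = "condom_nonsteady"
#: code meaning consistent condom use
CONSISTENT_CODE = "always"


@dataclass(frozen=True)
class IndicatorSpec:
    """A binary longitudinal indicator derived from one source item.

    ``positive_levels`` lists the coded levels mapping to 1 (for a binary 0/1
    source item, the level is the float 1.0). ``exposure_direction`` states
    which direction of change increases STI exposure: "increase", "decrease"
    or "none" (the rising-mode subgroup criterion skips "none").
    """

    name: str
    source_item: str
    positive_levels: tuple = (1.0,)
    exposure_direction: str = "none"

    def __post_init__(self):
        if self.exposure_direction not in ("increase", "decrease", "none"):
            raise ValueError(f"bad exposure_direction {self.exposure_direction!r}")


def default_indicator_specs() -> list[IndicatorSpec]:
    """Default indicator set: per-level expansion of the online-partner item,
    the raw binary behaviors, and the two derived composites."""
    return [
        IndicatorSpec("nscai", "nscai", (1.0,), "increase"),
        IndicatorSpec("group_sex", "group_sex", (1.0,), "increase"),
        IndicatorSpec("partners_gt5", "partners_gt5", (1.0,), "increase"),
        IndicatorSpec("partnership_single", "partnership_single", (1.0,), "none"),
        IndicatorSpec(
            "online_up_to_half", "online_partners", ("up_to_half",), "increase"
        ),
        IndicatorSpec(
            "online_more_than_half", "online_partners", ("more_than_half",), "increase"
        ),
        IndicatorSpec("chemsex", "chemsex", (1.0,), "increase"),
        IndicatorSpec("negotiated_safety", "negotiated_safety", (1.0,), "none"),
    ]


def _freq_rank(value, item: str) -> float:
    """Rank on the use-frequency scale; NaN for missing; error on bad codes."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        return float(_FREQ_RANK[value])
    except KeyError:
        raise ValueError(f"unknown frequency code {value!r} for item {item!r}") from None


def derive_chemsex(record: Mapping) -> float:
    """1 if any chemsex drug is used often/always; 0 if every *observed* drug
    is below that; missing only when all four drug items are missing."""
    ranks = [_freq_rank(record.get(d, np.nan), d) for d in CHEMSEX_DRUG_ITEMS]
    arr = np.array(ranks, dtype=float)
    if np.all(np.isnan(arr)):
        return np.nan
    return float(np.nanmax(arr) >= _CHEMSEX_THRESHOLD)


def derive_negotiated_safety(record: Mapping) -> float:
    """1 iff condom use is consistent with non-steady partners and not
    consistent with steady partners; missing if either item is missing."""
    ns = record.get(CONDOM_NONSTEADY_ITEM, np.nan)
    st = record.get(CONDOM_STEADY_ITEM, np.nan)
    ns_r = _freq_rank(ns, CONDOM_NONSTEADY_ITEM)
    st_r = _freq_rank(st, CONDOM_STEADY_ITEM)
    if np.isnan(ns_r) or np.isnan(st_r):
        return np.nan
    return float(ns == CONSISTENT_CODE and st != CONSISTENT_CODE)


def add_derived_items(visits: pd.DataFrame) -> pd.DataFrame:
    """Append ``chemsex`` and ``negotiated_safety`` columns derived from the
    raw drug- and condom-use codes (vectorized; codes validated)."""
    out = visits.copy()

    drug_cols = [c for c in CHEMSEX_DRUG_ITEMS if c in out.columns]
    if drug_cols:
        ranks = pd.DataFrame(index=out.index)
        for c in drug_cols:
            bad = out[c].dropna().loc[lambda s: ~s.isin(FREQUENCY_CODES)]
            if len(bad):
                raise ValueError(
                    f"unknown frequency code {bad.iloc[0]!r} for item {c!r}"
                )
            ranks[c] = out[c].map(_FREQ_RANK)
        any_high = (ranks >= _CHEMSEX_THRESHOLD).any(axis=1)
        all_missing = ranks.isna().all(axis=1)
        out["chemsex"] = any_high.astype(float).mask(all_missing)

    if CONDOM_NONSTEADY_ITEM in out.columns and CONDOM_STEADY_ITEM in out.columns:
        for c in (CONDOM_NONSTEADY_ITEM, CONDOM_STEADY_ITEM):
            bad = out[c].dropna().loc[lambda s: ~s.isin(FREQUENCY_CODES)]
            if len(bad):
                raise ValueError(
                    f"unknown frequency code {bad.iloc[0]!r} for item {c!r}"
                )
        ns = out[CONDOM_NONSTEADY_ITEM]
        st = out[CONDOM_STEADY_ITEM]
        val = ((ns == CONSISTENT_CODE) & (st != CONSISTENT_CODE)).astype(float)
        out["negotiated_safety"] = val.mask(ns.isna() | st.isna())
    return out


def binarize(visits: pd.DataFrame, specs: Iterable[IndicatorSpec]) -> pd.DataFrame:
    """Project the visit table onto binary indicator columns.

    Returns ``man_id``, ``visit_date`` (+ ``hiv_diagnosis_date`` if present)
    and one 1/0/NaN column per indicator. Observed codes outside
    ``positive_levels`` map to 0; missing source values stay missing — the
    projection never invents values.
    """
    keep = ["man_id", "visit_date"]
    if "hiv_diagnosis_date" in visits.columns:
        keep.append("hiv_diagnosis_date")
    out = visits[keep].copy()
    for spec in specs:
        if spec.source_item not in visits.columns:
            raise KeyError(f"source item {spec.source_item!r} not in visit table")
        src = visits[spec.source_item]
        out[spec.name] = src.isin(spec.positive_levels).astype(float).mask(src.isna())
    return out


def censor_post_hiv(visits: pd.DataFrame) -> pd.DataFrame:
    """Drop every record dated on/after a man's first registered HIV
    diagnosis; men without a diagnosis are untouched."""
    if "hiv_diagnosis_date" not in visits.columns or visits["hiv_diagnosis_date"].isna().all():
        return visits.copy()
    diag = pd.to_datetime(visits["hiv_diagnosis_date"])  # raises on bad dates
    first_diag = diag.groupby(visits["man_id"]).min()
    vdate = pd.to_datetime(visits["visit_date"])
    cutoff = visits["man_id"].map(first_diag)
    keep = cutoff.isna() | (vdate < cutoff)
    return visits.loc[keep].copy()


def filter_min_visits(visits: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Retain only men with at least ``k`` visit records."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = visits.groupby("man_id")["visit_date"].transform("size")
    return visits.loc[counts >= k].copy()


def select_longitudinal_variables(
    binarized: pd.DataFrame,
    specs: Iterable[IndicatorSpec],
    min_span_years: float = 3.0,
    min_peak_freq: float = 0.20,
    min_valid: int = 10_000,
) -> list[IndicatorSpec]:
    """Keep indicators dense enough for longitudinal analysis.

    An indicator qualifies when its valid records (a) span strictly more than
    ``min_span_years`` years, (b) reach a population frequency strictly above
    ``min_peak_freq`` in at least one calendar month, and (c) number strictly
    more than ``min_valid``. All comparisons are strict ("exceeding").
    Input order is preserved.
    """
    dates = pd.to_datetime(binarized["visit_date"])
    month = dates.dt.to_period("M")
    selected: list[IndicatorSpec] = []
    for spec in specs:
        col = binarized[spec.name]
        valid = col.notna()
        n_valid = int(valid.sum())
        if n_valid <= min_valid:
            continue
        span_days = (dates[valid].max() - dates[valid].min()).days
        if span_days / 365.25 <= min_span_years:
            continue
        monthly = col[valid].groupby(month[valid]).mean()
        if not (monthly > min_peak_freq).any():
            continue
        selected.append(spec)
    if not selected:
        raise ValueError(
            "no indicator meets the density thresholds; review min_span_years/"
            "min_peak_freq/min_valid against the data"
        )
    return selected


def read_visits(path) -> pd.DataFrame:
    """Read a visit table from comma-separated text (empty cell = missing)."""
    return pd.read_csv(path)


def write_visits(visits: pd.DataFrame, path) -> None:
    visits.to_csv(path, index=False)
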