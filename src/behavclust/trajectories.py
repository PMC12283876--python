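"""Monthly behavioral-status matrices and the data-density inclusion rules.

A man's *behavioral status* at month ``t`` is his latest self-reported value
for each longitudinal indicator at or before ``t`` (last observation carried
forward on a monthly grid). The *dense period* is the longest contiguous run
of months in which the number of men with any valid status strictly exceeds
the median monthly count; the *coverage filter* then drops men observed for
less than the median fraction of that period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StatusMatrix",
    "build_status_matrix",
    "monthly_valid_counts",
    "find_dense_period",
    "coverage_filter",
]

MISSING = np.nan


@dataclass
class StatusMatrix:
    """Tri-state man x indicator x month grid (1 active, 0 inactive, NaN
    missing) on a contiguous half-open month interval starting at ``start``."""

    values: np.ndarray  # (n_men, n_indicators, n_months) float, NaN = missing
    men: list[str]
    indicators: list[str]
    start: pd.Period

    def __post_init__(self):
        n, v, t = self.values.shape
        assert n == len(self.men) and v == len(self.indicators)

    @property
    def n_months(self) -> int:
        return self.values.shape[2]

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=self.n_months, freq="M")

    def indicator_index(self, name: str) -> int:
        try:
            return self.indicators.index(name)
        except ValueError:
            raise KeyError(f"unknown indicator {name!r}") from None

    def restrict(self, period: tuple[int, int]) -> "StatusMatrix":
        """Slice to the half-open month-index interval [lo, hi)."""
        lo, hi = period
        if not (0 <= lo < hi <= self.n_months):
            raise ValueError(f"period {period} outside grid of {self.n_months} months")
        return StatusMatrix(
            self.values[:, :, lo:hi], list(self.men), list(self.indicators), self.start + lo
        )

    def subset_men(self, keep: list[str]) -> "StatusMatrix":
        idx = [self.men.index(m) for m in keep]
        return StatusMatrix(self.values[idx], list(keep), list(self.indicators), self.start)

    def to_long_frame(self) -> pd.DataFrame:
        n, v, t = self.values.shape
        men = np.repeat(self.men, v * t)
        ind = np.tile(np.repeat(self.indicators, t), n)
        month = np.tile(np.arange(t), n * v)
        return pd.DataFrame(
            {"man_id": men, "indicator": ind, "month_index": month,
             "value": self.values.ravel()}
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, start: str | pd.Period) -> "StatusMatrix":
        men = sorted(df["man_id"].unique())
        indicators = list(pd.unique(df["indicator"]))
        t = int(df["month_index"].max()) + 1
        values = np.full((len(men), len(indicators), t), np.nan)
        mi = {m: i for i, m in enumerate(men)}
        vi = {v: i for i, v in enumerate(indicators)}
        values[
            df["man_id"].map(mi), df["indicator"].map(vi), df["month_index"]
        ] = df["value"]
        return cls(values, men, indicators, pd.Period(start, freq="M"))


def build_status_matrix(
    binarized: pd.DataFrame,
    indicators: list[str],
    start: str | pd.Period,
    end: str | pd.Period,
) -> StatusMatrix:
    """Build the LOCF status matrix on the half-open month grid [start, end).

    Within a calendar month, an indicator is 1 if *any* valid record that
    month reports it (a behavior reported at any point in a month sets the
    month), 0 if all valid records report 0; across months the latest
    non-missing monthly value is carried forward. Entries before a man's
    first valid record stay missing. Visits outside the grid raise.
    """
    start = pd.Period(start, freq="M")
    end = pd.Period(end, freq="M")
    n_months = (end - start).n
    if n_months <= 0:
        raise ValueError("empty month grid")
    men = sorted(binarized["man_id"].unique())
    mi = {m: i for i, m in enumerate(men)}
    month_idx = (pd.to_datetime(binarized["visit_date"]).dt.to_period("M") - start).map(
        lambda off: off.n
    )
    if (month_idx < 0).any() or (month_idx >= n_months).any():
        bad = binarized.loc[(month_idx < 0) | (month_idx >= n_months), "visit_date"].iloc[0]
        raise ValueError(f"visit dated {bad} falls outside the month grid")

    values = np.full((len(men), len(indicators), n_months), np.nan)
    rows = binarized["man_id"].map(mi).to_numpy()
    cols = month_idx.to_numpy()
    for v, name in enumerate(indicators):
        col = binarized[name].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        # any active report sets the month; otherwise observed-inactive
        # (fmax: a valid 0 must overwrite the NaN initialization)
        np.fmax.at(values[:, v, :], (rows[ok], cols[ok]), col[ok])
    # carry forward across months
    flat = values.reshape(-1, n_months)
    filled = pd.DataFrame(flat).ffill(axis=1).to_numpy()
    return StatusMatrix(filled.reshape(values.shape), men, list(indicators), start)


def monthly_valid_counts(
    matrix: StatusMatrix,
    mode: str = "carried",
    binarized: pd.DataFrame | None = None,
) -> np.ndarray:
    """c(t) = number of men with >=1 valid entry across indicators at month t.

    ``mode="carried"`` (default) counts carried-forward statuses — the object
    actually clustered; ``mode="raw"`` counts men with a same-month visit
    record carrying any valid indicator value (requires ``binarized``).
    """
    if mode == "carried":
        return (~np.isnan(matrix.values)).any(axis=1).sum(axis=0).astype(int)
    if mode != "raw":
        raise ValueError("mode must be 'carried' or 'raw'")
    if binarized is None:
        raise ValueError("raw mode needs the binarized visit table")
    month_idx = (
        pd.to_datetime(binarized["visit_date"]).dt.to_period("M") - matrix.start
    ).map(lambda off: off.n)
    valid = binarized[matrix.indicators].notna().any(axis=1)
    counts = np.zeros(matrix.n_months, dtype=int)
    sub = pd.DataFrame({"man_id": binarized["man_id"], "m": month_idx})[valid]
    per_month = sub.drop_duplicates().groupby("m").size()
    counts[per_month.index.to_numpy()] = per_month.to_numpy()
    return counts


def find_dense_period(counts: np.ndarray) -> tuple[int, int]:
    """Longest contiguous run of months whose count strictly exceeds the
    median over all months, as a half-open index interval; ties broken by
    earliest start. Raises when no month exceeds the median."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    med = float(np.median(counts))
    above = counts > med
    if not above.any():
        raise ValueError("degenerate density profile: no month exceeds the median")
    best = (0, 0)
    i = 0
    n = len(counts)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def coverage_filter(
    matrix: StatusMatrix, period: tuple[int, int] | None = None
) -> tuple[list[str], pd.Series]:
    """Retain men whose coverage of the clustering period is at or above the
    median coverage ("below the overall median" excludes strict inferiority).

    Coverage of a man = fraction of period months at which he has >=1
    non-missing indicator entry. Returns (retained ids, coverage per man).
    """
    sub = matrix if period is None else matrix.restrict(period)
    if sub.n_months == 0:
        raise ValueError("empty period")
    has_status = (~np.isnan(sub.values)).any(axis=1)  # (n_men, n_months)
    coverage = pd.Series(has_status.mean(axis=1), index=sub.men, name="coverage")
    med = float(coverage.median())
    retained = [m for m in sub.men if coverage[m] >= med]
    return retained, coverage
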