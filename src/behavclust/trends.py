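"""Population- and subgroup-level frequency trend series with 95% CIs.

Monthly series are raw proportions of men whose carried-forward status is
active among those with any valid status; no smoothing is applied. Intervals
are Wald (normal approximation) by default — the presentation style of
symmetric intervals around the estimate — with Wilson available by
configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .subgroups import cluster_frequency_series
from .trajectories import StatusMatrix

__all__ = ["frequency_with_ci", "overall_trends", "subgroup_trends"]

CI_METHODS = {"wald": "normal", "wilson": "wilson"}


def frequency_with_ci(
    active: int, denominator: int, alpha: float = 0.05, method: str = "wald"
) -> tuple[float, float, float]:
    """Point estimate and (1-alpha) interval for a binomial proportion,
    clipped to [0, 1]."""
    if method not in CI_METHODS:
        raise ValueError(f"method must be one of {sorted(CI_METHODS)}")
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= active <= denominator:
        raise ValueError("need 0 <= active <= denominator")
    p = active / denominator
    lo, hi = proportion_confint(active, denominator, alpha=alpha, method=CI_METHODS[method])
    return p, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def _series_with_ci(
    series: pd.DataFrame, indicator: str, months: pd.PeriodIndex,
    alpha: float, method: str,
) -> pd.DataFrame:
    rows = []
    for _, r in series.iterrows():
        n = int(r["denom"])
        if n == 0:
            freq = lo = hi = np.nan  # undefined point, length preserved
        else:
            active = int(round(r["freq"] * n))
            freq, lo, hi = frequency_with_ci(active, n, alpha, method)
        rows.append(
            {"indicator": indicator, "month": str(months[int(r["month"])]),
             "freq": freq, "ci_low": lo, "ci_high": hi, "n": n}
        )
    return pd.DataFrame(rows)


def overall_trends(
    matrix: StatusMatrix,
    indicators: list[str] | None = None,
    alpha: float = 0.05,
    method: str = "wald",
) -> pd.DataFrame:
    """Tidy per-indicator monthly frequency table over the whole study
    population: indicator, month, freq, ci_low, ci_high, n."""
    indicators = indicators or matrix.indicators
    frames = [
        _series_with_ci(
            cluster_frequency_series(matrix.men, matrix, v), v, matrix.months,
            alpha, method,
        )
        for v in indicators
    ]
    return pd.concat(frames, ignore_index=True)


def subgroup_trends(
    matrix: StatusMatrix,
    members_by_label: dict[str, list[str]],
    indicators: list[str] | None = None,
    alpha: float = 0.05,
    method: str = "wald",
) -> pd.DataFrame:
    """Per-subgroup trend table with a ``subgroup`` column."""
    indicators = indicators or matrix.indicators
    frames = []
    for label, members in members_by_label.items():
        for v in indicators:
            f = _series_with_ci(
                cluster_frequency_series(members, matrix, v), v, matrix.months,
                alpha, method,
            )
            f.insert(0, "subgroup", label)
            frames.append(f)
    return pd.concat(frames, ignore_index=True)
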