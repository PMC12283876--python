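"""Hierarchical clustering of trajectory distances and heuristic subgroup
screening.

The dendrogram's top ``L`` hierarchy levels (level ``l`` = the partition into
``l`` clusters obtained by cutting the ``l-1`` highest merges) define the
candidate clusters: the distinct non-root nodes appearing in those levels —
exactly ``2(L-1)`` of them on a binary merge tree. A candidate is a
*subgroup* when, for at least one indicator, its within-cluster frequency
series satisfies both heuristic criteria:

1. the frequency reaches or surpasses ``min_reach`` (default 25%); and
2. either the behavior is *hegemonic* — frequency above ``hegemony_level``
   (75%) for at least ``hegemony_time_fraction`` (95%) of the retained months
   — or *rising* — relative change between first and last retained months of
   at least ``rise_fraction`` (75%) toward increased STI exposure.

Months whose within-cluster denominator falls below the first quartile of the
denominator sequence are discarded first, to avoid jumps from small
denominators. A subgroup descending from another subgroup is kept only if its
criterion-2 mode set differs from its ancestor's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .distance import DistanceMatrix
from .trajectories import StatusMatrix

__all__ = [
    "SubgroupCriteria",
    "Dendrogram",
    "CandidateCluster",
    "cluster_hierarchical",
    "enumerate_top_levels",
    "cluster_frequency_series",
    "discard_sparse_segments",
    "evaluate_subgroup_criteria",
    "prune_descendants",
    "screen_subgroups",
    "to_newick",
]

log = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single", "ward")


@dataclass(frozen=True)
class SubgroupCriteria:
    """Thresholds of the heuristic subgroup definition."""

    min_reach: float = 0.25
    hegemony_level: float = 0.75
    hegemony_time_fraction: float = 0.95
    rise_fraction: float = 0.75
    levels_scanned: int = 6
    #: "relative": (last-first)/first; "absolute": last-first in pp
    rise_mode: str = "relative"

    def __post_init__(self):
        for name in ("min_reach", "hegemony_level", "hegemony_time_fraction",
                     "rise_fraction"):
            x = getattr(self, name)
            if not 0 < x <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.levels_scanned < 2:
            raise ValueError("levels_scanned must be >= 2")
        if self.rise_mode not in ("relative", "absolute"):
            raise ValueError("rise_mode must be 'relative' or 'absolute'")


@dataclass
class Dendrogram:
    """Binary merge tree over men, backed by a scipy linkage matrix.

    Node ids follow the scipy convention: leaves are ``0..n-1`` (positions in
    ``leaves``), internal node ``n+r`` is row ``r`` of ``Z``; the root is
    ``2n-2``.
    """

    Z: np.ndarray
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def children(self, node: int) -> tuple[int, int]:
        n = self.n_leaves
        if node < n:
            raise ValueError(f"leaf {node} has no children")
        a, b = self.Z[node - n, :2]
        return int(a), int(b)

    def height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.Z[node - n, 2])

    def members(self, node: int) -> list[int]:
        """Leaf indices under a node (iterative, sorted)."""
        stack, out = [node], []
        n = self.n_leaves
        while stack:
            x = stack.pop()
            if x < n:
                out.append(x)
            else:
                stack.extend(self.children(x))
        return sorted(out)

    def member_ids(self, node: int) -> list[str]:
        return [self.leaves[i] for i in self.members(node)]

    def parent_map(self) -> dict[int, int]:
        return {
            child: self.n_leaves + r
            for r in range(len(self.Z))
            for child in (int(self.Z[r, 0]), int(self.Z[r, 1]))
        }


@dataclass
class CandidateCluster:
    node: int
    level: int  # shallowest hierarchy level (partition size) exposing it
    member_ids: list[str]
    parent: int


def cluster_hierarchical(
    dist: DistanceMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative hierarchical clustering of the distance matrix.

    Merge order is fully deterministic: scipy's nearest-neighbor chain breaks
    height ties by cluster index, which our fixed (sorted man-id) leaf order
    makes reproducible across runs and platforms.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if not np.isfinite(dist.values).all():
        raise ValueError("distance matrix contains non-finite values")
    Z = hierarchy.linkage(dist.condensed(), method=linkage)
    return Dendrogram(Z, list(dist.men))


def enumerate_top_levels(tree: Dendrogram, L: int = 6) -> list[CandidateCluster]:
    """Distinct non-root clusters appearing in the top ``L`` hierarchy levels.

    Level ``l`` is the partition into ``l`` clusters given by cutting the
    ``l-1`` highest merges; scanning levels 1..L therefore exposes the
    children of the ``L-1`` highest merges: exactly ``2(L-1)`` distinct
    non-root nodes on a binary tree. Candidates are returned top-down
    (children of the highest merge first, larger child first).
    """
    n = tree.n_leaves
    if n < L:
        raise ValueError(f"tree has {n} leaves, fewer than L={L}")
    heights = tree.Z[:, 2]
    if np.any(np.diff(heights) < -1e-12):
        raise ValueError("non-monotone linkage heights; use a monotone linkage")
    out: list[CandidateCluster] = []
    for level, r in enumerate(range(len(tree.Z) - 1, len(tree.Z) - L, -1), start=2):
        parent = n + r
        kids = sorted(tree.children(parent), key=lambda c: (-len(tree.members(c)), c))
        for c in kids:
            out.append(CandidateCluster(c, level, tree.member_ids(c), parent))
    return out


def cluster_frequency_series(
    member_ids: list[str], matrix: StatusMatrix, indicator: str
) -> pd.DataFrame:
    """Within-cluster monthly frequency of one indicator.

    Returns a frame with ``month`` (index into the matrix grid), ``freq``
    (NaN where no member has a valid status) and ``denom``.
    """
    if not member_ids:
        raise ValueError("empty cluster")
    idx = [matrix.men.index(m) for m in member_ids]
    v = matrix.indicator_index(indicator)
    sub = matrix.values[idx, v, :]  # (m, T)
    valid = ~np.isnan(sub)
    denom = valid.sum(axis=0)
    active = np.nansum(sub, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, active / np.where(denom > 0, denom, 1), np.nan)
    return pd.DataFrame(
        {"month": np.arange(matrix.n_months), "freq": freq, "denom": denom}
    )


def discard_sparse_segments(series: pd.DataFrame, q: float = 0.25) -> pd.DataFrame:
    """Drop months whose denominator is below the first quartile of the
    denominator sequence (linear-interpolation quartile), suppressing jumps
    caused by small denominators."""
    if len(series) < 4:
        raise ValueError("series too short to assess sparsity (need >= 4 months)")
    q1 = float(np.percentile(series["denom"].to_numpy(), 100 * q))
    out = series.loc[series["denom"] >= q1].copy()
    out = out.loc[out["denom"] > 0]
    if out.empty:
        raise ValueError("series too sparse: every month discarded")
    return out


def _rising(first: float, last: float, direction: str, crit: SubgroupCriteria) -> bool:
    if direction == "none":
        return False
    change = last - first if direction == "increase" else first - last
    if crit.rise_mode == "absolute":
        return change >= crit.rise_fraction
    if first == 0:
        # relative change from zero is unbounded: any positive move counts
        return change > 0
    return change / first >= crit.rise_fraction


def evaluate_subgroup_criteria(
    series_by_indicator: dict[str, pd.DataFrame],
    criteria: SubgroupCriteria,
    directions: dict[str, str],
) -> dict:
    """Apply the two heuristic criteria to a candidate's per-indicator series
    (sparse segments already discarded).

    Returns a report entry: per-indicator flags, the criterion-2 mode set
    (pairs ``(indicator, "hegemonic"|"rising")`` restricted to indicators
    also passing criterion 1), and ``is_subgroup``.
    """
    per_indicator = {}
    modes: set[tuple[str, str]] = set()
    for name, series in series_by_indicator.items():
        obs = series.loc[series["denom"] > 0]
        if obs.empty:
            per_indicator[name] = {
                "criterion1": False, "hegemonic": False, "rising": False}
            continue
        freq = obs["freq"].to_numpy()
        c1 = bool(freq.max() >= criteria.min_reach)
        heg = bool(
            (freq > criteria.hegemony_level).mean() >= criteria.hegemony_time_fraction
        )
        direction = directions.get(name, "none")
        if direction == "none":
            log.debug("indicator %s has no exposure direction; rising mode skipped", name)
            rise = False
        else:
            rise = _rising(float(freq[0]), float(freq[-1]), direction, criteria)
        per_indicator[name] = {"criterion1": c1, "hegemonic": heg, "rising": rise}
        if c1 and heg:
            modes.add((name, "hegemonic"))
        if c1 and rise:
            modes.add((name, "rising"))
    return {
        "per_indicator": per_indicator,
        "modes": sorted(modes),
        "is_subgroup": bool(modes),
    }


def prune_descendants(
    candidates: list[CandidateCluster], reports: dict[int, dict], tree: Dendrogram
) -> list[int]:
    """Resolve nested subgroups top-down.

    A subgroup whose nearest retained-subgroup ancestor (within the
    candidates) has the *same* criterion-2 mode set is discarded; it survives
    when the mode set differs in any way, or when no ancestor is a subgroup.
    Returns the node ids of the final subgroups; each pruned report entry
    gains a ``pruned_reason``.
    """
    parent = tree.parent_map()
    cand_nodes = {c.node for c in candidates}
    retained: set[int] = set()
    # top-down: shallower levels (bigger clusters) first
    for cand in sorted(candidates, key=lambda c: (c.level, c.node)):
        rep = reports[cand.node]
        if not rep["is_subgroup"]:
            continue
        anc = parent.get(cand.node)
        nearest = None
        while anc is not None:
            if anc in cand_nodes and anc in retained:
                nearest = anc
                break
            anc = parent.get(anc)
        if nearest is not None and set(map(tuple, reports[nearest]["modes"])) == set(
            map(tuple, rep["modes"])
        ):
            rep["pruned_reason"] = (
                f"criterion-2 modes identical to ancestor subgroup node {nearest}"
            )
            continue
        retained.add(cand.node)
    return sorted(retained)


def _assign_labels(
    final: list[int], candidates: list[CandidateCluster], tree: Dendrogram
) -> dict[int, str]:
    """Human-readable labels: letters by size for subgroups with no subgroup
    ancestor, dotted suffixes for nested subgroups (A, B, ..., D.1)."""
    parent = tree.parent_map()
    cand = {c.node: c for c in candidates}
    by_size = sorted(final, key=lambda nd: (-len(cand[nd].member_ids), nd))
    labels: dict[int, str] = {}
    letters = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    children_count: dict[int, int] = {}
    for node in by_size:
        anc = parent.get(node)
        anc_label = None
        while anc is not None:
            if anc in labels:
                anc_label = labels[anc]
                break
            anc = parent.get(anc)
        if anc_label is None:
            labels[node] = next(letters)
        else:
            children_count[anc_label] = children_count.get(anc_label, 0) + 1
            labels[node] = f"{anc_label}.{children_count[anc_label]}"
    return labels


def screen_subgroups(
    tree: Dendrogram,
    matrix: StatusMatrix,
    directions: dict[str, str],
    criteria: SubgroupCriteria | None = None,
) -> dict:
    """Full screening pass: enumerate candidates in the top levels, evaluate
    the criteria on their denominator-filtered frequency series, prune nested
    duplicates, and label the survivors. Returns a JSON-serializable report."""
    criteria = criteria or SubgroupCriteria()
    candidates = enumerate_top_levels(tree, criteria.levels_scanned)
    reports: dict[int, dict] = {}
    for cand in candidates:
        series = {}
        for name in matrix.indicators:
            s = cluster_frequency_series(cand.member_ids, matrix, name)
            try:
                series[name] = discard_sparse_segments(s)
            except ValueError:
                # degenerate series (all months sparse): excluded from criteria
                continue
        reports[cand.node] = evaluate_subgroup_criteria(series, criteria, directions)
        reports[cand.node]["size"] = len(cand.member_ids)
        reports[cand.node]["level"] = cand.level
    final = prune_descendants(candidates, reports, tree)
    labels = _assign_labels(final, candidates, tree)
    return {
        "criteria": {
            "min_reach": criteria.min_reach,
            "hegemony_level": criteria.hegemony_level,
            "hegemony_time_fraction": criteria.hegemony_time_fraction,
            "rise_fraction": criteria.rise_fraction,
            "levels_scanned": criteria.levels_scanned,
            "rise_mode": criteria.rise_mode,
        },
        "candidates": [
            {
                "node": c.node,
                "level": c.level,
                "size": len(c.member_ids),
                "is_subgroup": reports[c.node]["is_subgroup"],
                "modes": reports[c.node]["modes"],
                "per_indicator": reports[c.node]["per_indicator"],
                "pruned_reason": reports[c.node].get("pruned_reason"),
                "final": c.node in labels,
                "label": labels.get(c.node),
            }
            for c in candidates
        ],
        "subgroups": {
            labels[nd]: {"node": nd, "members": tree.member_ids(nd)} for nd in final
        },
    }


def to_newick(tree: Dendrogram) -> str:
    """Newick serialization: leaf labels are man ids, branch lengths are
    merge-height differences between parent and child."""

    def rec(node: int, parent_h: float) -> str:
        h = tree.height(node)
        bl = parent_h - h
        if node < tree.n_leaves:
            return f"{tree.leaves[node]}:{bl:.6g}"
        a, b = tree.children(node)
        return f"({rec(a, h)},{rec(b, h)}):{bl:.6g}"

    root = tree.root
    h = tree.height(root)
    a, b = tree.children(root)
    return f"({rec(a, h)},{rec(b, h)});"
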