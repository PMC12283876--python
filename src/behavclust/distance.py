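"""Pairwise behavioral-trajectory dissimilarity.

The distance between men ``j`` and ``k`` sums, over the longitudinal
indicators ``v``, a comparability-weighted Jaccard dissimilarity

    d(j, k) = sum_v  w_v(j, k) * (1 - J_v(j, k))

where ``J_v`` is the Jaccard similarity between the sets of months in which
each man is active on ``v`` (restricted to months where both statuses are
non-missing), and the weight

    w_v(j, k) = (#shared valid months for v) / max_v' (#shared valid months)

is pair-specific: the best-observed indicator of the pair carries weight 1
and sparser indicators proportionally less. Two men who never report a
behavior on their shared months are maximally similar on it (empty-union
Jaccard = 1). Pairs with no shared valid month on any indicator receive the
maximal distance (the number of indicators) so the matrix stays complete.

The weighted sum is a dissimilarity, not a metric: the triangle inequality
is not guaranteed and is not relied upon downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectories import StatusMatrix

__all__ = [
    "DistanceMatrix",
    "jaccard_similarity",
    "comparability_weight",
    "pairwise_distance",
    "pair_terms",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise trajectory dissimilarities with zero diagonal.

    ``weights`` (men x men x indicators), when retained, holds the
    comparability weights for audit; for large cohorts it is dropped and
    :func:`pair_terms` recomputes any pair on demand.
    """

    men: list[str]
    values: np.ndarray  # (n, n) float
    weights: np.ndarray | None = None  # (n, n, V) or None

    @property
    def n(self) -> int:
        return len(self.men)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.men, columns=self.men)


def jaccard_similarity(seq_j: np.ndarray, seq_k: np.ndarray) -> float:
    """Jaccard similarity of the active-month sets of two tri-state monthly
    sequences, restricted to months non-missing in both.

    Empty union (neither man active on any shared month) gives 1 — absence of
    the behavior is shared behavior. No shared valid month also gives 1 by
    convention; the comparability weight is 0 there, so the value never
    contributes.
    """
    a = np.asarray(seq_j, dtype=float)
    b = np.asarray(seq_k, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"sequence length mismatch: {a.shape} vs {b.shape}")
    shared = ~np.isnan(a) & ~np.isnan(b)
    aj = (a == 1) & shared
    ak = (b == 1) & shared
    union = int((aj | ak).sum())
    if union == 0:
        return 1.0
    return float((aj & ak).sum() / union)


def _shared_counts(matrix: StatusMatrix) -> np.ndarray:
    """(V, n, n) counts of months valid in both men, per indicator."""
    valid = (~np.isnan(matrix.values)).astype(float)  # (n, V, T)
    return np.einsum("ivt,jvt->vij", valid, valid)


def comparability_weight(j: int, k: int, v: int, matrix: StatusMatrix) -> float:
    """Weight of indicator ``v`` for the pair (j, k): shared valid months for
    ``v`` over the pair's maximum shared valid months across indicators;
    0 when the pair shares no valid month on any indicator."""
    if j == k:
        raise ValueError("weight is defined for distinct men")
    valid_j = ~np.isnan(matrix.values[j])
    valid_k = ~np.isnan(matrix.values[k])
    shared = (valid_j & valid_k).sum(axis=1)  # per indicator
    denom = shared.max()
    if denom == 0:
        return 0.0
    return float(shared[v] / denom)


def pairwise_distance(
    matrix: StatusMatrix, keep_weights: bool | str = "auto"
) -> DistanceMatrix:
    """Full pairwise distance matrix over the men of a status matrix.

    Vectorized over indicator-wise boolean month masks; exact, no
    approximation. ``keep_weights``: True/False or "auto" (retain the weight
    tensor when the cohort has <= 1000 men).
    """
    n, V, T = matrix.values.shape
    if n < 2:
        raise ValueError("need at least two men")
    vals = matrix.values
    valid = ~np.isnan(vals)
    act = (vals == 1) & valid

    shared = _shared_counts(matrix)  # (V, n, n)
    actf = act.astype(float)
    validf = valid.astype(float)
    inter = np.einsum("ivt,jvt->vij", actf, actf)
    union = (
        np.einsum("ivt,jvt->vij", actf, validf)
        + np.einsum("ivt,jvt->vij", validf, actf)
        - inter
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
        denom = shared.max(axis=0)  # (n, n) pair-specific max
        w = np.where(denom > 0, shared / np.where(denom > 0, denom, 1.0), 0.0)

    d = (w * (1.0 - jac)).sum(axis=0)
    no_overlap = denom == 0
    np.fill_diagonal(no_overlap, False)
    if no_overlap.any():
        log.warning(
            "%d pairs share no valid month on any indicator; assigned the "
            "maximal distance %d",
            int(no_overlap.sum()) // 2,
            V,
        )
        d = np.where(no_overlap, float(V), d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise

    if keep_weights == "auto":
        keep_weights = n <= 1000
    weights = np.moveaxis(w, 0, 2) if keep_weights else None
    return DistanceMatrix(list(matrix.men), d, weights)


def pair_terms(matrix: StatusMatrix, j: int, k: int) -> pd.DataFrame:
    """Audit table for one pair: per indicator, shared valid months, weight,
    Jaccard similarity, and the distance contribution."""
    rows = []
    valid_j = ~np.isnan(matrix.values[j])
    valid_k = ~np.isnan(matrix.values[k])
    shared = (valid_j & valid_k).sum(axis=1)
    denom = shared.max()
    for v, name in enumerate(matrix.indicators):
        w = float(shared[v] / denom) if denom > 0 else 0.0
        jac = jaccard_similarity(matrix.values[j, v], matrix.values[k, v])
        rows.append(
            {"indicator": name, "shared_months": int(shared[v]),
             "weight": w, "jaccard": jac, "term": w * (1 - jac)}
        )
    return pd.DataFrame(rows)
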