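"""Dendrogram scanning, heuristic subgroup criteria and descendant pruning."""

import numpy as np
import pandas as pd
import pytest

from behavclust.distance import DistanceMatrix
from behavclust.subgroups import (
    Dendrogram,
    SubgroupCriteria,
    cluster_frequency_series,
    cluster_hierarchical,
    discard_sparse_segments,
    enumerate_top_levels,
    evaluate_subgroup_criteria,
    prune_descendants,
    to_newick,
)
from conftest import status_matrix


def dmat(values, men=None):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(men or [f"m{i}" for i in range(len(values))], values)


def balanced8() -> Dendrogram:
    Z = np.array([
        [0, 1, 1.0, 2], [2, 3, 1.0, 2], [4, 5, 1.0, 2], [6, 7, 1.0, 2],
        [8, 9, 2.0, 4], [10, 11, 2.0, 4], [12, 13, 3.0, 8],
    ])
    return Dendrogram(Z, [f"m{i}" for i in range(8)])


def chain5() -> Dendrogram:
    Z = np.array([
        [3, 4, 1.0, 2], [2, 5, 2.0, 3], [1, 6, 3.0, 4], [0, 7, 4.0, 5],
    ])
    return Dendrogram(Z, [f"m{i}" for i in range(5)])


class TestClusterHierarchical:
    def test_closest_pair_merges_first(self):
        d = dmat([[0, .1, .9], [.1, 0, .9], [.9, .9, 0]])
        tree = cluster_hierarchical(d)
        assert set(tree.Z[0, :2].astype(int)) == {0, 1}

    def test_two_men_give_single_merge(self):
        tree = cluster_hierarchical(dmat([[0, .5], [.5, 0]]))
        assert len(tree.Z) == 1 and tree.root == 2

    def test_all_equal_distances_still_deterministic(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        t1 = cluster_hierarchical(dmat(d))
        t2 = cluster_hierarchical(dmat(d))
        np.testing.assert_array_equal(t1.Z, t2.Z)

    def test_non_finite_distances_rejected(self):
        d = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValueError):
            cluster_hierarchical(dmat(d))

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValueError):
            cluster_hierarchical(dmat([[0, 1], [1, 0]]), "median-magic")


class TestEnumerateTopLevels:
    def test_ten_candidates_at_six_levels(self):
        rng = np.random.default_rng(0)
        for n in (7, 12, 40):
            x = rng.random((n, 5))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            tree = cluster_hierarchical(dmat(d, men=[f"m{i}" for i in range(n)]))
            cands = enumerate_top_levels(tree, 6)
            assert len(cands) == 10
            assert len({c.node for c in cands}) == 10
            assert tree.root not in {c.node for c in cands}

    def test_two_levels_give_root_children(self):
        tree = balanced8()
        cands = enumerate_top_levels(tree, 2)
        assert {c.node for c in cands} == {12, 13}

    def test_balanced_eight_leaves_three_levels(self):
        cands = enumerate_top_levels(balanced8(), 3)
        assert {c.node for c in cands} == {12, 13, 10, 11}

    def test_fewer_leaves_than_levels_rejected(self):
        with pytest.raises(ValueError, match="leaves"):
            enumerate_top_levels(chain5(), 6)

    def test_members_partition_parent(self):
        for cand in enumerate_top_levels(balanced8(), 4):
            tree = balanced8()
            kids = tree.children(cand.parent)
            parent_members = set(tree.member_ids(cand.parent))
            union = set(tree.member_ids(kids[0])) | set(tree.member_ids(kids[1]))
            assert union == parent_members


class TestFrequencySeries:
    def test_all_active_cluster_is_constant_one(self):
        m = status_matrix([[[1, 1, 1]], [[1, 1, 1]]])
        s = cluster_frequency_series(["m0", "m1"], m, "v0")
        assert (s["freq"] == 1.0).all() and (s["denom"] == 2).all()

    def test_counting_with_missing_members(self):
        m = status_matrix([[[1, 0]], [[None, 1]]])
        s = cluster_frequency_series(["m0", "m1"], m, "v0")
        assert list(s["denom"]) == [1, 2]
        assert list(s["freq"]) == [1.0, 0.5]

    def test_empty_cluster_rejected(self):
        m = status_matrix([[[1, 0]]])
        with pytest.raises(ValueError, match="empty"):
            cluster_frequency_series([], m, "v0")

    def test_unknown_indicator_rejected(self):
        m = status_matrix([[[1, 0]]])
        with pytest.raises(KeyError):
            cluster_frequency_series(["m0"], m, "nope")


def series(freqs, denoms):
    return pd.DataFrame({
        "month": np.arange(len(freqs)), "freq": freqs, "denom": denoms
    })


class TestDiscardSparseSegments:
    def test_small_denominator_month_removed(self):
        s = series([.5, .5, .5, .5], [10, 10, 10, 1])  # Q1 = 7.75
        out = discard_sparse_segments(s)
        assert list(out["month"]) == [0, 1, 2]

    def test_constant_denominators_identity(self):
        s = series([.1, .2, .3, .4], [8, 8, 8, 8])
        pd.testing.assert_frame_equal(discard_sparse_segments(s), s)

    def test_quartile_interpolation_example(self):
        s = series([.5, .5, .5, .5], [1, 2, 3, 100])  # Q1 = 1.75
        out = discard_sparse_segments(s)
        assert list(out["month"]) == [1, 2, 3]

    def test_everything_sparse_rejected(self):
        with pytest.raises(ValueError, match="sparse"):
            discard_sparse_segments(series([np.nan] * 4, [0, 0, 0, 0]))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="4 months"):
            discard_sparse_segments(series([.5] * 3, [5] * 3))


class TestEvaluateCriteria:
    def crit(self):
        return SubgroupCriteria()

    def test_constant_high_frequency_is_hegemonic(self):
        rep = evaluate_subgroup_criteria(
            {"x": series([0.80] * 30, [100] * 30)}, self.crit(), {"x": "increase"}
        )
        assert rep["is_subgroup"]
        assert ("x", "hegemonic") in map(tuple, rep["modes"])

    def test_doubling_series_is_rising(self):
        freqs = np.linspace(0.20, 0.40, 30)
        rep = evaluate_subgroup_criteria(
            {"x": series(freqs, [100] * 30)}, self.crit(), {"x": "increase"}
        )
        assert rep["modes"] == [("x", "rising")]

    def test_low_flat_series_is_not_a_subgroup(self):
        rep = evaluate_subgroup_criteria(
            {"x": series([0.10] * 30, [100] * 30)}, self.crit(), {"x": "increase"}
        )
        assert not rep["is_subgroup"]

    def test_reach_criterion_gates_the_modes(self):
        # rises 0.05 -> 0.20 (+300%) but never reaches 25%
        freqs = np.linspace(0.05, 0.20, 30)
        rep = evaluate_subgroup_criteria(
            {"x": series(freqs, [100] * 30)}, self.crit(), {"x": "increase"}
        )
        assert rep["per_indicator"]["x"]["rising"]
        assert not rep["is_subgroup"]

    def test_direction_none_skips_rising_mode(self):
        freqs = np.linspace(0.20, 0.60, 30)
        rep = evaluate_subgroup_criteria(
            {"x": series(freqs, [100] * 30)}, self.crit(), {"x": "none"}
        )
        assert not rep["is_subgroup"]

    def test_decrease_direction_flags_falling_series(self):
        freqs = np.linspace(0.80, 0.10, 30)
        rep = evaluate_subgroup_criteria(
            {"x": series(freqs, [100] * 30)}, self.crit(), {"x": "decrease"}
        )
        assert ("x", "rising") in map(tuple, rep["modes"])

    def test_rise_from_zero_counts_as_rising(self):
        freqs = [0.0] + list(np.linspace(0.1, 0.4, 29))
        rep = evaluate_subgroup_criteria(
            {"x": series(freqs, [100] * 30)}, self.crit(), {"x": "increase"}
        )
        assert ("x", "rising") in map(tuple, rep["modes"])

    def test_hegemony_time_fraction_enforced(self):
        # above 75% for only 80% of the period: not hegemonic
        freqs = [0.85] * 24 + [0.5] * 6
        rep = evaluate_subgroup_criteria(
            {"x": series(freqs, [100] * 30)}, self.crit(), {"x": "none"}
        )
        assert not rep["per_indicator"]["x"]["hegemonic"]

    def test_same_indicator_must_satisfy_both_criteria(self):
        # x reaches 25% but is flat; y doubles but stays under 25%
        rep = evaluate_subgroup_criteria(
            {
                "x": series([0.30] * 30, [100] * 30),
                "y": series(np.linspace(0.05, 0.2, 30), [100] * 30),
            },
            self.crit(),
            {"x": "increase", "y": "increase"},
        )
        assert not rep["is_subgroup"]


class TestPruneDescendants:
    def make(self):
        tree = chain5()
        # candidates at L=3: children of root (0, 7) and of node 7 (1, 6)
        cands = enumerate_top_levels(tree, 3)
        return tree, cands

    def rep(self, modes, is_subgroup=True):
        return {"modes": sorted(modes), "is_subgroup": is_subgroup and bool(modes)}

    def test_identical_mode_set_discards_descendant(self):
        tree, cands = self.make()
        reports = {c.node: self.rep([]) for c in cands}
        reports[7] = self.rep([("nscai", "rising")])
        reports[6] = self.rep([("nscai", "rising")])
        final = prune_descendants(cands, reports, tree)
        assert final == [7]
        assert "pruned_reason" in reports[6]

    def test_differing_mode_set_keeps_descendant(self):
        tree, cands = self.make()
        reports = {c.node: self.rep([]) for c in cands}
        reports[7] = self.rep([("group_sex", "hegemonic")])
        reports[6] = self.rep([("group_sex", "hegemonic"), ("nscai", "rising")])
        assert prune_descendants(cands, reports, tree) == [6, 7]

    def test_non_subgroup_ancestor_never_prunes(self):
        tree, cands = self.make()
        reports = {c.node: self.rep([]) for c in cands}
        reports[6] = self.rep([("nscai", "rising")])  # ancestor 7 not a subgroup
        assert prune_descendants(cands, reports, tree) == [6]


class TestNewick:
    def test_roundtrips_through_dendropy(self):
        import dendropy

        tree = balanced8()
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert labels == set(tree.leaves)

    def test_branch_lengths_are_height_differences(self):
        tree = chain5()
        nwk = to_newick(tree)
        # leaf m0 hangs directly off the root at height 4
        assert "m0:4" in nwk
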