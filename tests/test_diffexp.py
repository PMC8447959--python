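"""Differential-expression calling, ranking and clustering order."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from circsponge import diffexp, fixtures
from circsponge.diffexp import (
    DifferentialTable,
    average_linkage_merges,
    bh_adjust,
    chromosome_distribution,
    correlation_distance,
    fold_change_and_direction,
    hierarchical_cluster_order,
    select_differential,
    top_n,
    two_group_t_test,
)
from circsponge.matrix import DesignError

from conftest import make_matrix


class TestFoldChange:
    def test_two_fold_up_and_down(self):
        m = make_matrix([[5.0, 5.0, 5.0, 3.0, 3.0, 3.0],
                         [3.0, 3.0, 3.0, 5.0, 5.0, 5.0]])
        out = fold_change_and_direction(m, case_group="a", control_group="b")
        assert out.loc["p1", "fold_change"] == pytest.approx(4.0)
        assert out.loc["p1", "regulation"] == "up"
        assert out.loc["p2", "fold_change"] == pytest.approx(4.0)
        assert out.loc["p2", "regulation"] == "down"

    def test_equal_means_tie_flagged_up(self):
        m = make_matrix([[4.0, 4.0, 4.0, 4.0]])
        out = fold_change_and_direction(m, "a", "b")
        assert out.loc["p1", "fold_change"] == pytest.approx(1.0)
        assert out.loc["p1", "regulation"] == "up"
        assert bool(out.loc["p1", "tie"])

    def test_direction_swap_inverts_linear_fold(self, small_log2_matrix):
        ab = fold_change_and_direction(small_log2_matrix, "a", "b")
        ba = fold_change_and_direction(small_log2_matrix, "b", "a")
        signed_ab = np.where(ab["regulation"] == "up", 1, -1) * np.log2(ab["fold_change"])
        signed_ba = np.where(ba["regulation"] == "up", 1, -1) * np.log2(ba["fold_change"])
        assert np.allclose(signed_ab, -signed_ba)

    def test_unknown_group_rejected(self, small_log2_matrix):
        with pytest.raises(DesignError):
            fold_change_and_direction(small_log2_matrix, "a", "nope")


class TestTTest:
    def test_identical_groups_p_one(self):
        m = make_matrix([[2.0, 2.0, 2.0, 2.0, 2.0, 2.0]])
        out = two_group_t_test(m, "a", "b")
        assert out.loc["p1", "p_raw"] == 1.0
        assert bool(out.loc["p1", "zero_variance"])

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_matches_scipy_reference(self, variant, rng):
        m = make_matrix(rng.normal(5, 1, size=(50, 6)))
        out = two_group_t_test(m, "b", "a", variant=variant)
        a = m.values[m.samples_in_group("b")].to_numpy()
        b = m.values[m.samples_in_group("a")].to_numpy()
        ref = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "pooled"))
        assert np.allclose(out["p_raw"], ref.pvalue, atol=1e-10)
        assert np.allclose(out["t"], ref.statistic, atol=1e-10)

    def test_hand_worked_pooled_example(self):
        # 3 vs 3: textbook pooled t computed explicitly
        case, ctrl = [6.0, 7.0, 8.0], [4.0, 5.0, 4.5]
        m = make_matrix([ctrl + case])
        out = two_group_t_test(m, "b", "a", variant="pooled")
        sp2 = (np.var(case, ddof=1) * 2 + np.var(ctrl, ddof=1) * 2) / 4
        t = (np.mean(case) - np.mean(ctrl)) / np.sqrt(sp2 * (2 / 3))
        p = 2 * stats.t.sf(abs(t), 4)
        assert out.loc["p1", "t"] == pytest.approx(t, abs=1e-10)
        assert out.loc["p1", "p_raw"] == pytest.approx(p, abs=1e-10)


class TestBHAdjust:
    def test_step_up_hand_example(self):
        # step-up: min over j>=i of p_(j) * m / j = 0.04 for every rank here
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_degenerate_inputs(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0)


class TestSelection:
    def _tables(self, folds, regs, ps):
        idx = [f"p{i+1}" for i in range(len(folds))]
        fold = pd.DataFrame(
            {"fold_change": folds, "regulation": regs,
             "log2_fc": np.log2(folds), "mean_log2_case": 0.0,
             "mean_log2_control": 0.0, "tie": False},
            index=idx,
        )
        pv = pd.DataFrame({"p_raw": ps}, index=idx)
        return fold, pv

    def test_boundary_semantics(self):
        # fold >= threshold passes, p must be strictly below
        fold, pv = self._tables([2.0, 2.0], ["up", "up"], [0.05, 0.049])
        table = select_differential(fold, pv, fc_min=2.0, p_max=0.05)
        assert list(table.records.index) == ["p2"]

    def test_vacuous_thresholds_keep_all(self, rng):
        folds = rng.uniform(1, 5, size=30)
        fold, pv = self._tables(folds, ["up"] * 30, rng.uniform(size=30))
        assert len(select_differential(fold, pv, fc_min=1.0, p_max=1.0)) == 30

    def test_monotone_in_thresholds(self, rng):
        folds = rng.uniform(1, 8, size=100)
        regs = rng.choice(["up", "down"], size=100)
        ps = rng.uniform(size=100)
        fold, pv = self._tables(folds, regs, ps)
        base = set(select_differential(fold, pv, 2.0, 0.05).records.index)
        for fc_min, p_max in [(2.5, 0.05), (2.0, 0.01), (4.0, 0.001)]:
            sub = set(select_differential(fold, pv, fc_min, p_max).records.index)
            assert sub <= base

    def test_sorted_up_block_then_down_by_fold(self, rng):
        folds = rng.uniform(2.5, 50, size=40)
        regs = rng.choice(["up", "down"], size=40)
        fold, pv = self._tables(folds, regs, rng.uniform(0, 0.04, size=40))
        recs = select_differential(fold, pv).records
        regs_seen = list(recs["regulation"])
        assert regs_seen == sorted(regs_seen, key=lambda r: 0 if r == "up" else 1)
        for _, block in recs.groupby("regulation"):
            assert np.all(np.diff(block["fold_change"]) <= 1e-12)


class TestChromosomeDistribution:
    def test_table1_chr14_count(self):
        table = fixtures.table1_differential()
        ann = table.records[["chromosome"]]
        counts = chromosome_distribution(table, ann)
        chr14 = counts[counts["chromosome"] == "chr14"]["count"].sum()
        assert chr14 == 4
        assert counts["count"].sum() == 20

    def test_empty_table(self):
        table = fixtures.table1_differential()
        empty = DifferentialTable(records=table.records.iloc[:0], fc_min=2, p_max=0.05)
        counts = chromosome_distribution(empty, table.records[["chromosome"]])
        assert counts["count"].sum() == 0

    def test_missing_annotation_unplaced(self):
        table = fixtures.table1_differential()
        ann = table.records[["chromosome"]].iloc[:5]
        counts = chromosome_distribution(table, ann)
        unplaced = counts[counts["chromosome"] == "unplaced"]["count"].sum()
        assert unplaced == 15
        assert counts["count"].sum() == 20


def _brute_force_average_linkage(D):
    """Enumerate every merge step greedily with the same tie-break rule but
    computed from scratch with plain python loops."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    nid = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            lo, hi = sorted((min(clusters[a]), min(clusters[b])))
            cand = (d, lo, hi, a, b)
            if best is None or cand[:3] < best[:3]:
                best = cand
        d, lo, hi, a, b = best
        if min(clusters[b]) < min(clusters[a]):
            a, b = b, a
        merges.append((a, b, d))
        clusters[nid] = clusters.pop(a) + clusters.pop(b)
        nid += 1
    return merges


class TestClustering:
    def test_identical_rows_merge_first(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 4.0, 6.0, 8.0],   # perfectly correlated with row 0
                      [4.0, 3.0, 2.0, 1.0]])
        D, _ = correlation_distance(X)
        merges = average_linkage_merges(D)
        assert merges[0][:2] == (0, 1)
        assert merges[0][2] == pytest.approx(0.0)

    def test_three_row_merge_sequence_matches_bruteforce(self, rng):
        for _ in range(10):
            X = rng.normal(size=(3, 5))
            D, _ = correlation_distance(X)
            assert average_linkage_merges(D) == _brute_force_average_linkage(D)

    def test_matches_scipy_average_linkage_heights(self, rng):
        X = rng.normal(size=(12, 8))
        D, _ = correlation_distance(X)
        merges = average_linkage_merges(D)
        Z = hierarchy.linkage(D[np.triu_indices(12, k=1)], method="average")
        assert np.allclose(sorted(m[2] for m in merges), sorted(Z[:, 2]), atol=1e-10)

    def test_group_columns_contiguous_for_separated_groups(self):
        rng = np.random.default_rng(3)
        base = rng.normal(8, 0.05, size=(30, 6))
        base[:15, 3:] += 2.0   # group b high on the first probe block
        base[15:, :3] += 2.0   # group a high on the second block
        m = make_matrix(base)
        _rows, cols = hierarchical_cluster_order(m)
        groups = [m.groups[c] for c in cols]
        assert groups in (["a"] * 3 + ["b"] * 3, ["b"] * 3 + ["a"] * 3)

    def test_zero_variance_row_flagged(self):
        X = np.vstack([np.ones(4), np.arange(4.0), -np.arange(4.0)])
        D, flat = correlation_distance(X)
        assert flat[0] and not flat[1]
        assert np.all(D[0, 1:] == 1.0)


class TestTopN:
    def test_table1_top_record(self):
        table = fixtures.table1_differential()
        top = top_n(table, 20)
        assert top.records.index[0] == "circRNA.7079"
        assert (top.records["regulation"] == "up").sum() == 10
        assert (top.records["regulation"] == "down").sum() == 10

    def test_zero_returns_empty(self):
        assert len(top_n(fixtures.table1_differential(), 0)) == 0

    def test_fold_ties_broken_by_p(self):
        recs = pd.DataFrame(
            {"fold_change": [3.0, 3.0, 3.0], "regulation": ["up"] * 3,
             "p_raw": [0.03, 0.01, 0.02]},
            index=["pa", "pb", "pc"],
        )
        table = DifferentialTable(records=diffexp._sort_records(recs), fc_min=2, p_max=0.05)
        top = top_n(table, 2)
        assert list(top.records.index)[0] == "pb"

    def test_warns_when_short(self):
        table = fixtures.table1_differential()
        with pytest.warns(UserWarning):
            top_n(table, 100)
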