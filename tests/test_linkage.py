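"""Two-point engine, grouping, ordering and map-refinement rules."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import kendalltau

from snailqtl.linkage import (GroupingParams, estimate_rf, group_markers,
                              order_markers, pairwise_rf, prune_by_lod,
                              resolve_contig_conflicts, sex_average,
                              to_f2_codes)
from snailqtl.sim import MISSING, haldane_cm, haldane_r

import pandas as pd


class TestEstimateRf:
    def test_identical_vectors_ten_meioses(self):
        g = np.array([1, 2, 1, 1, 2, 2, 1, 2, 1, 2], dtype=np.int8)
        res = estimate_rf(g, g)
        assert res.r_hat == 0.0
        assert res.lod == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_two_recombinants_of_ten(self):
        g1 = np.array([1] * 10, dtype=np.int8)
        g2 = np.array([1] * 8 + [2] * 2, dtype=np.int8)
        res = estimate_rf(g1, g2)
        assert res.r_hat == pytest.approx(0.2)
        # oracle: evaluate both binomial likelihoods directly
        expected = np.log10(0.8**8 * 0.2**2 / 0.5**10)
        assert res.lod == pytest.approx(expected, abs=1e-9)

    def test_independent_markers_drift_to_half(self, rng):
        g1 = rng.integers(1, 3, size=2000).astype(np.int8)
        g2 = rng.integers(1, 3, size=2000).astype(np.int8)
        res = estimate_rf(g1, g2)
        assert 0.45 < res.r_hat <= 0.5
        assert res.lod < 1.0

    def test_no_shared_meioses_flagged(self):
        g1 = np.array([1, MISSING], dtype=np.int8)
        g2 = np.array([MISSING, 2], dtype=np.int8)
        res = estimate_rf(g1, g2)
        assert res.uninformative and res.r_hat == 0.5 and res.lod == 0.0

    def test_intercross_matches_grid_search_oracle(self, rng):
        # simulate F2 codes at two loci with r = 0.15 and compare the
        # phase-marginal ML against an independent likelihood grid search
        r_true, n = 0.15, 400
        pat1 = rng.integers(0, 2, n)
        mat1 = rng.integers(0, 2, n)
        flip = lambda s: np.where(rng.random(n) < r_true, 1 - s, s)
        pat2, mat2 = flip(pat1), flip(mat1)
        c1 = (pat1 + mat1).astype(np.int8)  # 0/1/2 == AA/AB/BB
        c2 = (pat2 + mat2).astype(np.int8)
        res = estimate_rf(c1, c2, phased=False)

        def joint(r):
            P = np.zeros((3, 3))
            for s in itertools.product((0, 1), repeat=2):
                for t in itertools.product((0, 1), repeat=2):
                    p = 0.25
                    p *= (1 - r) if s[0] == t[0] else r
                    p *= (1 - r) if s[1] == t[1] else r
                    P[s[0] + s[1], t[0] + t[1]] += p
            return P

        grid = np.linspace(1e-4, 0.5, 2000)
        lls = [sum(np.log(joint(r)[a, b]) for a, b in zip(c1, c2)) for r in grid]
        r_oracle = grid[int(np.argmax(lls))]
        assert res.r_hat == pytest.approx(r_oracle, abs=1e-3)
        assert abs(res.r_hat - r_true) < 3 * np.sqrt(r_true * (1 - r_true) / (2 * n))


class TestPairwiseRf:
    def test_matches_per_pair_estimator(self, rng):
        digits = rng.integers(1, 3, size=(6, 60)).astype(np.int8)
        digits[rng.random(digits.shape) < 0.1] = MISSING
        r, lod, n = pairwise_rf(digits)
        for i in range(6):
            for j in range(i + 1, 6):
                res = estimate_rf(digits[i], digits[j])
                assert r[i, j] == pytest.approx(res.r_hat, abs=1e-12)
                assert lod[i, j] == pytest.approx(res.lod, abs=1e-9)


class TestGrouping:
    def _lod(self, pairs, m):
        lod = np.zeros((m, m))
        for (i, j), v in pairs.items():
            lod[i, j] = lod[j, i] = v
        return lod

    def test_transitive_closure(self):
        lod = self._lod({(0, 1): 12, (1, 2): 12, (0, 2): 0.1}, 3)
        labels = group_markers(lod, GroupingParams(lod_limit=9.5, size_limit=1,
                                                   join_singles_lod=5))
        assert len(set(labels)) == 1 and labels[0] != 0

    def test_high_threshold_dissolves(self):
        lod = self._lod({(0, 1): 12, (1, 2): 12, (0, 2): 0.1}, 3)
        labels = group_markers(lod, GroupingParams(lod_limit=13, size_limit=1,
                                                   join_singles_lod=5))
        assert (labels == 0).sum() == 0 and len(set(labels)) == 3

    def test_planted_clusters_match_component_oracle(self, rng):
        m = 50
        plant = np.array([0] * 25 + [1] * 25)
        lod = np.where(plant[:, None] == plant[None, :], 15.0, 2.0)
        lod += rng.normal(0, 0.1, size=(m, m))
        lod = np.triu(lod, 1) + np.triu(lod, 1).T
        params = GroupingParams(lod_limit=9.5, size_limit=2, join_singles_lod=5)
        labels = group_markers(lod, params)
        G = nx.Graph((i, j) for i in range(m) for j in range(i + 1, m)
                     if lod[i, j] >= params.lod_limit)
        G.add_nodes_from(range(m))
        comps = list(nx.connected_components(G))
        assert len(set(labels)) == len(comps) == 2
        for comp in comps:
            assert len({labels[i] for i in comp}) == 1

    def test_size_limit_and_join_singles(self):
        # big cluster {0..4}, small pair {5,6} dissolved; 5 rejoins via LOD 6
        pairs = {(i, j): 15 for i in range(5) for j in range(i + 1, 5)}
        pairs[(5, 6)] = 15
        pairs[(0, 5)] = 6.0
        lod = self._lod(pairs, 7)
        labels = group_markers(lod, GroupingParams(lod_limit=9.5, size_limit=3,
                                                   join_singles_lod=5))
        assert labels[5] == labels[0] != 0
        assert labels[6] == 0  # best link (to 5) is no longer in a group


class TestOrdering:
    def _simulate_digits(self, positions, n, rng):
        m = len(positions)
        digits = np.empty((m, n), dtype=np.int8)
        for j in range(n):
            s = int(rng.integers(2))
            for i, p in enumerate(positions):
                if i > 0 and rng.random() < haldane_r(p - positions[i - 1]):
                    s = 1 - s
                digits[i, j] = s + 1
        return digits

    def test_matches_exhaustive_search_up_to_reversal(self, rng):
        positions = np.array([0.0, 7.0, 15.0, 21.0, 30.0, 38.0, 44.0, 52.0])
        digits = self._simulate_digits(positions, 150, rng)
        D, _, _ = pairwise_rf(digits)
        ids = [f"M{i}" for i in range(8)]
        om = order_markers(D, ids, n_restarts=20, seed=0)
        cost = D[om.order[:-1], om.order[1:]].sum()
        best_cost = min(D[np.array(p)[:-1], np.array(p)[1:]].sum()
                        for p in itertools.permutations(range(8)))
        assert cost == pytest.approx(best_cost, abs=1e-12)
        tau = abs(kendalltau(om.order, np.arange(8)).statistic)
        assert tau == pytest.approx(1.0)

    def test_recovers_truth_on_error_free_data(self, rng):
        positions = np.array([0.0, 10.0, 20.0, 30.0])
        digits = self._simulate_digits(positions, 200, rng)
        D, _, _ = pairwise_rf(digits)
        om = order_markers(D, [f"M{i}" for i in range(4)], n_restarts=20, seed=1)
        tau = abs(kendalltau(om.order, np.arange(4)).statistic)
        assert tau == pytest.approx(1.0)

    def test_two_markers_distance_is_map_image(self):
        digits = np.array([[1] * 10, [1] * 8 + [2] * 2], dtype=np.int8)
        D, _, _ = pairwise_rf(digits)
        om = order_markers(D, ["A", "B"], n_restarts=1, seed=0)
        assert om.cm_male[-1] == pytest.approx(haldane_cm(0.2))

    def test_all_uninformative_warns_and_keeps_order(self):
        D = np.full((3, 3), 0.5)
        np.fill_diagonal(D, 0.0)
        with pytest.warns(UserWarning, match="uninformative"):
            om = order_markers(D, ["A", "B", "C"], n_restarts=2, seed=0)
        assert list(om.order) == [0, 1, 2]
        assert np.all(om.cm_male == 0)

    def test_map_length_reversal_invariant(self, rng):
        positions = np.array([0.0, 5.0, 12.0, 20.0, 31.0, 40.0])
        digits = self._simulate_digits(positions, 150, rng)
        D, _, _ = pairwise_rf(digits)
        ids = [f"M{i}" for i in range(6)]
        om1 = order_markers(D, ids, n_restarts=10, seed=0)
        rev = np.arange(6)[::-1]
        om2 = order_markers(D[np.ix_(rev, rev)], [ids[i] for i in rev],
                            n_restarts=10, seed=0)
        assert om1.cm_male[-1] == pytest.approx(om2.cm_male[-1], abs=1e-9)
        assert om1.cm_avg[0] == 0.0


class TestPruneByLod:
    def test_equal_scores_none_removed(self):
        [mask] = prune_by_lod([np.array([1.0, 1.0, 1.0])])
        assert not mask.any()

    def test_outlier_removed(self):
        [mask] = prune_by_lod([np.array([0.9, 0.9, 0.9, 0.0])])
        assert mask.tolist() == [False, False, False, True]

    def test_two_close_scores_kept(self):
        [mask] = prune_by_lod([np.array([0.5, 0.6])])
        assert not mask.any()

    def test_single_snp_never_removed(self):
        [mask] = prune_by_lod([np.array([0.01])])
        assert not mask.any()


class TestContigConflicts:
    def _map(self, rows):
        return pd.DataFrame(rows, columns=["marker_id", "contig_id", "lg",
                                           "cm_male", "cm_female", "cm_avg"])

    def test_small_split_contig_fully_removed(self):
        rows = [(f"m{i}", "tigA", 1 if i < 6 else 2, 0.0, 0.0, 0.0) for i in range(10)]
        kept, log = resolve_contig_conflicts(self._map(rows))
        assert len(kept) == 0
        assert log["small_split_contig"] == ["tigA"]

    def test_minor_fraction_removed_majority_kept(self):
        rows = [(f"m{i}", "tigB", 1 if i < 95 else 2, 0.0, 0.0, 0.0) for i in range(100)]
        kept, log = resolve_contig_conflicts(self._map(rows))
        assert len(kept) == 95 and set(kept["lg"]) == {1}
        assert log["minor_lg_fraction"] == ["tigB"]

    def test_single_lg_contig_untouched(self):
        rows = [(f"m{i}", "tigC", 3, 0.0, 0.0, 0.0) for i in range(100)]
        kept, log = resolve_contig_conflicts(self._map(rows))
        assert len(kept) == 100
        assert not any(log.values())

    def test_even_split_large_contig_removed_and_logged(self):
        rows = [(f"m{i}", "tigD", 1 if i < 10 else 2, 0.0, 0.0, 0.0) for i in range(20)]
        kept, log = resolve_contig_conflicts(self._map(rows))
        assert len(kept) == 0
        assert log["unresolved_split_contig"] == ["tigD"]


class TestSexAverageAndCodes:
    def test_sex_average_values(self):
        df = pd.DataFrame({"cm_male": [10.0, 0.0, 5.0],
                           "cm_female": [20.0, 0.0, 5.0]})
        out = sex_average(df)
        assert out["cm_avg"].tolist() == [15.0, 0.0, 5.0]

    def test_f2_code_mapping(self):
        assert to_f2_codes(["1 1", "1 2", "2 1", "2 2", "?", ""]).tolist() == \
            [0, 1, 1, 2, MISSING, MISSING]

    def test_f2_code_shape_preserved(self):
        out = to_f2_codes([["1 1", "2 2"], ["1 2", "x"]])
        assert out.shape == (2, 2)
        assert out[1, 1] == MISSING
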