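"""Genotype-probability HMM, binary scan, peaks, credible intervals and the
segregation validation."""

import itertools

import numpy as np
import pytest

from snailqtl.scan import (ScanParams, allele_effects, bayes_interval,
                           binary_scan, calc_genoprob, candidate_region,
                           find_peaks, permutation_threshold,
                           segregation_check)
from snailqtl.sim import (MISSING, CrossConfig, TraitLocus, haldane_r,
                          simulate_cross)
from snailqtl.linkage import infer_transmissions


def genoprob_oracle(positions, codes, eps):
    """Brute-force posterior by enumerating all hidden genotype paths."""
    codes = np.atleast_2d(codes)
    P = len(positions)
    T = []
    for d in np.diff(positions):
        r = haldane_r(d)
        s, t = 1 - r, r
        T.append(np.array([[s * s, 2 * s * t, t * t],
                           [s * t, s * s + t * t, s * t],
                           [t * t, 2 * s * t, s * s]]))
    pi = np.array([0.25, 0.5, 0.25])
    out = np.zeros((codes.shape[0], P, 3))
    for ind, obs in enumerate(codes):
        for path in itertools.product(range(3), repeat=P):
            p = pi[path[0]]
            for t in range(1, P):
                p *= T[t - 1][path[t - 1], path[t]]
            for t in range(P):
                if obs[t] != MISSING:
                    p *= (1 - eps) if obs[t] == path[t] else eps / 2
            for t in range(P):
                out[ind, t, path[t]] += p
        out[ind] /= out[ind].sum(axis=-1, keepdims=True)
    return out


class TestCalcGenoprob:
    def test_error_free_observation_is_certain(self):
        probs = calc_genoprob([0.0, 10.0], [[0, 2]], error_prob=0.0)
        assert probs[0, 0].tolist() == [1.0, 0.0, 0.0]
        assert probs[0, 1].tolist() == [0.0, 0.0, 1.0]

    @pytest.mark.parametrize("eps", [0.002, 0.05])
    @pytest.mark.parametrize("obs", [[0, 2], [1, MISSING], [2, 1]])
    def test_two_marker_chain_matches_enumeration(self, eps, obs):
        pos = [0.0, 12.5]
        got = calc_genoprob(pos, [obs], error_prob=eps)
        want = genoprob_oracle(pos, [obs], eps)
        assert got == pytest.approx(want, abs=1e-12)

    def test_chains_up_to_four_markers_match_enumeration(self, rng):
        pos = np.array([0.0, 3.0, 9.5, 14.0])
        for _ in range(20):
            obs = rng.integers(-1, 3, size=4).astype(np.int8)
            got = calc_genoprob(pos, [obs], error_prob=0.002)
            want = genoprob_oracle(pos, [obs], 0.002)
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_flanked_at_zero_distance(self):
        probs = calc_genoprob([5.0, 5.0, 5.0], [[0, MISSING, 0]], error_prob=0.0)
        assert probs[0, 1, 0] == pytest.approx(1.0)

    def test_rows_normalised(self, rng):
        pos = np.sort(rng.uniform(0, 50, size=12))
        codes = rng.integers(-1, 3, size=(30, 12)).astype(np.int8)
        probs = calc_genoprob(pos, codes, error_prob=0.01)
        assert probs.sum(axis=-1) == pytest.approx(np.ones((30, 12)), abs=1e-9)
        assert (probs >= 0).all()

    def test_unordered_map_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            calc_genoprob([10.0, 0.0], [[0, 0]], 0.002)


class TestBinaryScan:
    def test_no_genotype_information_gives_zero(self):
        probs = np.tile([0.25, 0.5, 0.25], (20, 5, 1))
        y = np.array([0, 1] * 10)
        lod = binary_scan(probs, y)
        assert lod == pytest.approx(np.zeros(5), abs=1e-6)

    def test_perfect_separation_saturates(self):
        # 5 affected BB vs 5 unaffected AA: saturated likelihood vs 0.5^10
        probs = np.zeros((10, 1, 3))
        probs[:5, 0, 2] = 1.0
        probs[5:, 0, 0] = 1.0
        y = np.array([1] * 5 + [0] * 5)
        lod = binary_scan(probs, y)
        assert lod[0] == pytest.approx(10 * np.log10(2), abs=1e-3)

    def test_matches_statsmodels_without_separation(self, rng):
        import statsmodels.api as sm

        probs = rng.dirichlet([1, 1, 1], size=(40, 3)).reshape(40, 3, 3)
        y = rng.integers(0, 2, size=40)
        lod = binary_scan(probs, y)
        for p in range(3):
            X = sm.add_constant(probs[:, p, 1:])
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, np.ones((40, 1)), family=sm.families.Binomial()).fit()
            want = (full.llf - null.llf) / np.log(10)
            assert lod[p] == pytest.approx(max(want, 0.0), abs=1e-5)

    def test_single_class_warns(self):
        probs = np.tile([0.25, 0.5, 0.25], (6, 2, 1))
        with pytest.warns(UserWarning, match="single class"):
            lod = binary_scan(probs, np.zeros(6))
        assert (lod == 0).all()

    def test_argmax_near_true_locus(self):
        # fully penetrant locus at 20 cM on a 40 cM group; 100 replicates.
        # n = 150 meioses-per-parent: the merged AB class hides half the
        # transmissions, so this is where argmax localisation to 5 cM is
        # supported by the two-point information content.
        hits = 0
        for rep in range(100):
            cfg = CrossConfig(seed=1000 + rep, n_offspring=150,
                              lg_lengths_cm=[40.0], markers_per_lg=[40],
                              genotyping_error=0.0, missing_rate=0.0,
                              both_parent_het_fraction=1.0)
            ds = simulate_cross(cfg, [TraitLocus("T", 1, 20.0, dominant_phenotype=0)])
            off = [s for s in ds.calls.samples if s.startswith("O")]
            trans = infer_transmissions(ds.calls, off)
            pos = ds.calls.markers["cm_pos"].to_numpy()
            probs = calc_genoprob(pos, trans.f2.T, 0.002)
            y = ds.phenotypes.set_index("individual_id")["value"].loc[off].to_numpy(float)
            lod = binary_scan(probs, y)
            hits += abs(pos[np.argmax(lod)] - 20.0) <= 5.0
        assert hits >= 95


class TestPermutationThreshold:
    def _probs_y(self, rng, n=40, P=6):
        codes = rng.integers(0, 3, size=(n, P)).astype(np.int8)
        probs = calc_genoprob(np.linspace(0, 50, P), codes, 0.002)
        return probs, rng.integers(0, 2, size=n).astype(float)

    def test_threshold_finite_nonnegative(self, rng):
        probs, y = self._probs_y(rng)
        thr = permutation_threshold(probs, y, ScanParams(n_perm=50, seed=0))
        assert np.isfinite(thr) and thr >= 0

    def test_alpha_one_gives_minimum(self, rng):
        probs, y = self._probs_y(rng)
        params = ScanParams(n_perm=25, alpha=1.0, seed=3)
        thr = permutation_threshold(probs, y, params)
        params2 = ScanParams(n_perm=25, alpha=0.04, seed=3)
        assert thr <= permutation_threshold(probs, y, params2)

    def test_seeded_reproducibility(self, rng):
        probs, y = self._probs_y(rng)
        p = ScanParams(n_perm=30, seed=9)
        assert permutation_threshold(probs, y, p) == permutation_threshold(probs, y, p)


class TestFindPeaks:
    def test_single_bump(self):
        lod = np.array([0.0, 1.0, 5.0, 1.0, 0.0])
        peaks = find_peaks(lod, threshold=4.0)
        assert len(peaks) == 1 and peaks[0].index == 2

    def test_deep_valley_separates(self):
        peaks = find_peaks(np.array([5.0, 2.9, 5.0]), threshold=4.0, peakdrop=1.8)
        assert [p.index for p in peaks] == [0, 2]

    def test_shallow_valley_merges(self):
        peaks = find_peaks(np.array([5.0, 4.0, 5.0]), threshold=4.0, peakdrop=1.8)
        assert len(peaks) == 1

    def test_below_threshold_ignored(self):
        assert find_peaks(np.array([1.0, 2.0, 1.0]), threshold=4.0) == []


class TestBayesInterval:
    def test_point_mass_zero_width(self):
        lod = np.array([0.0, 12.0, 0.0])
        ci = bayes_interval(lod, [0.0, 5.0, 10.0], peak_index=1)
        assert (ci.start_cm, ci.end_cm) == (5.0, 5.0)

    def test_matches_enumeration_oracle(self, rng):
        pos = np.array([0.0, 2.0, 5.0, 9.0, 14.0])
        for _ in range(25):
            lod = rng.uniform(0, 4, size=5)
            peak = int(np.argmax(lod))
            ci = bayes_interval(lod, pos, peak, ci_prob=0.9)
            mass = 10.0 ** (lod - lod.max())
            mass /= mass.sum()
            feasible = [(j - i, pos[j] - pos[i], i, j)
                        for i in range(5) for j in range(i, 5)
                        if i <= peak <= j and mass[i:j + 1].sum() >= 0.9 - 1e-12]
            _, _, i, j = min(feasible)
            assert (ci.lo_index, ci.hi_index) == (i, j)

    def test_wider_probability_never_shrinks(self, rng):
        pos = np.linspace(0, 20, 8)
        lod = rng.uniform(0, 3, size=8)
        peak = int(np.argmax(lod))
        widths = []
        for cp in (0.5, 0.8, 0.95, 0.99):
            ci = bayes_interval(lod, pos, peak, cp)
            widths.append(ci.hi_index - ci.lo_index)
        assert widths == sorted(widths)


class TestAlleleEffects:
    def test_independent_trait_equal_effects(self, rng):
        probs = np.tile([0.25, 0.5, 0.25], (40, 4, 1))
        y = np.array([0, 1] * 20, dtype=float)
        eff = allele_effects(probs, y)
        assert np.ptp(eff) < 1e-3

    def test_penetrant_recessive_bb_sign_pattern(self):
        # all BB affected, AA/AB unaffected: BB effect high, AA/AB low
        n = 60
        codes = np.array([2] * 20 + [1] * 20 + [0] * 20, dtype=np.int8)
        probs = np.zeros((n, 1, 3))
        probs[np.arange(n), 0, codes] = 1.0
        y = (codes == 2).astype(float)
        eff = allele_effects(probs, y)[0]
        assert eff[2] > eff[1] and eff[2] > eff[0]
        assert abs(eff[1] - eff[0]) < 5.0 < eff[2] - eff[0]


class TestSegregationCheck:
    def test_two_incompatible_homozygotes(self):
        codes = np.array([[0], [0], [1], [2], [2]], dtype=np.int8)
        y = np.array([1, 1, 0, 1, 1])  # two label-1 individuals coded AA
        res = segregation_check(codes, y, label1_homozygote=2)
        assert res["violations"].tolist() == [2]
        assert not res["consistent"][0]

    def test_perfect_pattern_consistent(self):
        codes = np.array([[2], [2], [1], [1], [0]], dtype=np.int8)
        y = np.array([1, 1, 1, 0, 0])
        res = segregation_check(codes, y, label1_homozygote=2)
        assert res["violations"][0] == 0 and bool(res["consistent"][0])

    def test_heterozygotes_exempt(self):
        codes = np.ones((6, 1), dtype=np.int8)
        y = np.array([0, 1, 0, 1, 0, 1])
        res = segregation_check(codes, y, label1_homozygote=2)
        assert res["violations"][0] == 0 and bool(res["consistent"][0])

    def test_all_missing_uninformative(self):
        codes = np.full((4, 1), MISSING, dtype=np.int8)
        y = np.array([0, 1, 0, 1])
        res = segregation_check(codes, y)
        assert not res["informative"][0] and not res["consistent"][0]


class TestCandidateRegion:
    def test_colour_region_width(self):
        region = candidate_region([31.385, 32.056, 32.727])
        assert region["width_cm"] == pytest.approx(1.3)

    def test_midband_region_width(self):
        region = candidate_region([39.511, 40.182])
        assert region["width_cm"] == pytest.approx(0.7)

    def test_single_position_zero_width(self):
        region = candidate_region([12.0])
        assert region["width_cm"] == 0.0

    def test_empty_not_localised(self):
        region = candidate_region([])
        assert not region["localized"]

    def test_contig_union(self):
        region = candidate_region([1.0, 2.0], {1.0: {"tigA"}, 2.0: {"tigA", "tigB"}})
        assert region["contigs"] == ["tigA", "tigB"]
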