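"""Adaptive P-value combination: scores, permutation adjustment, exact mode."""

import numpy as np
import pytest
from scipy import stats

from famada.ada import DEFAULT_THRESHOLDS, ada_test, significance_scores
from famada.errors import ConfigurationError, NoTestError
from famada.kinship import kinship_matrix
from famada.pedio import HaplotypeSet, Individual, Pedigree, Site, TraitTable

from conftest import make_haps


class TestScores:
    def test_all_pvalues_above_max_threshold(self):
        p = np.array([0.6, 0.9, 0.51])
        s = significance_scores(p, np.ones(3, bool), (0.05, 0.5))
        assert (s == 0).all()

    def test_single_site(self):
        s = significance_scores(np.array([0.01]), np.array([True]), (0.05,))
        assert s[0] == pytest.approx(-np.log(0.01))
        assert s[0] == pytest.approx(4.6052, abs=1e-4)

    def test_hand_example_two_thresholds(self):
        p = np.array([0.04, 0.06, 0.5])
        s = significance_scores(p, np.ones(3, bool), (0.05, 0.10))
        assert s[0] == pytest.approx(-np.log(0.04))
        assert s[1] == pytest.approx(-np.log(0.04) - np.log(0.06))
        assert s == pytest.approx([3.2189, 6.0323], abs=1e-4)

    def test_strict_inequality_at_threshold(self):
        s = significance_scores(np.array([0.05]), np.array([True]), (0.05,))
        assert s[0] == 0.0

    def test_invalid_sites_never_contribute(self):
        p = np.array([1e-9, 0.01])
        s = significance_scores(p, np.array([False, True]), (0.05,))
        assert s[0] == pytest.approx(-np.log(0.01))

    def test_scores_nondecreasing_in_threshold(self, rng):
        p = rng.random(40)
        s = significance_scores(p, np.ones(40, bool), DEFAULT_THRESHOLDS)
        assert (np.diff(s) >= 0).all()

    def test_batch_matches_rowwise(self, rng):
        p = rng.random((6, 15))
        v = rng.random(15) > 0.2
        batch = significance_scores(p, v, (0.05, 0.2, 0.5))
        rows = np.stack([
            significance_scores(p[i], v, (0.05, 0.2, 0.5)) for i in range(6)
        ])
        assert batch == pytest.approx(rows)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            significance_scores(np.array([0.5]), np.array([True]), ())


def many_trios(n: int) -> Pedigree:
    members = []
    for k in range(n):
        fam = f"T{k}"
        members += [
            Individual(fam, "1", None, None, 1),
            Individual(fam, "2", None, None, 2),
            Individual(fam, "3", "1", "2", 1),
        ]
    return Pedigree(members)


def strong_signal_dataset(n_trios=80):
    """Trios with het x hom parents; trait equals the child's genotype, so
    the observed association is essentially unbeatable by permutation."""
    ped = many_trios(n_trios)
    haps = np.zeros((ped.n, 2, 1), dtype=np.uint8)
    y = np.zeros(ped.n)
    for k in range(n_trios):
        haps[3 * k, 1, 0] = 1  # father 0|1
        child_allele = k % 2
        haps[3 * k + 2, 0, 0] = child_allele
        y[3 * k + 2] = child_allele
    sites = [Site("s0", 1)]
    return ped, HaplotypeSet(sites, haps), TraitTable(trait=y)


class TestAdaTest:
    def test_extreme_rank_gives_one_over_b_plus_one(self):
        ped, hap, traits = strong_signal_dataset()
        res = ada_test(ped, hap, traits, B=100, seed=5)
        assert res.adjusted_pvalue == pytest.approx(1 / 101)

    def test_determinism(self):
        ped, hap, traits = strong_signal_dataset(20)
        a = ada_test(ped, hap, traits, B=150, seed=77)
        b = ada_test(ped, hap, traits, B=150, seed=77)
        assert a.adjusted_pvalue == b.adjusted_pvalue
        assert a.scores == pytest.approx(b.scores)
        assert a.per_threshold_pvalues == pytest.approx(b.per_threshold_pvalues)

    def test_neutral_monomorphic_sites_leave_result_unchanged(self):
        """Appending founder-monomorphic sites (P = 1 > max theta) changes
        neither the scores nor the adjusted P-value."""
        ped, hap, traits = strong_signal_dataset(30)
        base = ada_test(ped, hap, traits, B=120, seed=3)
        padded_haps = np.concatenate(
            [hap.haps, np.zeros((ped.n, 2, 4), dtype=np.uint8)], axis=2
        )
        padded = HaplotypeSet(
            hap.sites + [Site(f"mono{k}") for k in range(4)], padded_haps
        )
        res = ada_test(ped, padded, traits, B=120, seed=3)
        assert res.scores == pytest.approx(base.scores)
        assert res.adjusted_pvalue == base.adjusted_pvalue
        assert res.n_valid_sites == base.n_valid_sites

    def test_site_order_invariance(self, rng):
        """Permuting site columns leaves the adjusted P-value unchanged."""
        ped = many_trios(40)
        haps = rng.integers(0, 2, size=(ped.n, 2, 6), dtype=np.uint8)
        hap = HaplotypeSet([Site(f"s{l}") for l in range(6)], haps)
        traits = TraitTable(trait=rng.normal(size=ped.n))
        base = ada_test(ped, hap, traits, B=150, seed=9)
        order = rng.permutation(6)
        shuffled = HaplotypeSet(
            [hap.sites[o] for o in order], haps[:, :, order]
        )
        res = ada_test(ped, shuffled, traits, B=150, seed=9)
        assert res.adjusted_pvalue == base.adjusted_pvalue
        assert res.minp_observed == base.minp_observed

    def test_single_threshold_reduction(self):
        """With J = 1 the adjustment reduces to the plain permutation rank of
        the single-threshold score."""
        ped, hap, traits = strong_signal_dataset(25)
        res = ada_test(
            ped, hap, traits, B=200, seed=21, thresholds=(0.2,),
            keep_permutations=True,
        )
        pv_obs = (res.perm_scores[:, 0] >= res.scores[0]).sum() / res.B
        # replicate ranks on the exchangeable common scale
        allS = np.concatenate([[res.scores[0]], res.perm_scores[:, 0]])
        pv_all = np.array([(np.delete(allS, i) >= allS[i]).mean()
                           for i in range(allS.size)])
        expect = (1 + (pv_all[1:] <= pv_all[0]).sum()) / (res.B + 1)
        assert res.minp_observed == pytest.approx(pv_obs)
        assert res.adjusted_pvalue == pytest.approx(expect)

    def test_all_monomorphic_raises(self, trio_ped):
        hap = make_haps(trio_ped, {
            "1": ((0,), (0,)), "2": ((0,), (0,)), "3": ((0,), (0,)),
        })
        with pytest.raises(NoTestError):
            ada_test(
                trio_ped, hap, TraitTable(trait=np.array([1.0, 0.0, 0.0])),
                B=100, seed=1,
            )

    def test_small_b_rejected(self):
        ped, hap, traits = strong_signal_dataset(10)
        with pytest.raises(ConfigurationError):
            ada_test(ped, hap, traits, B=50, seed=1)

    def test_early_stop_returns_larger_null_pvalue(self, rng):
        """Sequential stopping on a null dataset finishes early and still
        reports a clearly non-significant adjusted P-value."""
        ped = many_trios(30)
        haps = rng.integers(0, 2, size=(ped.n, 2, 5), dtype=np.uint8)
        hap = HaplotypeSet([Site(f"s{l}") for l in range(5)], haps)
        traits = TraitTable(trait=rng.normal(size=ped.n))
        res = ada_test(ped, hap, traits, B=2000, seed=4, early_stop_count=100)
        assert res.B < 2000
        assert res.adjusted_pvalue > 0.04


class TestExhaustiveOracle:
    def test_trio_matches_hand_enumeration(self, trio_ped):
        """One informative meiosis: the exhaustive-permutation ADA P-value
        equals the exact P computed by hand over the two-point law."""
        hap = make_haps(trio_ped, {
            "1": ((0,), (1,)), "2": ((0,), (0,)), "3": ((1,), (0,)),
        })
        y = np.array([1.0, 0.0, 1.0])
        traits = TraitTable(trait=y)
        res = ada_test(trio_ped, hap, traits, exhaustive=True)

        # --- independent hand computation ---------------------------------
        km = kinship_matrix(trio_ped)
        r = y - y.mean()
        rPr = r @ km.Phi @ r
        p_hat = 0.25  # founder haplotypes 0,1,0,0
        stats_by_g = {}
        for g_child in (0, 1):
            g = np.array([1.0, 0.0, g_child])
            T = (r @ g) ** 2 / (2 * p_hat * (1 - p_hat) * rPr)
            stats_by_g[g_child] = stats.chi2.sf(T, df=1)
        # child outcomes 0 and 1 each carry exact probability 1/2
        pv = {g: p for g, p in stats_by_g.items()}
        th = np.asarray(DEFAULT_THRESHOLDS)
        S = {g: np.where(pv[g] < th, -np.log(pv[g]), 0.0) for g in (0, 1)}
        S_obs = S[1]  # observed child genotype score is 1
        # per-threshold exact P: mass of patterns with S >= S_obs
        pt = 0.5 * (S[0] >= S_obs) + 0.5 * (S[1] >= S_obs)
        minp_obs = pt.min()
        minp = {}
        for g in (0, 1):
            ptg = 0.5 * (S[0] >= S[g]) + 0.5 * (S[1] >= S[g])
            minp[g] = ptg.min()
        adjusted = 0.5 * (minp[0] <= minp_obs) + 0.5 * (minp[1] <= minp_obs)

        assert res.scores == pytest.approx(S_obs)
        assert res.per_threshold_pvalues == pytest.approx(pt)
        assert res.minp_observed == pytest.approx(minp_obs)
        assert res.adjusted_pvalue == pytest.approx(adjusted)

    def test_exhaustive_probabilities_sum_to_one(self, trio_ped):
        hap = make_haps(trio_ped, {
            "1": ((0,), (1,)), "2": ((0,), (1,)), "3": ((0,), (1,)),
        })
        res = ada_test(
            trio_ped, hap, TraitTable(trait=np.array([2.0, 0.0, 1.0])),
            exhaustive=True,
        )
        assert 0 < res.adjusted_pvalue <= 1
        assert res.B == 4 ** 1
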