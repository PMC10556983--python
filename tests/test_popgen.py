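"""pi / D_XY / Weir-Cockerham F_ST: hand enumerations, formula oracle,
all-sites accounting, feature aggregation, gene-set contrasts."""

import numpy as np
import pandas as pd
import pytest

import qpt
from qpt.genio import MISSING, GenotypeMatrix, SiteCallMatrix
from qpt.popgen import (compare_gene_sets, dxy_site_sums, dxy_window,
                        feature_stats, fst_wc_window, make_windows,
                        pi_site_sums, pi_window, wc_components)

from oracles import dxy_pairwise, pi_pairwise, wc_components_site


def sites_from_alt(alt, called=None, clusters=None):
    alt = np.asarray(alt, dtype=np.int16)
    n, L = alt.shape
    called = (np.asarray(called, dtype=np.int16) if called is not None
              else np.full((n, L), 2, dtype=np.int16))
    return SiteCallMatrix(samples=[f"s{i}" for i in range(n)],
                          chrom=np.full(L, "Chr01", dtype=object),
                          pos=np.arange(1, L + 1), called=called, alt=alt,
                          clusters=(np.asarray(clusters, dtype=object)
                                    if clusters is not None else None))


def geno_from_dosage(dosage, clusters=None):
    dosage = np.asarray(dosage, dtype=np.int16)
    n, L = dosage.shape
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                          chrom=np.full(L, "Chr01", dtype=object),
                          pos=np.arange(1, L + 1),
                          ref=np.full(L, "A", dtype=object),
                          alt=np.full(L, "T", dtype=object), dosage=dosage,
                          clusters=(np.asarray(clusters, dtype=object)
                                    if clusters is not None else None))


class TestPi:
    def test_hand_enumeration_example(self):
        # 2 diploids, 1 variant site (dosages 0, 2) + 9 invariant sites
        alt = np.zeros((2, 10), dtype=int)
        alt[1, 0] = 2
        sites = sites_from_alt(alt)
        w = make_windows({"Chr01": 10}, 10)
        pi = pi_window(sites, np.array([True, True]), w)
        assert np.isclose(pi["pi"].iloc[0], 4 / 60)
        assert pi["diff_sum"].iloc[0] == 4 and pi["comp_sum"].iloc[0] == 60

    def test_masked_sample_recomputed(self):
        # masking one diploid at the variant site leaves 1 diploid:
        # comps = C(2,2) = 1, diffs = 0 at that site
        alt = np.zeros((2, 1), dtype=int)
        alt[1, 0] = 2
        called = np.full((2, 1), 2)
        called[1, 0] = 0
        alt[1, 0] = 0
        sites = sites_from_alt(alt, called)
        d, c = pi_site_sums(sites, np.array([True, True]))
        assert d[0] == 0 and c[0] == 1

    def test_all_invariant_zero(self):
        sites = sites_from_alt(np.zeros((3, 20), dtype=int))
        w = make_windows({"Chr01": 20}, 20)
        assert pi_window(sites, np.ones(3, bool), w)["pi"].iloc[0] == 0.0

    def test_matches_pair_enumeration_oracle(self, rng):
        alt = rng.integers(0, 3, size=(5, 30))
        miss = rng.random((5, 30)) < 0.2
        called = np.where(miss, 0, 2)
        alt = np.where(miss, 0, np.minimum(alt, 2))
        sites = sites_from_alt(alt, called)
        d, c = pi_site_sums(sites, np.ones(5, bool))
        allele_lists = []
        for j in range(30):
            al = []
            for i in range(5):
                if called[i, j]:
                    al += ([1] * alt[i, j] + [0] * (2 - alt[i, j]))
            allele_lists.append(al)
        assert np.isclose(d.sum() / c.sum(), pi_pairwise(allele_lists))

    def test_zero_comparison_window_missing_not_zero(self):
        sites = sites_from_alt(np.zeros((2, 5), dtype=int),
                               called=np.zeros((2, 5), dtype=int))
        w = make_windows({"Chr01": 5}, 5)
        assert np.isnan(pi_window(sites, np.ones(2, bool), w)["pi"].iloc[0])

    def test_adding_invariant_sites_scales_by_comparisons(self):
        alt = np.zeros((2, 1), dtype=int)
        alt[1, 0] = 2
        small = sites_from_alt(alt)
        big = sites_from_alt(np.hstack([alt, np.zeros((2, 9), dtype=int)]))
        w1 = make_windows({"Chr01": 1}, 1)
        w10 = make_windows({"Chr01": 10}, 10)
        p1 = pi_window(small, np.ones(2, bool), w1)
        p10 = pi_window(big, np.ones(2, bool), w10)
        assert p1["diff_sum"].iloc[0] == p10["diff_sum"].iloc[0]
        ratio = p1["comp_sum"].iloc[0] / p10["comp_sum"].iloc[0]
        assert np.isclose(p10["pi"].iloc[0], p1["pi"].iloc[0] * ratio)
        assert p10["pi"].iloc[0] < p1["pi"].iloc[0]


class TestDxy:
    def test_hand_enumeration_example(self):
        # two pops of 2 diploids; 1 of 10 sites fixed different
        alt = np.zeros((4, 10), dtype=int)
        alt[2:, 0] = 2
        sites = sites_from_alt(alt, clusters=["p1", "p1", "p2", "p2"])
        w = make_windows({"Chr01": 10}, 10)
        dxy = dxy_window(sites, "p1", "p2", w)
        assert np.isclose(dxy["dxy"].iloc[0], 16 / 160)
        assert dxy["diff_sum"].iloc[0] == 16
        assert dxy["comp_sum"].iloc[0] == 160

    def test_identical_monomorphic_pops_zero(self):
        sites = sites_from_alt(np.zeros((4, 8), dtype=int),
                               clusters=["p1", "p1", "p2", "p2"])
        w = make_windows({"Chr01": 8}, 8)
        assert dxy_window(sites, "p1", "p2", w)["dxy"].iloc[0] == 0.0

    def test_symmetric_in_pop_order(self, rng):
        alt = rng.integers(0, 3, size=(6, 40))
        sites = sites_from_alt(alt, clusters=["a"] * 3 + ["b"] * 3)
        w = make_windows({"Chr01": 40}, 40)
        ab = dxy_window(sites, "a", "b", w)["dxy"].iloc[0]
        ba = dxy_window(sites, "b", "a", w)["dxy"].iloc[0]
        assert np.isclose(ab, ba)

    def test_matches_pair_enumeration_oracle(self, rng):
        alt = rng.integers(0, 3, size=(6, 25))
        miss = rng.random((6, 25)) < 0.15
        called = np.where(miss, 0, 2)
        alt = np.where(miss, 0, alt)
        sites = sites_from_alt(alt, called)
        m1 = np.array([True] * 3 + [False] * 3)
        d, c = dxy_site_sums(sites, m1, ~m1)
        a1, a2 = [], []
        for j in range(25):
            a1.append([x for i in range(3) if called[i, j]
                       for x in [1] * alt[i, j] + [0] * (2 - alt[i, j])])
            a2.append([x for i in range(3, 6) if called[i, j]
                       for x in [1] * alt[i, j] + [0] * (2 - alt[i, j])])
        assert np.isclose(d.sum() / c.sum(), dxy_pairwise(a1, a2))

    def test_dxy_pop_with_itself_equals_pi_up_to_self_pairs(self, rng):
        """D_XY(pop, pop) equals pi(pop) * (n-1)/n exactly: the between-
        population comparison pairs every allele with every allele of the
        second copy including itself, so only the self-pair terms differ."""
        alt = rng.integers(0, 3, size=(8, 2000))
        sites = sites_from_alt(alt)
        m = np.ones(8, bool)
        dp, cp = pi_site_sums(sites, m)
        dd, cd = dxy_site_sums(sites, m, m)
        n_alleles = 16
        assert np.isclose(dd.sum() / cd.sum(),
                          dp.sum() / cp.sum() * (n_alleles - 1) / n_alleles,
                          rtol=1e-12)


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        d = np.array([[2, 2], [2, 2], [0, 0], [0, 0]])
        g = geno_from_dosage(d, clusters=["a", "a", "b", "b"])
        w = make_windows({"Chr01": 2}, 2)
        theta = fst_wc_window(g, "a", "b", w)["fst"].iloc[0]
        assert np.isclose(theta, 1.0)

    def test_null_split_mean_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, size=2000)
        d = rng.binomial(2, p, size=(100, 2000))
        g = geno_from_dosage(d, clusters=["a"] * 50 + ["b"] * 50)
        w = make_windows({"Chr01": 2000}, 2000)
        theta = fst_wc_window(g, "a", "b", w)["fst"].iloc[0]
        assert abs(theta) < 0.01

    def test_components_match_formula_oracle(self, rng):
        d = rng.integers(0, 3, size=(10, 20)).astype(np.int16)
        d[rng.random((10, 20)) < 0.1] = MISSING
        g = geno_from_dosage(d)
        m1 = np.array([True] * 5 + [False] * 5)
        a, b, c = wc_components(g, m1, ~m1)
        for j in range(20):
            g1 = [int(x) for x in d[:5, j] if x != MISSING]
            g2 = [int(x) for x in d[5:, j] if x != MISSING]
            ref = wc_components_site(g1, g2)
            if ref is None or not (min(len(g1), len(g2)) > 0):
                continue
            if np.isnan(a[j]):
                continue
            assert abs(a[j] - ref[0]) < 1e-12
            assert abs(b[j] - ref[1]) < 1e-12
            assert abs(c[j] - ref[2]) < 1e-12

    def test_window_is_ratio_of_sums_not_mean_of_ratios(self, rng):
        d = rng.integers(0, 3, size=(20, 50)).astype(np.int16)
        g = geno_from_dosage(d, clusters=["a"] * 10 + ["b"] * 10)
        w = make_windows({"Chr01": 50}, 50)
        res = fst_wc_window(g, "a", "b", w)
        a, b, c = wc_components(g, np.arange(20) < 10, np.arange(20) >= 10)
        tot = a + b + c
        ok = np.isfinite(tot) & (tot != 0)
        ratio_of_sums = np.nansum(a[ok]) / np.nansum(tot[ok])
        mean_of_ratios = np.nanmean(a[ok] / tot[ok])
        assert np.isclose(res["fst"].iloc[0], ratio_of_sums)
        assert not np.isclose(ratio_of_sums, mean_of_ratios, atol=1e-6)

    def test_absent_population_missing_value(self):
        d = np.array([[0, 2], [2, 0]])
        g = geno_from_dosage(d, clusters=["a", "a"])
        w = make_windows({"Chr01": 2}, 2)
        res = fst_wc_window(g, "a", "b", w)
        assert np.isnan(res["fst"].iloc[0])


class TestFeatureStats:
    @pytest.fixture
    def setup(self):
        alt = np.zeros((4, 40), dtype=int)
        alt[2:, 4] = 2  # fixed difference at pos 5 (0-based 4)
        sites = sites_from_alt(alt, clusters=["p1", "p1", "p2", "p2"])
        g = geno_from_dosage(alt[:, [4]], clusters=["p1", "p1", "p2", "p2"])
        g.pos = np.array([5])
        features = pd.DataFrame({
            "gene": ["gA", "gA", "gB"],
            "feature": ["CDS", "CDS", "CDS"],
            "chrom": "Chr01",
            "start": [0, 20, 30],
            "end": [10, 25, 40]})
        return sites, g, features

    def test_cds_dxy_hand_value(self, setup):
        sites, g, features = setup
        res = feature_stats(sites, g, features, {"p1": "p1", "p2": "p2"})
        row = res[(res["gene"] == "gA") & (res["stat"] == "dxy")]
        # gA CDS covers 15 sites incl. the fixed difference: 16/(16*15)
        assert np.isclose(row["value"].iloc[0], 16 / 240)

    def test_no_called_sites_missing(self, setup):
        sites, g, features = setup
        res = feature_stats(sites, g, features, {"p1": "p1", "p2": "p2"})
        row = res[(res["gene"] == "gB") & (res["stat"] == "fst")]
        assert np.isnan(row["value"].iloc[0])  # no variant site in gB

    def test_feature_equal_to_window_matches_window_stat(self, setup):
        sites, g, features = setup
        whole = pd.DataFrame({"gene": ["all"], "feature": ["gene"],
                              "chrom": "Chr01", "start": [0], "end": [40]})
        res = feature_stats(sites, g, whole, {"p1": "p1", "p2": "p2"})
        w = make_windows({"Chr01": 40}, 40)
        dxy = dxy_window(sites, "p1", "p2", w)["dxy"].iloc[0]
        row = res[res["stat"] == "dxy"]["value"].iloc[0]
        assert np.isclose(row, dxy)


class TestCompareGeneSets:
    def make_stats(self, rng, shift=0.0, n=100):
        genes = [f"g{i}" for i in range(2 * n)]
        vals = rng.normal(0.01, 0.003, size=2 * n)
        vals[:n] += shift
        return pd.DataFrame({"gene": genes, "feature": "CDS", "stat": "dxy",
                             "pops": "a~b", "value": vals,
                             "num_sum": 1, "den_sum": 1}), genes

    def test_elevated_set_detected(self, rng):
        stats, genes = self.make_stats(rng, shift=0.006)  # 2 SD effect
        res = compare_gene_sets(stats, {"CDE": genes[:100],
                                        "NDE": genes[100:]})
        assert res["p_tukey"].iloc[0] < 0.05
        assert res["mean_a"].iloc[0] > res["mean_b"].iloc[0]

    def test_null_no_systematic_signal(self, rng):
        ps = []
        for _ in range(40):
            stats, genes = self.make_stats(rng, shift=0.0, n=50)
            res = compare_gene_sets(stats, {"CDE": genes[:50],
                                            "NDE": genes[50:]})
            ps.append(res["p_anova"].iloc[0])
        assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8  # p roughly uniform

    def test_se_matches_bootstrap(self, rng):
        stats, genes = self.make_stats(rng, n=200)
        res = compare_gene_sets(stats, {"CDE": genes[:200],
                                        "NDE": genes[200:]})
        vals = stats.set_index("gene").loc[genes[:200], "value"].to_numpy()
        boots = np.array([rng.choice(vals, size=len(vals)).mean()
                          for _ in range(2000)])
        assert abs(res["se_a"].iloc[0] - boots.std(ddof=1)) < 0.2 * boots.std()

    def test_overlapping_sets_rejected(self, rng):
        stats, genes = self.make_stats(rng)
        with pytest.raises(ValueError):
            compare_gene_sets(stats, {"A": genes[:10], "B": genes[5:20]})
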