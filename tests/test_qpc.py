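"""The Q_PC selection test: projections, V_A, F tests, q-values, outliers."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import qpt
from qpt.exprtraits import TraitSet
from qpt.genio import RegionSet
from qpt.qpc import (qpc_batch, call_outliers, neutral_envelope, qpc_scan,
                     qpc_test, qvalues)

from oracles import qpc_brute_force


class TestQpcTest:
    def test_constant_trait(self, eigen):
        res = qpc_test(np.full(eigen.n_samples, 3.14), eigen)
        assert all(r.F == 0 and r.p == 1.0 for r in res)

    def test_matches_brute_force_oracle(self, eigen, neutral_traits):
        trait = neutral_traits[:, 7]
        F_o, p_o = qpc_brute_force(trait, eigen.K, len(eigen.test_pcs),
                                   len(eigen.neutral_pcs))
        res = qpc_test(trait, eigen)
        assert np.allclose([r.F for r in res], F_o, rtol=1e-8)
        assert np.allclose([r.p for r in res], p_o, rtol=1e-8)

    def test_neutral_pvalues_uniform(self, eigen, neutral_traits):
        _, p, _, _ = qpc_batch(neutral_traits, eigen)
        rate = (p[0] < 0.05).mean()
        assert 0.035 <= rate <= 0.065
        assert st.kstest(p[0], "uniform").pvalue > 0.01

    def test_scale_equivariance(self, eigen, neutral_traits):
        z = neutral_traits[:, :20]
        F1, p1, c1, va1 = qpc_batch(z, eigen)
        F2, p2, c2, va2 = qpc_batch(z * 3.0, eigen)
        assert np.allclose(va2, 9.0 * va1, rtol=1e-10)
        assert np.allclose(F2, F1, rtol=1e-10)
        assert np.allclose(p2, p1, rtol=1e-10)

    def test_va_recovery(self, eigen, neutral_traits):
        _, _, _, va = qpc_batch(neutral_traits, eigen)
        assert abs(va.mean() - 1.0) < 0.10

    def test_power_matches_noncentral_f(self, eigen):
        ncp = 16.0
        lam1 = eigen.eigenvalues[0]
        delta = np.sqrt(ncp * lam1)
        truth = qpt.TraitTruth(va_true=1.0,
                               shifts={t: [(1, delta)] for t in range(1000)})
        z = qpt.simulate_traits(eigen, truth, 1000, seed=55)
        _, p, _, _ = qpc_batch(z, eigen)
        alpha = 0.05
        dfd = len(eigen.neutral_pcs)
        fcrit = st.f.ppf(1 - alpha, 1, dfd)
        predicted = st.ncf.sf(fcrit, 1, dfd, ncp)
        observed = (p[0] < alpha).mean()
        assert abs(observed - predicted) < 0.05

    def test_mismatched_length_rejected(self, eigen):
        with pytest.raises(ValueError):
            qpc_test(np.zeros(eigen.n_samples + 1), eigen)


class TestQvalues:
    def test_bh_equality_on_worked_example(self):
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        q = qvalues(np.ones(50))
        assert np.allclose(q, 1.0)

    def test_monotone_in_p(self, rng):
        for _ in range(20):
            p = rng.random(200) ** rng.uniform(0.5, 2)
            q = qvalues(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_shrinks_q_under_signal(self, rng):
        p = np.concatenate([rng.random(2000),
                            rng.random(500) * 1e-4])
        q_storey = qvalues(p)
        q_bh = qvalues(p, pi0=1.0)
        assert np.all(q_storey <= q_bh + 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.2]))


def trait_set(eigen, Z, genes=None):
    genes = genes or [f"g{i}" for i in range(Z.shape[1])]
    Zc = Z - Z.mean(axis=0)
    return TraitSet(accessions=list(eigen.samples), genes=genes,
                    constitutive=Zc, plastic=Zc.copy())


class TestQpcScan:
    @pytest.fixture
    def shifted_scan(self, eigen):
        """200 genes, the first 20 shifted along PC1 at ncp 16."""
        lam1 = eigen.eigenvalues[0]
        delta = np.sqrt(16.0 * 1.0 * lam1)
        truth = qpt.TraitTruth(va_true=1.0,
                               shifts={t: [(1, delta)] for t in range(20)})
        Z = qpt.simulate_traits(eigen, truth, 200, seed=123)
        scan = qpc_scan(trait_set(eigen, Z), eigen, which="constitutive")
        return scan

    def test_power_and_fdr_with_known_truth(self, shifted_scan):
        out = call_outliers(shifted_scan, q_threshold=0.1)
        pc1_calls = set(out["per_pc"][1])
        true_pos = {f"g{i}" for i in range(20)}
        power = len(pc1_calls & true_pos) / 20
        fdr = (len(pc1_calls - true_pos) / max(len(pc1_calls), 1))
        assert power >= 0.8
        assert fdr <= 0.2

    def test_null_scan_few_calls(self, eigen, neutral_traits):
        scan = qpc_scan(trait_set(eigen, neutral_traits[:, :300]), eigen,
                        which="plastic")
        out = call_outliers(scan, q_threshold=0.1)
        # with no signal, pi0~1 and BH at 0.1 keeps expected calls near 0;
        # bound by a generous binomial tail on 300 genes x PCs
        assert len(out["union"]) <= 12

    def test_constrained_full_cover_equals_relaxed(self, eigen,
                                                   neutral_traits):
        Z = neutral_traits[:, :50]
        ts = trait_set(eigen, Z)
        coords = pd.DataFrame({"gene": ts.genes, "chrom": "Chr01",
                               "start": np.arange(50) * 100 + 1})
        allcover = RegionSet(np.array(["Chr01"]), np.array([0]),
                             np.array([10_000_000]))
        relaxed = qpc_scan(ts, eigen, mode="relaxed")
        constrained = qpc_scan(ts, eigen, mode="constrained",
                               regions=allcover, gene_coords=coords)
        pd.testing.assert_frame_equal(relaxed.table, constrained.table)

    def test_constrained_drops_outside_genes(self, eigen, neutral_traits):
        Z = neutral_traits[:, :50]
        ts = trait_set(eigen, Z)
        coords = pd.DataFrame({"gene": ts.genes, "chrom": "Chr01",
                               "start": np.arange(50) * 100 + 1})
        half = RegionSet(np.array(["Chr01"]), np.array([0]),
                         np.array([2500]))
        scan = qpc_scan(ts, eigen, mode="constrained", regions=half,
                        gene_coords=coords)
        assert scan.n_genes == 25

    def test_constrained_needs_inputs(self, eigen, neutral_traits):
        ts = trait_set(eigen, neutral_traits[:, :5])
        with pytest.raises(ValueError):
            qpc_scan(ts, eigen, mode="constrained")


class TestOutlierCalls:
    def test_empty_scan(self, eigen, neutral_traits):
        scan = qpc_scan(trait_set(eigen, neutral_traits[:, :5]), eigen)
        scan.table["q"] = 1.0
        out = call_outliers(scan)
        assert out["union"] == [] and out["multi_pc"] == []

    def test_per_pc_membership_and_union(self, eigen, neutral_traits):
        scan = qpc_scan(trait_set(eigen, neutral_traits[:, :5]), eigen)
        t = scan.table
        t["q"] = 1.0
        t.loc[(t["gene"] == "g0") & (t["pc"] == 1), "q"] = 0.09
        t.loc[(t["gene"] == "g0") & (t["pc"] == 2), "q"] = 0.2
        t.loc[(t["gene"] == "g1") & (t["pc"].isin([1, 2])), "q"] = 0.01
        out = call_outliers(scan)
        assert "g0" in out["per_pc"][1] and "g0" not in out["per_pc"][2]
        assert out["union"] == ["g0", "g1"]
        assert out["multi_pc"] == ["g1"]


class TestNeutralEnvelope:
    def test_zero_va_zero_width(self, eigen):
        assert neutral_envelope(eigen, 0.0, pc=1) == 0.0

    def test_quadrupling_va_doubles_width(self, eigen):
        b1 = neutral_envelope(eigen, 1.0, pc=1)
        b4 = neutral_envelope(eigen, 4.0, pc=1)
        assert np.isclose(b4, 2 * b1)

    def test_exceedance_iff_significant(self, eigen, neutral_traits):
        """A trait's regression slope on u_1 exceeds the envelope slope
        exactly when its PC1 F-test rejects at the same alpha."""
        alpha = 0.05
        _, p, c, va = qpc_batch(neutral_traits, eigen)
        lam1 = eigen.eigenvalues[0]
        slopes = np.abs(c[0]) * np.sqrt(lam1)   # u_1' z_c
        b = np.array([neutral_envelope(eigen, v, pc=1, alpha=alpha)
                      for v in va])
        outside = slopes > b
        reject = p[0] < alpha
        assert np.array_equal(outside, reject)
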