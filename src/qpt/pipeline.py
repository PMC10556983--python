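"""End-to-end orchestration: simulate -> filter -> kinship -> traits ->
Q_PC -> DAPC plasticity -> windowed popgen -> ancestry -> enrichment.

A run is driven by a single RunConfig (YAML-loadable, unknown keys
rejected) and a single seed; every stage draws from its own stream of that
seed so stage-level reruns match full-run results.  All artifacts are plain
TSV/JSON with the config hash in a provenance header file, and a rerun with
an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, assoc, dapc, exprtraits, genio, kinship, qpc, synthdata
from .synthdata import SimConfig, TraitTruth

log = logging.getLogger("qpt")


@dataclass
class RunConfig:
    """Parameters of a full synthetic-study run (paper-design defaults)."""

    # synthetic design
    n_per_cluster: list = field(default_factory=lambda: [53, 22, 11])
    n_loci: int = 5000
    fst_per_cluster: list = field(default_factory=lambda: [0.22, 0.10, 0.32])
    selfing_het_rate: float = 0.01
    n_reps: int = 3
    nb_dispersion: float = 0.05
    site_effect_sd: float = 0.5
    va: float = 1.0
    n_genes: int = 200
    n_selected: int = 20
    shift_ncp: float = 16.0
    seed: int = 0
    # analysis parameters
    test_fraction: float = 0.25
    neutral_fraction: float = 0.50
    neutral_rule: str = "tail-share"
    fdr: float = 0.1
    min_mean: float = 1.0
    window: int = 20_000
    promoter_length: int = 2000
    min_variant_sites: int = 3
    n_boot: int = 10_000
    theta: float = 0.005
    missing_rate: float = 0.1
    n_orthogroups: int = 500
    p_coastal_ancestral: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim(self) -> SimConfig:
        return SimConfig(
            n_per_cluster=list(self.n_per_cluster), n_loci=self.n_loci,
            fst_per_cluster=list(self.fst_per_cluster),
            selfing_het_rate=self.selfing_het_rate, n_reps=self.n_reps,
            nb_dispersion=self.nb_dispersion,
            site_effect_sd=self.site_effect_sd, va=self.va, seed=self.seed)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_end_to_end(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline into ``outdir``; returns a summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim()
    summary = {"config_hash": config.digest(), "seed": config.seed}
    stage = "simulate-genotypes"
    try:
        geno = synthdata.simulate_genotypes(sim)
        genio.write_vcf(geno, out / "genotypes.vcf")

        stage = "kinship"
        panel, report = genio.filter_sites(geno, **genio.PRESETS["neutral-panel"])
        K = kinship.standardized_kinship(panel)
        eigen = kinship.conditional_eigen(K, samples=geno.samples,
                                          provenance=panel.provenance)
        kinship.pc_sets(eigen, config.test_fraction, config.neutral_fraction,
                        neutral_rule=config.neutral_rule)
        genio.write_matrix_tsv(K, geno.samples, geno.samples,
                               out / "kinship.tsv", index_name="sample")
        (out / "eigen.json").write_text(json.dumps({
            "eigenvalues": eigen.eigenvalues.tolist(),
            "test_pcs": (eigen.test_pcs + 1).tolist(),
            "neutral_pcs": (eigen.neutral_pcs + 1).tolist(),
        }, indent=1))
        summary["panel"] = str(report)
        summary["n_test_pcs"] = int(len(eigen.test_pcs))

        stage = "simulate-expression"
        lam1 = eigen.eigenvalues[0]
        delta = float(np.sqrt(config.shift_ncp * config.va * lam1))
        truth = TraitTruth(va_true=config.va,
                           shifts={g: [(1, delta)]
                                   for g in range(config.n_selected)})
        rng_tr = sim.rng(4)
        cons_true = synthdata.simulate_traits(eigen, truth, config.n_genes,
                                              rng_tr)
        plas_true = synthdata.simulate_traits(
            eigen, TraitTruth(va_true=config.va * 0.25), config.n_genes,
            rng_tr) - 10.0
        counts, meta = synthdata.simulate_expression_counts(
            cons_true - 10.0, plas_true, sim, baseline_log2=6.0)
        counts.to_csv(out / "counts.tsv", sep="\t")
        meta.to_csv(out / "sample_meta.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps({
            "va_true": config.va, "delta_pc1": delta,
            "selected_genes": [f"gene{g:05d}" for g in truth.selected()],
        }, indent=1))

        stage = "traits"
        traits = exprtraits.traits_from_counts(counts, meta,
                                               min_mean=config.min_mean)

        stage = "qpc"
        scans = {}
        for which in ("constitutive", "plastic"):
            scan = qpc.qpc_scan(traits, eigen, which=which, mode="relaxed",
                                fdr=config.fdr)
            scan.table.to_csv(out / f"qpc_{which}.tsv", sep="\t", index=False,
                              float_format="%.8g")
            scans[which] = qpc.call_outliers(scan, config.fdr)
        summary["cde_genes"] = scans["constitutive"]["n_union"]
        summary["pde_genes"] = scans["plastic"]["n_union"]

        stage = "plasticity"
        norm = exprtraits.vst(counts, exprtraits.size_factors(counts))
        native = {"Northern": "inland", "Central": "inland",
                  "Coastal": "coastal"}
        home = meta.apply(
            lambda r: native[r["cluster"]] == r["site"], axis=1)
        model = dapc.dapc_fit(norm.to_numpy()[home.to_numpy()],
                              meta.loc[home.to_numpy(), "cluster"]
                              .to_numpy(), n_pcs=10)
        scores, _ = dapc.dapc_project(model, norm.to_numpy())
        plast = dapc.plasticity(scores, meta, native)
        plast.to_csv(out / "plasticity.tsv", sep="\t", index=False)
        psum, p_anova, pairs = dapc.plasticity_test(plast)
        summary["plasticity_anova_p"] = p_anova

        stage = "popgen"
        sites, _ = synthdata.simulate_sites(
            sim, window_len=config.window, n_windows=2, theta=config.theta,
            missing_rate=config.missing_rate)
        windows = popwindows = None
        from .popgen import dxy_window, fst_wc_window, make_windows, pi_window
        popwindows = make_windows({"Chr01": config.window * 2}, config.window)
        stats = []
        clusters = pd.unique(np.asarray(sim.cluster_labels))
        for cl in clusters:
            t = pi_window(sites, cl, popwindows)
            t.insert(0, "stat", "pi")
            t.insert(1, "pops", cl)
            stats.append(t.rename(columns={"pi": "value"}))
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                t = dxy_window(sites, a, b, popwindows)
                t.insert(0, "stat", "dxy")
                t.insert(1, "pops", f"{a}~{b}")
                stats.append(t.rename(columns={"dxy": "value"}))
                tf = fst_wc_window(geno, a, b, popwindows)
                tf.insert(0, "stat", "fst")
                tf.insert(1, "pops", f"{a}~{b}")
                stats.append(tf.rename(columns={"fst": "value"})
                             .rename(columns={"a_sum": "diff_sum",
                                              "abc_sum": "comp_sum"}))
        popdf = pd.concat(stats, ignore_index=True)
        popdf.to_csv(out / "popgen_windows.tsv", sep="\t", index=False,
                     float_format="%.8g")

        stage = "ancestry"
        table = synthdata.simulate_orthogroups(
            config.n_orthogroups, (config.min_variant_sites, 12),
            config.p_coastal_ancestral, seed=sim.rng(5))
        table.to_csv(out / "orthogroups.tsv", sep="\t", index=False)
        fractions, point = ancestry.ancestral_fraction(
            table, config.min_variant_sites)
        lo, hi, _ = ancestry.bootstrap_ci(fractions, config.n_boot,
                                          seed=sim.rng(6))
        summary["coastal_ancestral"] = {"point": point, "ci": [lo, hi]}

        stage = "enrichment"
        universe = list(traits.genes)
        cde = scans["constitutive"]["union"]
        rng_e = sim.rng(7)
        category = sorted(set(cde[: len(cde) // 2]) | set(
            rng_e.choice(universe, size=max(len(universe) // 10, 1),
                         replace=False)))
        enr = assoc.fisher_enrichment(cde, category, universe)
        summary["enrichment"] = {"odds_ratio": enr.odds_ratio, "p": enr.p}
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    return summary
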