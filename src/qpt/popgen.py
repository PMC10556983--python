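"""Missing-data-aware diversity and divergence statistics.

Nucleotide diversity (pi) and absolute divergence (D_XY) are computed by
counting pairwise allele differences and pairwise comparisons per site and
taking the ratio of sums over a window — the all-sites convention in which
invariant and partially missing sites contribute to the denominator through
their callable comparisons, never through a site count.  Relative
differentiation is the Weir-Cockerham (1984) diploid theta from per-site
variance components a (among populations), b (among individuals within
populations), c (within individuals), combined across sites as
sum(a)/sum(a+b+c).  The same estimators aggregate over gene-feature
intervals, and gene-set contrasts (e.g. divergently expressed vs background
genes) are tested by one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats as st

from .genio import MISSING, GenotypeMatrix, SiteCallMatrix

log = logging.getLogger("qpt")


# ---------------------------------------------------------------------------
# per-site sums
# ---------------------------------------------------------------------------

def _pop_counts(sites: SiteCallMatrix, pop: np.ndarray):
    """(n_called_alleles, n_alt_alleles) per site for a sample mask."""
    called = sites.called[pop].sum(axis=0).astype(float)
    alt = sites.alt[pop].sum(axis=0).astype(float)
    return called, alt


def pi_site_sums(sites: SiteCallMatrix, pop: np.ndarray):
    """Per-site (diffs, comps) for within-population diversity."""
    n, alt = _pop_counts(sites, pop)
    diffs = alt * (n - alt)
    comps = n * (n - 1) / 2.0
    return diffs, comps


def dxy_site_sums(sites: SiteCallMatrix, pop1: np.ndarray, pop2: np.ndarray):
    """Per-site (diffs, comps) for between-population divergence."""
    n1, a1 = _pop_counts(sites, pop1)
    n2, a2 = _pop_counts(sites, pop2)
    diffs = (n1 - a1) * a2 + a1 * (n2 - a2)
    comps = n1 * n2
    return diffs, comps


def wc_components(g: GenotypeMatrix, pop1: np.ndarray, pop2: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components (a, b, c).

    Diploid, two populations, using observed heterozygosity.  Sites where a
    population has no called genotypes, or with fewer than two total
    populations represented, yield NaN components (skipped downstream).
    """
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    r = 2
    ns, ps, hs = [], [], []
    for pop in (pop1, pop2):
        dp = d[pop]
        n_i = np.sum(~np.isnan(dp), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p_i = np.nansum(dp, axis=0) / (2 * n_i)
            h_i = np.nansum(dp == 1, axis=0) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    valid = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                 - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = ~valid | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(chrom_sizes: dict, length: int = 20_000) -> pd.DataFrame:
    """Non-overlapping tiling windows [k*length, (k+1)*length)."""
    rows = []
    for chrom, size in chrom_sizes.items():
        for s in range(0, size, length):
            rows.append((chrom, s, min(s + length, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_masks(chrom, pos, windows: pd.DataFrame):
    pos0 = np.asarray(pos) - 1
    chrom = np.asarray(chrom, dtype=object).astype(str)
    for _, w in windows.iterrows():
        yield w, (chrom == str(w["chrom"])) & (pos0 >= w["start"]) & (pos0 < w["end"])


def _pop_mask(sites, pop) -> np.ndarray:
    if isinstance(pop, str):
        if sites.clusters is None:
            raise ValueError("no cluster labels attached; pass a boolean mask")
        return np.asarray(sites.clusters, dtype=object) == pop
    return np.asarray(pop, dtype=bool)


def pi_window(sites: SiteCallMatrix, pop, windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed nucleotide diversity; ratio of sums, NaN when no comparisons."""
    _warn_if_variant_only(sites)
    diffs, comps = pi_site_sums(sites, _pop_mask(sites, pop))
    return _aggregate(sites, diffs, comps, windows, "pi")


def dxy_window(sites: SiteCallMatrix, pop1, pop2,
               windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed absolute divergence between two populations."""
    _warn_if_variant_only(sites)
    diffs, comps = dxy_site_sums(sites, _pop_mask(sites, pop1),
                                 _pop_mask(sites, pop2))
    return _aggregate(sites, diffs, comps, windows, "dxy")


def _warn_if_variant_only(sites: SiteCallMatrix) -> None:
    with np.errstate(invalid="ignore"):
        alt_tot = sites.alt.sum(axis=0)
        called_tot = sites.called.sum(axis=0)
    invariant = (alt_tot == 0) | (alt_tot == called_tot)
    if not invariant.any():
        log.warning("input looks variant-only; pi/D_XY will be upward-biased "
                    "without invariant sites")


def _aggregate(sites, diffs, comps, windows, name) -> pd.DataFrame:
    rows = []
    for w, mask in _window_masks(sites.chrom, sites.pos, windows):
        dsum = float(np.nansum(diffs[mask]))
        csum = float(np.nansum(comps[mask]))
        val = dsum / csum if csum > 0 else np.nan
        rows.append((w["chrom"], w["start"], w["end"], val, dsum, csum,
                     int(mask.sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", name,
                                       "diff_sum", "comp_sum", "n_sites_used"])


def fst_wc_window(g: GenotypeMatrix, pop1, pop2,
                  windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed Weir-Cockerham theta = sum(a)/sum(a+b+c) over variant sites."""
    a, b, c = wc_components(g, _pop_mask(g, pop1), _pop_mask(g, pop2))
    tot = a + b + c
    rows = []
    for w, mask in _window_masks(g.chrom, g.pos, windows):
        ok = mask & np.isfinite(tot) & (tot != 0)
        asum = float(np.nansum(a[ok]))
        tsum = float(np.nansum(tot[ok]))
        theta = asum / tsum if ok.any() and tsum != 0 else np.nan
        rows.append((w["chrom"], w["start"], w["end"], theta, asum, tsum,
                     int(ok.sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst",
                                       "a_sum", "abc_sum", "n_sites_used"])


# ---------------------------------------------------------------------------
# gene features
# ---------------------------------------------------------------------------

def feature_stats(sites: SiteCallMatrix, g: GenotypeMatrix | None,
                  features: pd.DataFrame, populations: dict) -> pd.DataFrame:
    """pi / D_XY / F_ST aggregated per gene feature.

    ``features``: frame with gene/feature/chrom/start/end (0-based
    half-open; multi-interval features summed before the ratio).
    ``populations``: {name: mask-or-label}.  F_ST needs ``g`` (variant
    panel); pairwise statistics cover all population pairs.
    """
    pops = {name: _pop_mask(sites, p) for name, p in populations.items()}
    pairs = [(a, b) for i, a in enumerate(pops) for b in list(pops)[i + 1:]]
    per_site = {("pi", p): pi_site_sums(sites, pops[p]) for p in pops}
    for a_, b_ in pairs:
        per_site[("dxy", f"{a_}~{b_}")] = dxy_site_sums(sites, pops[a_], pops[b_])
    fst_site = {}
    if g is not None:
        gpops = {name: _pop_mask(g, p) for name, p in populations.items()}
        for a_, b_ in pairs:
            comp = wc_components(g, gpops[a_], gpops[b_])
            fst_site[f"{a_}~{b_}"] = comp
    pos0_s = sites.pos - 1
    chrom_s = sites.chrom.astype(str)
    rows = []
    for (gene, feat), grp in features.groupby(["gene", "feature"]):
        mask = np.zeros(sites.n_sites, dtype=bool)
        for _, iv in grp.iterrows():
            mask |= ((chrom_s == str(iv["chrom"])) & (pos0_s >= iv["start"])
                     & (pos0_s < iv["end"]))
        for (stat, label), (diffs, comps) in per_site.items():
            dsum, csum = float(np.nansum(diffs[mask])), float(np.nansum(comps[mask]))
            rows.append((gene, feat, stat, label,
                         dsum / csum if csum > 0 else np.nan, dsum, csum))
        if g is not None:
            gmask = np.zeros(g.n_loci, dtype=bool)
            gpos0 = g.pos - 1
            gchrom = g.chrom.astype(str)
            for _, iv in grp.iterrows():
                gmask |= ((gchrom == str(iv["chrom"])) & (gpos0 >= iv["start"])
                          & (gpos0 < iv["end"]))
            for label, (a, b, c) in fst_site.items():
                tot = a + b + c
                ok = gmask & np.isfinite(tot) & (tot != 0)
                asum, tsum = float(np.nansum(a[ok])), float(np.nansum(tot[ok]))
                rows.append((gene, feat, "fst", label,
                             asum / tsum if ok.any() and tsum != 0 else np.nan,
                             asum, tsum))
    return pd.DataFrame(rows, columns=["gene", "feature", "stat", "pops",
                                       "value", "num_sum", "den_sum"])


def compare_gene_sets(stats: pd.DataFrame, sets: dict) -> pd.DataFrame:
    """Contrast per-gene statistics between gene sets (e.g. CDE vs NDE).

    For every feature x statistic x population(-pair), reports each set's
    mean and SE and the ANOVA / Tukey-adjusted p for the set contrast.
    Sets with < 2 genes with finite values are dropped.
    """
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if set(sets[a]) & set(sets[b]):
                raise ValueError(f"gene sets {a} and {b} overlap")
    rows = []
    for (feat, stat, pops_), grp in stats.groupby(["feature", "stat", "pops"]):
        by_gene = grp.set_index("gene")["value"]
        groups, labels = [], []
        for name in names:
            vals = by_gene.reindex(list(sets[name])).dropna().to_numpy()
            if len(vals) >= 2:
                groups.append(vals)
                labels.append(name)
        if len(groups) < 2:
            continue
        _, p_anova = st.f_oneway(*groups)
        tk = st.tukey_hsd(*groups) if len(groups) > 1 else None
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                b = labels[j]
                rows.append((feat, stat, pops_, a, b,
                             groups[i].mean(),
                             groups[i].std(ddof=1) / np.sqrt(len(groups[i])),
                             groups[j].mean(),
                             groups[j].std(ddof=1) / np.sqrt(len(groups[j])),
                             float(p_anova), float(tk.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["feature", "stat", "pops",
                                       "set_a", "set_b", "mean_a", "se_a",
                                       "mean_b", "se_b", "p_anova", "p_tukey"])
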