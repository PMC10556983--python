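"""From raw counts to per-accession constitutive and plastic traits.

The reaction-norm decomposition: for each gene, the accession mean across
the two transplant sites is the "constitutive" trait (main genetic effect)
and the coastal - inland difference is the "plastic" trait (genotype x site
interaction).  Counts are low-expression filtered, size-normalized by
median-of-ratios, variance-stabilized by log2(x+1), replicate-collapsed,
then decomposed and mean-centered per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("qpt")

SITES = ("inland", "coastal")


@dataclass
class TraitSet:
    accessions: list
    genes: list
    constitutive: np.ndarray   # accessions x genes, mean-centered
    plastic: np.ndarray        # accessions x genes (coastal - inland)
    centered: bool = True

    def frame(self, which: str) -> pd.DataFrame:
        vals = getattr(self, which)
        return pd.DataFrame(vals, index=self.accessions, columns=self.genes)


def validate_meta(meta: pd.DataFrame) -> None:
    req = {"sample", "accession", "cluster", "site", "replicate"}
    missing = req - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    if meta.duplicated(["accession", "site", "replicate"]).any():
        raise ValueError("(accession, site, replicate) must be unique")
    bad = set(meta["site"]) - set(SITES)
    if bad:
        raise ValueError(f"unknown sites {sorted(bad)}; expected {SITES}")


def filter_low_expression(counts: pd.DataFrame, min_mean: float = 1.0):
    """Drop genes with mean count < min_mean across all samples (strict <)."""
    if counts.size == 0:
        raise ValueError("empty count matrix")
    keep = counts.mean(axis=0) >= min_mean
    log.info("filter_low_expression: kept %d/%d genes",
             int(keep.sum()), counts.shape[1])
    return counts.loc[:, keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, scaled to geometric mean 1.

    Reference gene values are geometric means over samples, computed on
    genes positive in every sample; if no such gene exists, falls back to
    total-count ratios with a warning.
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=0)
    if allpos.any():
        logx = np.log(x[:, allpos])
        ref = logx.mean(axis=0)
        f = np.exp(np.median(logx - ref, axis=1))
    else:
        log.warning("size_factors: no gene positive in all samples; "
                    "falling back to total-count ratios")
        tot = x.sum(axis=1)
        f = tot / np.exp(np.mean(np.log(tot)))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.index, name="size_factor")


def vst(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Variance-flattening transform: log2(count / size_factor + 1)."""
    f = factors.reindex(counts.index).to_numpy()
    if np.any(f <= 0):
        raise ValueError("size factors must be positive")
    return pd.DataFrame(np.log2(counts.to_numpy() / f[:, None] + 1.0),
                        index=counts.index, columns=counts.columns)


def accession_site_means(norm: pd.DataFrame,
                         meta: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per accession x site; absent combinations stay NaN.

    Returns a frame indexed by (accession, site).
    """
    validate_meta(meta)
    m = meta.set_index("sample").loc[norm.index]
    grouped = norm.groupby([m["accession"].to_numpy(),
                            m["site"].to_numpy()]).mean()
    grouped.index.names = ["accession", "site"]
    return grouped


def constitutive_plastic(means: pd.DataFrame) -> TraitSet:
    """Reaction-norm decomposition of accession x site means.

    constitutive = (inland + coastal) / 2, plastic = coastal - inland;
    each gene then mean-centered across accessions.  Accessions missing a
    site are dropped (logged).
    """
    wide_i = means.xs("inland", level="site")
    wide_c = means.xs("coastal", level="site")
    both = wide_i.index.intersection(wide_c.index)
    dropped = set(wide_i.index.symmetric_difference(wide_c.index))
    if dropped:
        log.info("constitutive_plastic: %d accessions missing a site "
                 "excluded: %s", len(dropped), sorted(dropped)[:5])
    wide_i, wide_c = wide_i.loc[both], wide_c.loc[both]
    cons = (wide_i.to_numpy() + wide_c.to_numpy()) / 2.0
    plas = wide_c.to_numpy() - wide_i.to_numpy()
    cons = cons - cons.mean(axis=0)
    plas = plas - plas.mean(axis=0)
    return TraitSet(accessions=list(both), genes=list(means.columns),
                    constitutive=cons, plastic=plas, centered=True)


def traits_from_counts(counts: pd.DataFrame, meta: pd.DataFrame,
                       min_mean: float = 1.0) -> TraitSet:
    """Full pipeline counts -> TraitSet (filter, normalize, vst, collapse)."""
    kept = filter_low_expression(counts, min_mean=min_mean)
    f = size_factors(kept)
    norm = vst(kept, f)
    return constitutive_plastic(accession_site_means(norm, meta))
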