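"""Ancestral-allele polarization between the inland and coastal clusters.

Given ortholog variant sites with outgroup-inferred ancestral states, the
per-orthogroup statistic is the fraction of polarizable sites (exactly one
ingroup allele matching the ancestral state) where the coastal allele is
ancestral.  The overall probability that the coastal cluster is ancestral
is the mean over orthogroups, with a percentile bootstrap CI over
orthogroups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLS = ("orthogroup", "inland", "coastal", "ancestral")
VALID_ALLELES = set("ACGT-")


def validate_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"polarized table missing columns {sorted(missing)}")
    for col in ("inland", "coastal", "ancestral"):
        vals = set(table[col].dropna().astype(str))
        bad = {v for v in vals if v not in VALID_ALLELES and v != "?"}
        if bad:
            raise ValueError(f"invalid alleles in {col}: {sorted(bad)}")


def ancestral_fraction(table: pd.DataFrame, min_variant_sites: int = 3,
                       majority_call: bool = False):
    """Per-orthogroup coastal-ancestral fraction and the overall mean.

    Orthogroups with fewer than ``min_variant_sites`` variant sites are
    excluded.  A site counts only if exactly one of the two ingroup alleles
    equals the ancestral state; sites with unknown ancestral state ('?')
    are uninformative.  With ``majority_call`` each orthogroup contributes
    a 0/1 majority vote instead of its fraction.  Returns (per-orthogroup
    Series, overall mean).
    """
    validate_table(table)
    t = table.copy()
    n_var = t.groupby("orthogroup").size()
    keep = n_var[n_var >= min_variant_sites].index
    t = t[t["orthogroup"].isin(keep)]
    coastal_anc = (t["coastal"] == t["ancestral"]) & (t["inland"] != t["ancestral"])
    inland_anc = (t["inland"] == t["ancestral"]) & (t["coastal"] != t["ancestral"])
    t = t.assign(coastal_anc=coastal_anc, informative=coastal_anc | inland_anc)
    t = t[t["informative"]]
    grp = t.groupby("orthogroup")["coastal_anc"]
    fractions = grp.mean()
    if majority_call:
        fractions = (fractions > 0.5).astype(float)
    if len(fractions) == 0:
        raise ValueError("no orthogroup passes the variant-site filter "
                         "with informative sites")
    return fractions, float(fractions.mean())


def bootstrap_ci(fractions, n_boot: int = 10_000, alpha: float = 0.05,
                 seed: int | np.random.Generator = 0):
    """Percentile bootstrap CI of the mean fraction over orthogroups.

    Returns (lower, upper, point).  Deterministic under a fixed seed.
    """
    x = np.asarray(fractions, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 orthogroups to bootstrap")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi), float(x.mean())
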