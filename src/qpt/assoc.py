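"""Small association statistics: Fisher enrichment of gene categories,
leaf relative water content, and partial Spearman correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st


@dataclass
class EnrichmentResult:
    table: np.ndarray          # [[a, b], [c, d]]
    odds_ratio: float
    p: float
    corrected: bool            # Haldane 0.5 applied to the OR
    labels: tuple = ("hits", "category")


def fisher_enrichment(hits, category, universe) -> EnrichmentResult:
    """Two-sided Fisher exact test of category enrichment among hits.

    2x2 table: a = |hits & category|, b = |hits - category|,
    c = |category - hits|, d = the rest of the universe.  The sample odds
    ratio ad/bc gets a Haldane 0.5 correction when any cell is zero
    (flagged); the p-value sums hypergeometric tables with point
    probability <= the observed one.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits, category = set(hits), set(category)
    if not hits <= universe or not category <= universe:
        raise ValueError("hits and category must be subsets of the universe")
    a = len(hits & category)
    b = len(hits - category)
    c = len(category - hits)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    oddsr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    p = float(st.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(table=table, odds_ratio=float(oddsr), p=p,
                            corrected=corrected)


def rwc(fresh: float, turgid: float, dry: float) -> float:
    """Leaf relative water content (%).

    (fresh - dry) / (turgid - dry) * 100.  Values above 100 are allowed
    (measurement noise) but flagged via a ValueError-free return; a turgid
    weight at or below the dry weight is invalid.
    """
    if turgid <= dry:
        raise ValueError("turgid weight must exceed dry weight")
    if fresh < dry:
        raise ValueError("fresh weight cannot be below dry weight")
    return (fresh - dry) / (turgid - dry) * 100.0


def partial_spearman(x, y, control):
    """Partial Spearman correlation of x and y controlling for a covariate.

    All three vectors are rank-transformed; the partial correlation is the
    Pearson correlation of the rank residuals after linear removal of the
    control, with p from the t approximation on n - 3 degrees of freedom.
    """
    x, y, control = (np.asarray(v, dtype=float) for v in (x, y, control))
    n = len(x)
    if not (len(y) == len(control) == n) or n < 4:
        raise ValueError("need three equal-length vectors with n >= 4")
    for name, v in (("x", x), ("y", y), ("control", control)):
        if np.ptp(v) == 0:
            raise ValueError(f"constant vector: {name}")
    rx, ry, rz = (st.rankdata(v) for v in (x, y, control))
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    rho = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho ** 2))
    p = float(2 * st.t.sf(abs(t), df))
    return rho, p
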