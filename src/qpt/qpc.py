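"""The Q_PC selection test on kinship principal components.

For a trait z over accessions, project the centered trait z_c = T z onto
eigenvectors of the conditional kinship matrix and scale each projection by
the eigenvalue: c_m = u_m' z_c / sqrt(lambda_m).  Under neutral drift the
c_m are iid N(0, V_A), so V_A is estimated as the mean of c_m^2 over the
trailing ("neutral") PCs and each leading ("test") PC yields
F = c_m^2 / V_A_hat ~ F(1, |neutral|).  Excessive divergence along a test
PC (upper tail) flags non-neutral constitutive (CDE) or plastic (PDE)
expression divergence; q-values control the FDR across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.interpolate import UnivariateSpline

from .exprtraits import TraitSet
from .genio import RegionSet
from .kinship import KinshipEigen

log = logging.getLogger("qpt")


# ---------------------------------------------------------------------------
# single-trait test
# ---------------------------------------------------------------------------

@dataclass
class QpcResult:
    gene: str
    pc: int            # 1-based PC index
    c: float           # scaled projection
    va_hat: float
    F: float
    p: float
    q: float = np.nan


def qpc_test(trait: np.ndarray, eigen: KinshipEigen,
             gene: str = "trait") -> list[QpcResult]:
    """Q_PC test of one trait on each test PC; returns one result per PC."""
    F, p, c, va = qpc_batch(np.asarray(trait, float)[:, None], eigen)
    return [QpcResult(gene=gene, pc=int(m) + 1, c=float(c[i, 0]),
                      va_hat=float(va[0]), F=float(F[i, 0]), p=float(p[i, 0]))
            for i, m in enumerate(eigen.test_pcs)]


def qpc_batch(Z: np.ndarray, eigen: KinshipEigen):
    """Vectorized Q_PC over trait columns. Returns (F, p, c_test, va_hat)."""
    if eigen.test_pcs is None or eigen.neutral_pcs is None:
        raise ValueError("run kinship.pc_sets on the eigen object first")
    if len(eigen.neutral_pcs) < 3:
        raise ValueError("need >= 3 neutral PCs")
    if Z.shape[0] != eigen.n_samples:
        raise ValueError("trait length does not match kinship samples")
    lam = eigen.eigenvalues
    zc = eigen.T @ Z
    zc[:, np.ptp(Z, axis=0) == 0] = 0.0  # constant trait: exactly zero
    c = eigen.eigenvectors.T @ zc
    nz = lam > 0
    c[nz] = c[nz] / np.sqrt(lam[nz])[:, None]
    va_hat = np.mean(c[eigen.neutral_pcs] ** 2, axis=0)
    c_test = c[eigen.test_pcs]
    dfd = len(eigen.neutral_pcs)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = c_test ** 2 / va_hat
    p = np.where(
        va_hat > 0,
        st.f.sf(np.where(va_hat > 0, F, 0.0), 1, dfd),
        np.where(c_test ** 2 > 0, 0.0, 1.0),
    )
    F = np.where(va_hat > 0, F, np.where(c_test ** 2 > 0, np.inf, 0.0))
    return F, p, c_test, va_hat


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey FDR q-values.

    pi0 is estimated from the p-value histogram on the lambda grid
    0.05..0.95 (step 0.05) with a cubic smoothing spline evaluated at the
    largest lambda; if the estimate is > 1 or unstable it falls back to 1
    (pure Benjamini-Hochberg).  q_i = pi0 * min_{p_j >= p_i} N p_j / rank_j.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(pi0 * q_sorted, 1.0)
    return q


def estimate_pi0(p: np.ndarray,
                 lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0 (Storey)."""
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n < 100:      # too few tests for a stable spline fit
        return 1.0
    pi0_l = np.array([(p >= lam).mean() / (1 - lam) for lam in lambdas])
    try:
        spl = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spl(lambdas[-1]))
    except Exception:
        return 1.0
    if not np.isfinite(pi0) or pi0 > 1 or pi0 <= 0:
        return 1.0
    return pi0


# ---------------------------------------------------------------------------
# scan over genes
# ---------------------------------------------------------------------------

@dataclass
class QpcScan:
    table: pd.DataFrame    # gene, pc, c, va_hat, F, p, q
    mode: str
    which: str
    fdr: float = 0.1
    n_genes: int = 0
    params: dict = field(default_factory=dict)

    def outliers(self, q_threshold: float | None = None) -> pd.DataFrame:
        thr = self.fdr if q_threshold is None else q_threshold
        return self.table[self.table["q"] < thr]


def qpc_scan(traits: TraitSet, eigen: KinshipEigen,
             which: str = "constitutive", mode: str = "relaxed",
             regions: RegionSet | None = None,
             gene_coords: pd.DataFrame | None = None,
             fdr: float = 0.1, pool_pcs: bool = False,
             pi0: float | None = None) -> QpcScan:
    """Q_PC scan of all genes' constitutive or plastic traits.

    ``constrained`` mode first restricts to genes inside ``regions`` (the
    highly recombined fraction of the genome); ``gene_coords`` must then
    provide gene/chrom/start (1-based) columns.  The kinship used in
    constrained mode should come from a region-purged SNP panel; a
    provenance mismatch is only warned about.  q-values are computed per
    tested PC across genes (or pooled with ``pool_pcs``).
    """
    if which not in ("constitutive", "plastic"):
        raise ValueError("which must be 'constitutive' or 'plastic'")
    if mode not in ("relaxed", "constrained"):
        raise ValueError("mode must be 'relaxed' or 'constrained'")
    if list(traits.accessions) != list(eigen.samples):
        raise ValueError("trait accessions do not match kinship samples")
    Z = getattr(traits, which)
    genes = np.asarray(traits.genes, dtype=object)
    if mode == "constrained":
        if regions is None or gene_coords is None:
            raise ValueError("constrained mode needs regions and gene_coords")
        prov = (eigen.provenance or {})
        if prov.get("region_mode") != "exclude":
            log.warning("constrained scan with a kinship not built from a "
                        "region-purged SNP panel")
        gc = gene_coords.set_index("gene").loc[genes]
        inside = regions.contains(gc["chrom"].to_numpy(),
                                  gc["start"].to_numpy() - 1)
        Z, genes = Z[:, inside], genes[inside]
    F, p, c_test, va = qpc_batch(Z, eigen)
    recs = []
    for i, m in enumerate(eigen.test_pcs):
        recs.append(pd.DataFrame({
            "gene": genes, "pc": int(m) + 1, "c": c_test[i],
            "va_hat": va, "F": F[i], "p": p[i]}))
    table = pd.concat(recs, ignore_index=True)
    if pool_pcs:
        table["q"] = qvalues(table["p"].to_numpy(), pi0=pi0)
    else:
        table["q"] = np.nan
        for m in table["pc"].unique():
            sel = table["pc"] == m
            table.loc[sel, "q"] = qvalues(table.loc[sel, "p"].to_numpy(),
                                          pi0=pi0)
    return QpcScan(table=table, mode=mode, which=which, fdr=fdr,
                   n_genes=len(genes),
                   params={"pool_pcs": pool_pcs})


def call_outliers(scan: QpcScan, q_threshold: float = 0.1) -> dict:
    """Per-PC outlier gene lists, their union, and multi-PC genes."""
    out = scan.table[scan.table["q"] < q_threshold]
    per_pc = {int(m): sorted(out.loc[out["pc"] == m, "gene"])
              for m in sorted(scan.table["pc"].unique())}
    union = sorted(set(out["gene"]))
    counts = out.groupby("gene")["pc"].nunique()
    multi = sorted(counts[counts >= 2].index)
    return {"per_pc": per_pc, "union": union, "multi_pc": multi,
            "n_union": len(union)}


# ---------------------------------------------------------------------------
# neutral envelope (confidence bands in the projection plots)
# ---------------------------------------------------------------------------

def neutral_envelope(eigen: KinshipEigen, va_hat: float, pc: int,
                     alpha: float = 0.05) -> float:
    """Half-width slope b of the (1-alpha) neutral envelope on a given PC.

    The envelope is the pair of lines through the origin with slopes +/- b
    against the unit-norm eigenvector coordinate, with
    b = sqrt(F_{1-alpha}(1, |neutral|) * va_hat * lambda_pc).  A gene falls
    outside the envelope exactly when its F test on that PC rejects at
    level alpha.
    """
    if va_hat < 0:
        raise ValueError("va_hat must be >= 0")
    if eigen.neutral_pcs is None:
        raise ValueError("run kinship.pc_sets first")
    lam = eigen.eigenvalues[pc - 1]
    fcrit = st.f.ppf(1 - alpha, 1, len(eigen.neutral_pcs))
    return float(np.sqrt(fcrit * va_hat * lam))
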