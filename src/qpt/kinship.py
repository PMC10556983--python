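"""Standardized kinship, conditional (mean-centered) eigendecomposition,
and the partition of PCs into "test" and "neutral" sets.

The selection test operates in the rank-(n-1) space left after conditioning
on the trait mean: K_cond = T K T' with T the first n-1 rows of the
centering projector I - 11'/n.  Traits are projected on eigenvectors of
K_cond; low-order PCs (largest eigenvalues, separating the major genetic
clusters) are tested, while a trailing block of high-order PCs provides the
neutral estimate of the additive genetic variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix

log = logging.getLogger("qpt")


@dataclass
class KinshipEigen:
    K: np.ndarray                 # n x n
    K_cond: np.ndarray            # (n-1) x (n-1)
    eigenvalues: np.ndarray       # descending, length n-1 (zeros clipped)
    eigenvectors: np.ndarray      # columns, unit norm
    T: np.ndarray                 # (n-1) x n centering operator
    samples: list
    test_pcs: np.ndarray | None = None      # 0-based indices
    neutral_pcs: np.ndarray | None = None
    provenance: dict | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def center_trait(self, z: np.ndarray) -> np.ndarray:
        """Map accession-space trait(s) into the conditional space (T z)."""
        return self.T @ z


def standardized_kinship(g: GenotypeMatrix) -> np.ndarray:
    """Standardized additive relationship matrix K = S S' / L.

    Per locus l with alt-allele frequency p_l (mean dosage / 2 over called
    samples), standardized scores are s_il = (g_il - 2 p_l) / sqrt(2 p_l q_l);
    missing dosages contribute 0 after centering (mean imputation).
    """
    d = g.dosage.astype(float)
    called = d != MISSING
    if np.any(~called.any(axis=0)):
        raise ValueError("loci with all genotypes missing; filter first")
    d = np.where(called, d, np.nan)
    p = np.nanmean(d, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "monomorphic loci present; apply filter_sites (MAC filter) first")
    miss_frac = 1.0 - called.mean()
    if miss_frac > 0:
        log.info("standardized_kinship: %.2f%% missing dosages mean-imputed",
                 100 * miss_frac)
    s = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    s = np.where(np.isnan(s), 0.0, s)
    return (s @ s.T) / g.n_loci


def centering_operator(n: int) -> np.ndarray:
    """First n-1 rows of the centering projector I - 11'/n."""
    return (np.eye(n) - np.ones((n, n)) / n)[:-1]


def conditional_eigen(K: np.ndarray, samples=None, rtol: float = 1e-8,
                      provenance: dict | None = None) -> KinshipEigen:
    """Mean-center K and eigendecompose the conditional kinship matrix.

    Eigenvalues below rtol * lambda_max are clipped to zero and excluded from
    both PC sets; each eigenvector's sign is fixed so its largest-magnitude
    entry is positive.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    if samples is None:
        samples = list(range(n))
    T = centering_operator(n)
    K_cond = T @ K @ T.T
    K_cond = (K_cond + K_cond.T) / 2
    w, U = np.linalg.eigh(K_cond)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    wmax = max(w.max(), 0.0)
    # relative clip plus an absolute floor so an all-identical (rank-0)
    # kinship is flagged degenerate rather than keeping ~1e-30 eigenvalues
    w = np.where(w < max(rtol * wmax, 1e-12), 0.0, w)
    wmax = max(w.max(), 0.0)
    if wmax <= 0:
        log.warning("conditional_eigen: degenerate kinship (no usable PCs)")
    # deterministic eigenvector orientation
    amax = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[amax, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    return KinshipEigen(K=K, K_cond=K_cond, eigenvalues=w, eigenvectors=U,
                        T=T, samples=list(samples),
                        provenance=dict(provenance or {}))


def pc_sets(eigen: KinshipEigen, test_fraction: float = 0.25,
            neutral_fraction: float = 0.50, max_test_pcs: int | None = None,
            neutral_rule: str = "tail-share") -> tuple[np.ndarray, np.ndarray]:
    """Partition PCs into a leading test prefix and a trailing neutral block.

    test set: smallest prefix of PCs whose cumulative eigenvalue share
    reaches ``test_fraction``.  neutral set: under ``tail-share`` (default),
    the smallest trailing block of nonzero PCs whose summed share reaches
    ``neutral_fraction``; under ``after-cum``, all PCs after the point where
    the cumulative share from the top exceeds 1 - neutral_fraction.  If the
    blocks would overlap, the neutral block is pushed to start after the
    test block (logged).  Indices are 0-based; sets are stored on ``eigen``.
    """
    if not (0 < test_fraction < 1 and 0 < neutral_fraction < 1):
        raise ValueError("fractions must be in (0, 1)")
    lam = eigen.eigenvalues
    nz = np.flatnonzero(lam > 0)
    if len(nz) == 0:
        raise ValueError("degenerate kinship: no nonzero eigenvalues")
    lam_nz = lam[nz]
    share = lam_nz / lam_nz.sum()
    cum = np.cumsum(share)
    n_test = int(np.searchsorted(cum, test_fraction) + 1)
    if max_test_pcs is not None:
        n_test = min(n_test, max_test_pcs)
    test = nz[:n_test]

    if neutral_rule == "tail-share":
        tail = np.cumsum(share[::-1])
        n_neut = int(np.searchsorted(tail, neutral_fraction) + 1)
        start = len(nz) - n_neut
    elif neutral_rule == "after-cum":
        # PCs strictly after the one at which the cumulative share from the
        # top first exceeds 1 - neutral_fraction
        start = int(np.searchsorted(cum, 1 - neutral_fraction,
                                    side="right")) + 1
    else:
        raise ValueError("neutral_rule must be 'tail-share' or 'after-cum'")
    if start < n_test:
        log.warning("pc_sets: neutral block overlapped test block; "
                    "starting neutral block after test PCs")
        start = n_test
    neutral = nz[start:]
    if len(neutral) < 3:
        raise ValueError(
            f"only {len(neutral)} neutral PCs; V_A estimate unstable")
    eigen.test_pcs = test
    eigen.neutral_pcs = neutral
    return test, neutral
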