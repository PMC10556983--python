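"""Independent reference implementations used only to check the package.

Everything here is deliberately written from the defining formulas in the
most direct (loop-based) way possible, sharing no code with qpt.
"""

import math

import numpy as np


def wc_components_site(genos1, genos2):
    """Weir-Cockerham (1984) a, b, c for one biallelic site, two populations.

    ``genos*``: lists of diploid alt-allele dosages (0/1/2), missing removed.
    Returns (a, b, c) or None when undefined.
    """
    r = 2
    n = [len(genos1), len(genos2)]
    if min(n) == 0 or sum(n) <= 2:
        return None
    p = [sum(genos1) / (2 * n[0]), sum(genos2) / (2 * n[1])]
    h = [sum(1 for g in genos1 if g == 1) / n[0],
         sum(1 for g in genos2 if g == 1) / n[1]]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni ** 2 for ni in n) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - 1.0 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def pi_pairwise(allele_lists):
    """Average pairwise difference per site by explicit pair enumeration.

    ``allele_lists``: per site, the list of called alleles (0/1).
    Returns sum(diffs)/sum(comps).
    """
    diffs = comps = 0
    for alleles in allele_lists:
        m = len(alleles)
        for i in range(m):
            for j in range(i + 1, m):
                comps += 1
                diffs += alleles[i] != alleles[j]
    return diffs / comps if comps else float("nan")


def dxy_pairwise(alleles1, alleles2):
    """Between-population average pairwise difference by enumeration."""
    diffs = comps = 0
    for a1, a2 in zip(alleles1, alleles2):
        for x in a1:
            for y in a2:
                comps += 1
                diffs += x != y
    return diffs / comps if comps else float("nan")


def fisher_exact_enumeration(table):
    """Two-sided Fisher exact p by complete enumeration of tables with the
    observed margins, summing point probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1)
                - math.lgamma(r1 - x + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - (c1 - x) + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                   - math.lgamma(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(logp(a))
    total = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(logp(x))
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def median_of_ratios(counts):
    """Brute-force size factors: counts is samples x genes ndarray."""
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=0)
    ref = np.exp(np.mean(np.log(counts[:, allpos]), axis=0))
    f = np.array([np.median(row[allpos] / ref) for row in counts])
    return f / np.exp(np.mean(np.log(f)))


def qpc_brute_force(trait, K, n_test, n_neutral_from_tail):
    """Direct Q_PC: center K and the trait, eigendecompose, project, F-test.

    Returns (F per test PC, p per test PC) using scipy's F distribution.
    """
    import scipy.stats as st

    n = len(trait)
    C = np.eye(n) - np.ones((n, n)) / n
    T = C[:-1]
    Kc = T @ K @ T.T
    w, U = np.linalg.eigh((Kc + Kc.T) / 2)
    idx = np.argsort(w)[::-1]
    w, U = w[idx], U[:, idx]
    zc = T @ np.asarray(trait, float)
    c = np.array([U[:, m] @ zc / np.sqrt(w[m]) for m in range(len(w))
                  if w[m] > 1e-10 * w[0]])
    va = np.mean(c[-n_neutral_from_tail:] ** 2)
    F = c[:n_test] ** 2 / va
    p = st.f.sf(F, 1, n_neutral_from_tail)
    return F, p
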