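"""Discriminant analysis of principal components (DAPC) and the
transcriptomic plasticity statistic.

DAPC first reduces the feature matrix by PCA (centered, unscaled), then
fits Fisher's linear discriminant on the retained PC scores, maximizing
between-group over within-group variance.  It serves two roles here:
inferring genetic clusters from SNP dosages (with k-means prior groups) and
measuring expression plasticity — the absolute shift of an accession's
discriminant score between its native and transplant sites, after
z-transforming scores within each genetic cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.cluster import KMeans

log = logging.getLogger("qpt")


@dataclass
class DapcModel:
    mean: np.ndarray          # feature means
    pc_loadings: np.ndarray   # features x n_pcs
    pc_var: np.ndarray
    axes: np.ndarray          # n_pcs x (k-1) discriminant directions
    groups: list
    group_means: np.ndarray   # k x (k-1), discriminant space
    within_cov: np.ndarray    # pooled, discriminant space
    n_pcs: int = 0
    scale: np.ndarray | None = None
    training_scores: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _pca(X: np.ndarray, n_pcs: int, scale: bool):
    mu = X.mean(axis=0)
    Xc = X - mu
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (X.shape[0] - 1)
    return mu, sd, Vt[:n_pcs].T, var[:n_pcs], Xc @ Vt[:n_pcs].T


def kmeans_groups(X: np.ndarray, k: int, n_pcs: int = 10, n_init: int = 20,
                  seed: int = 0):
    """k-means on top-PC scores; returns (labels, BIC).

    BIC follows the spherical-Gaussian convention used for choosing k in
    DAPC-style workflows: n*d*log(WSS/(n*d)) + k*d*log(n).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds number of samples")
    n_pcs = min(n_pcs, min(X.shape) - 1)
    _, _, _, _, scores = _pca(X, n_pcs, scale=False)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
    wss = km.inertia_
    d = scores.shape[1]
    bic = n * d * np.log(max(wss, 1e-12) / (n * d)) + k * d * np.log(n)
    return km.labels_, float(bic)


def dapc_fit(X: np.ndarray, groups, n_pcs: int = 10,
             scale: bool = False) -> DapcModel:
    """Fit DAPC: PCA to ``n_pcs`` then Fisher LDA on the PC scores.

    For k groups there are k-1 discriminant axes.  With two groups the
    single axis is oriented so the group listed first has negative mean.
    A singular pooled within-group covariance gets a small ridge (logged).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = [np.sum(groups == g) for g in uniq]
    if min(counts) < 2:
        raise ValueError("each group needs >= 2 members")
    n = X.shape[0]
    if n_pcs >= n - k + 1:
        n_pcs = max(1, n - k)
    n_pcs = min(n_pcs, min(X.shape))
    mu, sd, load, pcvar, scores = _pca(X, n_pcs, scale)

    gm = np.stack([scores[groups == g].mean(axis=0) for g in uniq])
    overall = scores.mean(axis=0)
    W = np.zeros((n_pcs, n_pcs))
    for g, m in zip(uniq, gm):
        d = scores[groups == g] - m
        W += d.T @ d
    W /= (n - k)
    B = np.zeros_like(W)
    for m, c in zip(gm, counts):
        d = (m - overall)[:, None]
        B += c * (d @ d.T)
    B /= max(k - 1, 1)
    try:
        Winv = np.linalg.inv(W)
    except np.linalg.LinAlgError:
        log.info("dapc_fit: singular within-group covariance; ridge added")
        W = W + 1e-8 * np.eye(n_pcs)
        Winv = np.linalg.inv(W)
    if np.linalg.cond(W) > 1e12:
        log.info("dapc_fit: ill-conditioned within covariance; ridge added")
        W = W + 1e-8 * np.trace(W) / n_pcs * np.eye(n_pcs)
        Winv = np.linalg.inv(W)
    evals, evecs = np.linalg.eig(Winv @ B)
    order = np.argsort(evals.real)[::-1][: k - 1]
    A = evecs[:, order].real
    # unit norm in the whitened (within-covariance) metric
    norms = np.sqrt(np.einsum("ij,jk,ki->i", A.T, W, A))
    A = A / norms
    disc = scores @ A
    dm = np.stack([disc[groups == g].mean(axis=0) for g in uniq])
    if k == 2 and dm[0, 0] > 0:
        A, disc, dm = -A, -disc, -dm
    Wd = np.zeros((k - 1, k - 1))
    for g, m in zip(uniq, dm):
        d = disc[groups == g] - m
        Wd += d.T @ d
    Wd /= (n - k)
    return DapcModel(mean=mu, pc_loadings=load, pc_var=pcvar, axes=A,
                     groups=uniq, group_means=dm, within_cov=Wd,
                     n_pcs=n_pcs, scale=sd, training_scores=disc,
                     params={"scale": scale})


def dapc_project(model: DapcModel, X: np.ndarray):
    """Project samples on the discriminant axes; returns (scores, posteriors).

    Posteriors come from a Gaussian class model in discriminant space with
    the pooled within-group covariance and equal priors.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature mismatch: model has {model.mean.shape[0]} features, "
            f"input has {X.shape[1]}")
    Xc = X - model.mean
    if model.scale is not None:
        Xc = Xc / model.scale
    disc = (Xc @ model.pc_loadings) @ model.axes
    cov = model.within_cov + 1e-12 * np.eye(model.within_cov.shape[0])
    logp = np.stack([
        st.multivariate_normal.logpdf(disc, mean=m, cov=cov,
                                      allow_singular=True)
        for m in model.group_means
    ], axis=-1)
    logp = np.atleast_2d(logp)
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return disc, pd.DataFrame(post, columns=model.groups)


def plasticity(scores: np.ndarray, meta: pd.DataFrame,
               native_site_map: dict) -> pd.DataFrame:
    """Per-accession transcriptomic plasticity from discriminant scores.

    Scores (first axis) are z-transformed within each genetic cluster
    (mean/SD over all that cluster's samples at both sites, ddof=1);
    plasticity = |mean z at transplant site - mean z at native site|.
    ``native_site_map`` maps cluster -> native site.  Accessions observed
    at a single site are excluded (logged).
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim > 1:
        s = s[:, 0]
    df = meta.reset_index(drop=True).copy()
    df["score"] = s
    z = np.empty(len(df))
    for cl, grp in df.groupby("cluster"):
        sd = grp["score"].std(ddof=1)
        z[grp.index] = (grp["score"] - grp["score"].mean()) / (sd if sd > 0 else 1.0)
    df["z"] = z
    recs = []
    for (acc, cl), grp in df.groupby(["accession", "cluster"]):
        native = native_site_map[cl]
        by_site = grp.groupby("site")["z"].mean()
        if len(by_site) < 2:
            log.info("plasticity: accession %s measured at one site only", acc)
            continue
        transplant = [sname for sname in by_site.index if sname != native][0]
        recs.append((acc, cl, abs(by_site[transplant] - by_site[native])))
    return pd.DataFrame(recs, columns=["accession", "cluster", "plasticity"])


def plasticity_test(plast: pd.DataFrame):
    """Cluster effect on plasticity: one-way ANOVA + Tukey HSD.

    Returns (summary frame with mean/SE per cluster, anova p, pairwise
    frame with Tukey-adjusted p).  Clusters with a single accession are
    dropped with a warning.
    """
    sizes = plast.groupby("cluster").size()
    small = sizes[sizes < 2].index
    if len(small):
        log.warning("plasticity_test: dropping clusters with <2 accessions: %s",
                    list(small))
        plast = plast[~plast["cluster"].isin(small)]
    clusters = sorted(plast["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters with >= 2 accessions")
    samples = [plast.loc[plast["cluster"] == c, "plasticity"].to_numpy()
               for c in clusters]
    summary = pd.DataFrame({
        "cluster": clusters,
        "mean": [x.mean() for x in samples],
        "se": [x.std(ddof=1) / np.sqrt(len(x)) for x in samples],
        "n": [len(x) for x in samples],
    })
    if np.ptp(np.concatenate(samples)) == 0:
        return summary, 1.0, pd.DataFrame(
            [(a, b, 1.0) for i, a in enumerate(clusters)
             for b in clusters[i + 1:]],
            columns=["cluster_a", "cluster_b", "p_adj"])
    F, p = st.f_oneway(*samples)
    tk = st.tukey_hsd(*samples)
    pairs = [(clusters[i], clusters[j], float(tk.pvalue[i, j]))
             for i in range(len(clusters)) for j in range(i + 1, len(clusters))]
    return summary, float(p), pd.DataFrame(
        pairs, columns=["cluster_a", "cluster_b", "p_adj"])
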