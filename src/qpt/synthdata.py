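"""Synthetic data generators for the whole pipeline.

Emulates the study design of a two-site reciprocal transplant on a strongly
selfing, three-cluster plant population: Balding-Nichols structured SNP
panels, additive expression traits with covariance proportional to the
conditional kinship, negative-binomial two-site count matrices with
replicates, all-sites sequence windows with missing calls, and
outgroup-polarized ortholog tables.  Every generator takes an explicit seed
(or numpy Generator) and is deterministic under it; ground truth is
returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, SiteCallMatrix
from .kinship import KinshipEigen

CLUSTER_NAMES = ("Northern", "Central", "Coastal")
SITES = ("inland", "coastal")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults mirror the field design: three genetic clusters with 53/22/11
    accessions, a neutral panel of 5,000 SNPs (a desk-scale stand-in for the
    50,000-SNP panel), strong selfing expressed as a 1% residual per-site
    heterozygosity, two transplant sites with three replicates each.
    """

    n_per_cluster: list = field(default_factory=lambda: [53, 22, 11])
    n_loci: int = 5000
    fst_per_cluster: list = field(default_factory=lambda: [0.22, 0.10, 0.32])
    selfing_het_rate: float = 0.01
    n_reps: int = 3
    nb_dispersion: float = 0.05
    site_effect_sd: float = 0.5
    gxe_sd: float = 0.0
    va: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_cluster) != len(self.fst_per_cluster):
            raise ValueError("n_per_cluster and fst_per_cluster lengths differ")
        if any(n < 2 for n in self.n_per_cluster):
            raise ValueError("need at least 2 accessions per cluster")
        if any(not (0 < f < 1) for f in self.fst_per_cluster):
            raise ValueError("fst values must lie in (0, 1)")
        if not (0 <= self.selfing_het_rate < 1):
            raise ValueError("selfing_het_rate must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @property
    def n_accessions(self) -> int:
        return int(sum(self.n_per_cluster))

    @property
    def cluster_labels(self) -> np.ndarray:
        names = [CLUSTER_NAMES[i % len(CLUSTER_NAMES)] if i < 3 else f"C{i}"
                 for i in range(len(self.n_per_cluster))]
        return np.repeat(np.asarray(names, dtype=object), self.n_per_cluster)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Stage-split generator: independent stream per pipeline stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class TraitTruth:
    """Ground truth for simulated traits: shared V_A and per-trait shifts."""

    va_true: float = 1.0
    shifts: dict = field(default_factory=dict)  # trait index -> [(pc, delta)]

    def __post_init__(self):
        if self.va_true < 0:
            raise ValueError("va_true must be >= 0")
        for tr, lst in self.shifts.items():
            for pc, _ in lst:
                if pc < 1:
                    raise ValueError("shift pc_index is 1-based and >= 1")

    def selected(self) -> list:
        return sorted(self.shifts)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Structured selfing genotypes under the Balding-Nichols F-model.

    Ancestral frequencies ~ U(0.05, 0.95); cluster k frequencies are Beta
    with mean p and variance F_k p(1-p).  Individuals are homozygotes
    (dosage = 2 x Bernoulli(p_k)) except a ``selfing_het_rate`` fraction of
    calls made heterozygous.  Loci monomorphic across all samples are
    removed; an all-monomorphic draw raises.
    """
    rng = config.rng(1)
    L = config.n_loci
    p_anc = rng.uniform(0.05, 0.95, size=L)
    labels = config.cluster_labels
    dosage = np.empty((config.n_accessions, L), dtype=np.int16)
    row = 0
    for n_k, f_k in zip(config.n_per_cluster, config.fst_per_cluster):
        a = p_anc * (1 - f_k) / f_k
        b = (1 - p_anc) * (1 - f_k) / f_k
        p_k = rng.beta(a, b)
        homo = 2 * rng.binomial(1, p_k, size=(n_k, L)).astype(np.int16)
        if config.selfing_het_rate > 0:
            het = rng.random((n_k, L)) < config.selfing_het_rate
            homo[het] = 1
        dosage[row:row + n_k] = homo
        row += n_k
    poly = (dosage.min(axis=0) != dosage.max(axis=0))
    if not poly.any():
        raise ValueError("degenerate config: all simulated loci monomorphic")
    dosage = dosage[:, poly]
    Lp = dosage.shape[1]
    pos = np.arange(1, Lp + 1) * 100  # 1-based, spaced
    return GenotypeMatrix(
        samples=[f"acc{i:03d}" for i in range(config.n_accessions)],
        chrom=np.full(Lp, "Chr01", dtype=object),
        pos=pos,
        ref=np.full(Lp, "A", dtype=object),
        alt=np.full(Lp, "T", dtype=object),
        dosage=dosage,
        clusters=labels,
        provenance={"source": "synthdata.simulate_genotypes",
                    "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(eigen: KinshipEigen, truth: TraitTruth, n_traits: int,
                    seed: int | np.random.Generator) -> np.ndarray:
    """Accession-space traits whose centered covariance is va_true * K_cond.

    Each neutral trait is U L^{1/2} w sqrt(va) in the conditional space with
    w standard normal; selected traits get an extra delta along the stated
    eigenvector (1-based PC index).  Traits are lifted back to accession
    space as mean-zero vectors plus a constant (the downstream test is
    translation invariant).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lam = eigen.eigenvalues
    U = eigen.eigenvectors
    m = len(lam)
    n_nonzero = int((lam > 0).sum())
    w = rng.standard_normal((m, n_traits))
    zc = U @ (np.sqrt(np.maximum(lam, 0.0))[:, None] * w) * np.sqrt(truth.va_true)
    for trait, shift_list in truth.shifts.items():
        if trait >= n_traits:
            raise ValueError(f"shift refers to trait {trait} >= n_traits")
        for pc, delta in shift_list:
            if pc > n_nonzero:
                raise ValueError(f"pc_index {pc} exceeds available PCs")
            zc[:, trait] += delta * U[:, pc - 1]
    # lift: mean-zero accession vector whose image under T is zc
    z = np.vstack([zc, -zc.sum(axis=0)])
    return z + 10.0  # arbitrary constant; test is translation invariant


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression_counts(constitutive: np.ndarray, plastic: np.ndarray,
                               config: SimConfig,
                               baseline_log2: float = 6.0):
    """Two-site replicated NB counts from constitutive/plastic trait values.

    For accession i, site s, gene g the log2 mean is
    baseline + constitutive_ig +/- plastic_ig / 2 (+ for the coastal site,
    - for inland, so coastal - inland equals the plastic trait exactly)
    plus a per-site shared effect.  Counts ~ NB with variance
    mu + dispersion * mu^2 (gamma-Poisson; dispersion 0 gives Poisson).
    Returns (counts DataFrame samples x genes, meta DataFrame).
    """
    constitutive = np.atleast_2d(constitutive)
    plastic = np.atleast_2d(plastic)
    if constitutive.shape != plastic.shape:
        raise ValueError("trait matrices must be conformable")
    if config.nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    n_acc, n_genes = constitutive.shape
    if n_acc != config.n_accessions:
        raise ValueError("trait rows must match config accessions")
    rng = config.rng(2)
    site_effect = {s: rng.normal(0.0, config.site_effect_sd)
                   for s in SITES}
    clusters = config.cluster_labels
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]
    recs, blocks = [], []
    for s, sign in zip(SITES, (-0.5, +0.5)):
        log2mu = (baseline_log2 + constitutive + sign * plastic
                  + site_effect[s])
        if config.gxe_sd > 0:
            log2mu = log2mu + rng.normal(0.0, config.gxe_sd,
                                         size=log2mu.shape)
        mu = np.exp2(log2mu)
        for r in range(config.n_reps):
            if config.nb_dispersion > 0:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, mu / shape)
            else:
                lam = mu
            counts = rng.poisson(lam)
            blocks.append(counts)
            for i in range(n_acc):
                recs.append((f"acc{i:03d}_{s}_r{r + 1}", f"acc{i:03d}",
                             clusters[i], s, r + 1))
    meta = pd.DataFrame(recs, columns=["sample", "accession", "cluster",
                                       "site", "replicate"])
    counts = pd.DataFrame(np.vstack(blocks), index=meta["sample"].to_numpy(),
                          columns=gene_ids)
    counts.index.name = "sample"
    return counts, meta


# ---------------------------------------------------------------------------
# all-sites sequence windows
# ---------------------------------------------------------------------------

def simulate_sites(config: SimConfig, window_len: int = 20_000,
                   n_windows: int = 1, theta: float = 0.005,
                   missing_rate: float = 0.1,
                   fixed_diff_rate: float = 0.0):
    """All-sites call matrix over contiguous windows, with ground truth.

    A ``theta`` fraction of positions are variant; cluster frequencies at
    variant sites follow the Balding-Nichols model of the config.  With
    ``fixed_diff_rate`` > 0, that fraction of positions is fixed for the
    alternate allele in the last cluster and reference in the others
    (marked in the truth table).  Per-sample calls are masked missing
    independently at ``missing_rate``.  Returns (SiteCallMatrix, truth
    DataFrame with per-cluster true allele frequencies).
    """
    if not (0 <= theta < 0.5):
        raise ValueError("theta must be in [0, 0.5)")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = config.rng(3)
    L = window_len * n_windows
    n = config.n_accessions
    labels = config.cluster_labels
    kinds = rng.choice(
        [0, 1, 2], size=L,
        p=[1 - theta - fixed_diff_rate, theta, fixed_diff_rate])
    K = len(config.n_per_cluster)
    freqs = np.zeros((K, L))
    var = kinds == 1
    if var.any():
        p_anc = rng.uniform(0.05, 0.95, size=var.sum())
        for k, f_k in enumerate(config.fst_per_cluster):
            a = p_anc * (1 - f_k) / f_k
            b = (1 - p_anc) * (1 - f_k) / f_k
            freqs[k, var] = rng.beta(a, b)
    freqs[-1, kinds == 2] = 1.0
    alt = np.zeros((n, L), dtype=np.int16)
    row = 0
    for k, n_k in enumerate(config.n_per_cluster):
        alt[row:row + n_k] = 2 * rng.binomial(1, freqs[k], size=(n_k, L))
        row += n_k
    called = np.full((n, L), 2, dtype=np.int16)
    if missing_rate > 0:
        miss = rng.random((n, L)) < missing_rate
        called[miss] = 0
        alt[miss] = 0
    pos = np.arange(1, L + 1)
    sites = SiteCallMatrix(
        samples=[f"acc{i:03d}" for i in range(n)],
        chrom=np.full(L, "Chr01", dtype=object), pos=pos,
        called=called, alt=alt, clusters=labels)
    truth = pd.DataFrame({"pos": pos, "kind": kinds})
    for k in range(K):
        truth[f"freq_{k}"] = freqs[k]
    return sites, truth


# ---------------------------------------------------------------------------
# polarized orthogroups
# ---------------------------------------------------------------------------

def simulate_orthogroups(n_groups: int, sites_per_group=(3, 12),
                         p_coastal_ancestral: float = 0.5,
                         seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Outgroup-polarized ortholog variant table.

    Each orthogroup carries a uniform number of variant sites in
    ``sites_per_group`` (inclusive range); at each site the ancestral state
    equals the coastal allele with probability ``p_coastal_ancestral`` and
    the inland allele otherwise.  Returns a PolarizedTable frame with
    columns orthogroup/site/inland/coastal/ancestral.
    """
    if not (0 <= p_coastal_ancestral <= 1):
        raise ValueError("p_coastal_ancestral must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lo, hi = sites_per_group
    bases = np.array(list("ACGT"))
    rows = []
    for og in range(n_groups):
        n_sites = int(rng.integers(lo, hi + 1))
        for s in range(n_sites):
            i, c = rng.choice(4, size=2, replace=False)
            anc = (bases[c] if rng.random() < p_coastal_ancestral
                   else bases[i])
            rows.append((f"OG{og:05d}", s + 1, bases[i], bases[c], anc))
    return pd.DataFrame(rows, columns=["orthogroup", "site", "inland",
                                       "coastal", "ancestral"])
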