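# Methods

This note documents the statistical models implemented in `qpt`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that make results exact
and reproducible.

## The Q_PC selection test

### Model

Let *z* be a per-accession trait (here a gene's constitutive or plastic
expression value) over *n* accessions with standardized kinship *K*.
Under neutral additive drift, the centered trait is multivariate normal
with covariance V_A · K_cond, where K_cond = T K T′ and *T* is the first
*n*−1 rows of the centering projector I − 11′/n (conditioning on the trait
mean, which carries no information about divergence).  With the
eigendecomposition K_cond = U Λ U′, the scaled projections

    c_m = u_m′ T z / √λ_m

are iid N(0, V_A) under neutrality.  The leading eigenvectors are exactly
the axes that separate the genetic clusters, so divergence *along
population structure* shows up as inflated |c_m| on low-order PCs.  V_A is
estimated as the mean of c_m² over a trailing "neutral" block of PCs, and
for each tested PC

    F_m = c_m² / V̂_A  ~  F(1, |neutral|)

with a one-sided upper-tail p-value: the target is excessive divergence;
detecting stabilizing selection (deflated projections) is out of scope.
V̂_A is shared across the test PCs of a gene — a single-variance neutral
model.

### PC partition

- **test set** (default `test_fraction = 0.25`): the smallest prefix of
  PCs whose cumulative eigenvalue share reaches 25%.
- **neutral set** (default `neutral_fraction = 0.50`): by default the
  smallest *trailing* block of nonzero PCs whose summed share reaches 50%
  (`tail-share`).  An alternative reading — all PCs strictly after the
  point where the cumulative share from the top exceeds 50% — is available
  as `neutral_rule="after-cum"`; the two disagree only in how much of the
  middle of the spectrum is discarded.  The sets are forced disjoint (the
  neutral block starts after the test block, with a logged warning) and at
  least 3 neutral PCs are required, since V̂_A is a mean of |neutral| χ²(1)
  draws.

On the synthetic design (three exchangeable clusters) the structure of
K_cond concentrates in only two eigenvalues (~13% of the trace), with a
flat noise floor behind them, so the 25% rule selects ≈11 test PCs.  Real
panels have pedigree and subpopulation structure that fills in
intermediate eigenvalues and yields a handful of test PCs; this difference
is a property of the exchangeable-cluster generator, not of the test,
whose calibration is exact PC-by-PC either way.

### Multiple testing

q-values follow Storey's procedure: π̂₀ estimated on the λ grid
0.05–0.95 (step 0.05) with a cubic smoothing spline evaluated at the
largest λ, falling back to π̂₀ = 1 (plain Benjamini–Hochberg) whenever the
spline estimate is unstable, out of (0, 1], or fewer than 100 p-values are
available.  q-values are computed per tested PC across genes (pooling
across PCs is available via a flag); outliers are called at q < 0.1.

### Confidence envelope

The (1−α) neutral envelope drawn in projection plots is the pair of lines
through the origin with slopes ±b against the eigenvector coordinate,
b = √(F⁻¹₁₋α(1, |neutral|) · V̂_A · λ_m).  A gene falls outside the
envelope exactly when its F test on that PC rejects at level α (the two
are algebraically the same comparison).

### Degenerate inputs

A constant trait has all projections set exactly to zero (F = 0, p = 1);
V̂_A = 0 with a nonzero test projection yields p = 0 and is flagged.
Eigenvalues below max(1e-8·λ_max, 1e-12) are clipped to zero and excluded
from both PC sets, so an all-identical-samples kinship is reported
degenerate instead of producing ~1e-30 eigenvalues.

## Kinship

Per locus with alt-allele frequency p (half the mean called dosage),
standardized scores are s = (g − 2p)/√(2p(1−p)); K = S S′ / L.  Missing
dosages contribute 0 after centering (mean imputation), with per-run
missingness logged.  The 2p(1−p) scaling is stated explicitly so tests can
be exact; any per-locus scaling variant would be admissible since the same
transform is applied to all samples.  *T* is deliberately non-orthonormal
(plain first n−1 rows of the centering projector): both K and z pass
through the same *T*, and the eigenvectors of K_cond absorb it.

## Expression traits

1. genes with mean raw count < 1 across all samples removed (strict <);
2. median-of-ratios size factors (reference = geometric mean over samples
   of genes positive everywhere; total-count fallback with a warning),
   scaled to geometric mean 1;
3. variance-flattening transform log2(count/factor + 1).  The fitted
   dispersion–mean VST of count-model packages is intentionally replaced
   by this monotone transform: the trait pipeline only needs approximate
   homoscedasticity, and the operation is isolated so a different
   transform can be substituted;
4. replicate collapse by arithmetic mean per accession × site (collapse
   after the transform; the order is exposed as a flag);
5. constitutive = (inland + coastal)/2 — the *unweighted* mean of the two
   site means, so unequal replication cannot bias toward one site;
   plastic = coastal − inland; both mean-centered per gene across
   accessions.  Accessions missing a site are excluded from the plastic
   trait with a log entry.

## DAPC and transcriptomic plasticity

DAPC = PCA (centered, unscaled by default — expression is already
variance-stabilized; a scaling flag exists) on the feature matrix,
retaining `n_pcs` components, then Fisher LDA maximizing between- over
within-group variance in PC space; k groups give k−1 axes, unit-norm in
the within-covariance metric.  With two groups the axis is oriented so the
first-listed group has negative mean.  Posterior group probabilities come
from a shared-covariance Gaussian model with equal priors in discriminant
space.  A singular or ill-conditioned within covariance receives a small
ridge (logged).  k-means prior groups are fit on the top 10 PC scores,
best of `n_init` restarts, with a spherical-Gaussian BIC for choosing k.

Plasticity of an accession: discriminant scores are z-transformed within
each genetic cluster (mean/SD with ddof = 1 over all that cluster's
samples at both sites), replicate scores averaged per accession × site,
and plasticity = |mean z at transplant site − mean z at native site|.
Accessions measured at a single site are excluded.  The cluster effect on
plasticity is tested by accession-level one-way ANOVA with Tukey HSD:
because the per-accession statistic already collapses replicates, the
mixed model with genotype random effects reduces approximately to this
ANOVA — a documented stand-in, not an equivalent.

## Population-genetic statistics

π and D_XY use comparison counting ("all-sites" convention): per site,
within-population differences = n_alt · n_ref and comparisons =
C(n_called, 2); between populations, differences = n_ref1·n_alt2 +
n_alt1·n_ref2 and comparisons = n_called1 · n_called2, where counts are
callable *alleles*.  A window's statistic is Σdiffs/Σcomps — a ratio of
sums, never a mean of per-site ratios — and a window with zero
comparisons is missing (NaN), never 0.  Invariant sites therefore dilute
the denominator exactly by their comparison counts; variant-only input is
detected and triggers an upward-bias warning.  Note D_XY of a population
with itself equals π · (n−1)/n: the between-population pairing includes
self-pairs.

F_ST is the diploid Weir–Cockerham (1984) estimator from per-site
variance components a (among populations), b (among individuals within),
c (within individuals), using observed heterozygosity — valid for selfers,
whose h is simply small — combined over windows as Σa/Σ(a+b+c).  Negative
window values are reported as-is (comparisons use means; clipping would
bias them).  Sites where a population has no called genotypes yield
missing components and are skipped.  Windows tile [k·20000, (k+1)·20000)
per chromosome by default.

Gene-feature statistics aggregate the same per-site sums over CDS, intron
(gaps between exons), 5′/3′-UTR, 2-kb promoters ([TSS−2000, TSS) on the +
strand, mirrored on −, truncated at the chromosome start) and whole gene
bodies, summing multi-interval features before the ratio.  Gene-set
contrasts (e.g. divergently expressed vs background genes) feed per-gene
values into one-way ANOVA + Tukey HSD; the alternative of pooling sites
across genes before testing is not implemented.

## Ancestral-allele polarization

Per orthogroup with ≥ 3 variant sites, the statistic is the fraction of
*polarizable* sites — exactly one of the two ingroup alleles equal to the
outgroup-inferred ancestral state — at which the coastal allele is the
ancestral one.  Sites where both or neither ingroup allele matches are
uninformative and excluded from numerator and denominator; this is the
convention under which "the more ancestral ecotype carries more ancestral
states" is well defined.  Outgroup conflicts are assumed resolved
upstream: the table carries one ancestral call per site.  The overall
probability is the unweighted mean over orthogroups (a majority-call
variant is available), with a percentile bootstrap CI over orthogroups
(default 10,000 replicates).

## Small statistics

- Fisher enrichment: 2×2 hits × category table within a gene universe;
  two-sided exact p sums tables with point probability ≤ observed; the
  sample odds ratio ad/bc gets a Haldane 0.5 correction only when a cell
  is zero (flagged).
- RWC = (fresh − dry)/(turgid − dry) × 100; values > 100 are permitted
  (field measurement noise), turgid ≤ dry is an error.
- Partial Spearman: rank-transform all three vectors, correlate the
  residuals after linear removal of the control, p from the t
  approximation on n−3 df.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *design* of the study: three genetic
clusters of 53/22/11 accessions (86 total), a neutral panel of 5,000 SNPs
(a desk-scale stand-in for a 50,000-SNP panel), strong selfing, two
transplant sites with 3 replicates (516 libraries), all-sites windows of
20 kb, and outgroup-polarized ortholog tables.

- **Genotypes**: Balding–Nichols F-model — ancestral frequency
  ~ U(0.05, 0.95), cluster frequency Beta-distributed with variance
  F_k·p(1−p).  Cluster defaults F = (0.22, 0.10, 0.32) for
  (Northern, Central, Coastal) were set once so that the additive
  approximation for pairwise differentiation, (F_j + F_k)/2, reproduces
  the relative ordering and magnitude of the observed cluster-pair F_ST
  (≈0.16 Central–Northern, ≈0.21 Coastal–Central, ≈0.27
  Coastal–Northern).  Selfing is represented directly at the genotype
  level — individuals are 2×Bernoulli(p_k) homozygotes with a 1%
  residual per-site heterozygosity — because only dosages enter the
  downstream mathematics; there is no pedigree simulation.
- **Traits**: exact draws from the null, z_c = U Λ^½ w √V_A, plus
  optional shifts δ·u_m for selected traits; a shift of
  δ = √(ncp · V_A · λ_m) gives a noncentral-F test with that ncp, which
  is what the power checks use.  Traits are lifted to accession space as
  mean-zero vectors plus a constant (the test is translation-invariant).
- **Counts**: log2 mean = baseline + constitutive ± plastic/2 (+ for
  coastal), so the between-site difference equals the plastic trait
  exactly; gamma-Poisson (NB) noise with dispersion 0.05, a typical
  3′-tag-count overdispersion; a shared per-site effect (SD 0.5 log2
  units) mimics environment main effects.
- **All-sites windows**: a `theta` fraction of positions segregate (the
  realized per-site π is ≈0.3·theta since variant sites are not maximally
  heterozygous), with Balding–Nichols cluster frequencies, optional fixed
  inter-cluster differences, and independent per-call missingness.
- **Orthogroups**: each variant site's ancestral state equals the coastal
  allele with probability `p_coastal_ancestral`.

Not emulated: linkage and LD (loci are independent), isolation by
distance and admixture, pedigree/family structure within clusters (hence
the flatter kinship spectrum discussed above), read-level noise and
mapping artifacts, and selection on sequences.  Passing tests therefore
demonstrate the estimators' correctness and the test's calibration under
the stated null — not robustness to LD pruning choices, cryptic
relatedness, or expression-count artifacts in real data.

All generators draw from one explicitly passed seeded generator
(`numpy.random.default_rng`), stream-split per pipeline stage; nothing
touches global RNG state, and every artifact is byte-identical across
reruns with the same config.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `n_per_cluster` | 53/22/11 | accessions per cluster (study design) |
| `n_loci` | 5,000 | neutral SNP panel (desk-scale stand-in for 50,000) |
| `selfing_het_rate` | 0.01 | residual per-site heterozygosity in selfers |
| `n_reps` | 3 | replicates per accession × site |
| `nb_dispersion` | 0.05 | NB overdispersion of counts |
| `test_fraction` / `neutral_fraction` | 0.25 / 0.50 | PC partition |
| `fdr` | 0.1 | q-value threshold for outlier calls |
| `min_mean` | 1.0 | low-expression filter on raw counts |
| `window` | 20,000 bp | popgen window length |
| promoter length | 2,000 bp | upstream of TSS |
| `min_variant_sites` | 3 | orthogroup inclusion filter |
| `n_boot` | 10,000 | bootstrap replicates |
| het / missing / MAC filters | 3.6% / 20% / MAC ≥ 3 | the two site-filter presets (`variant-calling`: het < 3.6%, missing < 20%; `neutral-panel`: missing < 10%, MAC ≥ 3) |

The calibration, power and coverage checks in the test-suite use 1,000
simulated traits, 200-gene scans, 100-dataset estimator comparisons and
200 bootstrap-coverage replicates; these sizes put Monte-Carlo error
comfortably inside the asserted tolerances while the full suite runs in
seconds.

## Known limitations

- The heterozygosity site filter is applied per site among called
  genotypes; whether the original filtering was per-site or
  per-genotype-fraction at the 85th percentile is not recoverable, so the
  threshold is a parameter.
- LD pruning and synonymous-site annotation are upstream of this package:
  the neutral panel arrives pre-pruned.
- The plasticity test is accession-level ANOVA, not the replicate-level
  mixed model (see above).
- `vst` is a fixed log transform, not a fitted dispersion–mean VST.
- Effect sizes for selected genes are free simulation parameters; no
  empirical effect-size distribution is claimed.
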