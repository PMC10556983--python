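"""Genotype / site-call containers, VCF and GFF3 I/O, and site-level filters.

Coordinate conventions follow the file formats: VCF positions are 1-based,
BED-style regions are 0-based half-open.  All containers keep loci in file
order and samples in header order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("qpt")

MISSING = -1  # dosage sentinel in integer matrices


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic dosage calls (0/1/2, MISSING=-1) at variant sites.

    ``dosage`` is samples x loci.  ``clusters`` optionally labels each sample
    with its genetic cluster.  ``provenance`` records how the panel was made
    (e.g. whether nonrecombining regions were purged) so downstream scans can
    check that a constrained-mode kinship really came from a purged panel.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray          # 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray       # (n_samples, n_loci) int8/int16
    clusters: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.pos)} loci"
            )

    def take_loci(self, idx) -> "GenotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=np.asarray(self.ref)[idx],
            alt=np.asarray(self.alt)[idx],
            dosage=self.dosage[:, idx],
        )


@dataclass
class SiteCallMatrix:
    """Per-site allele calls including invariant sites (all-sites data).

    ``called``: number of callable alleles per sample (0 or 2 for diploids),
    ``alt``: alt-allele dosage among the called alleles.  Required by the
    comparison-counting (pixy-style) diversity estimators.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray          # 1-based
    called: np.ndarray       # (n, L)
    alt: np.ndarray          # (n, L)
    clusters: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if np.any(self.alt > self.called):
            raise ValueError("alt dosage exceeds called allele count")

    @property
    def n_sites(self) -> int:
        return len(self.pos)


@dataclass
class RegionSet:
    """Sorted, merged genomic intervals, 0-based half-open."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.start >= self.end):
            raise ValueError("regions require start < end")
        order = np.lexsort((self.start, self.chrom.astype(str)))
        self.chrom, self.start, self.end = (
            self.chrom[order], self.start[order], self.end[order])

    def __len__(self) -> int:
        return len(self.start)

    def contains(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions; vectorized per chromosome."""
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        inside = np.zeros(len(pos0), dtype=bool)
        for c in np.unique(chrom.astype(str)):
            sel = chrom.astype(str) == c
            rsel = self.chrom.astype(str) == c
            if not rsel.any():
                continue
            starts, ends = _merge(self.start[rsel], self.end[rsel])
            i = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = i >= 0
            ok[ok] &= pos0[sel][ok] < ends[i[ok]]
            inside[sel] = ok
        return inside

    def chrom_names(self) -> set:
        return set(self.chrom.astype(str))


def _merge(starts, ends):
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, include_invariant: bool = False,
             clusters: dict | None = None):
    """Read a VCF into a GenotypeMatrix (variant-only) or SiteCallMatrix.

    Multiallelic records are skipped with a logged count; missing genotypes
    are preserved.  ``clusters`` optionally maps sample id -> cluster label.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) > 1:
            n_multi += 1
            continue
        if not include_invariant and len(rec.ALT) == 0:
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        gt = rec.gt_types.astype(np.int16)  # 0/1/2, 3=missing with gts012
        gt[gt == 3] = MISSING
        rows.append(gt)
    if n_multi:
        log.info("read_vcf: skipped %d multiallelic records", n_multi)
    dosage = (np.stack(rows, axis=1) if rows
              else np.zeros((len(samples), 0), dtype=np.int16))
    cl = (np.asarray([clusters[s] for s in samples], dtype=object)
          if clusters else None)
    if include_invariant:
        called = np.where(dosage == MISSING, 0, 2)
        alt = np.where(dosage == MISSING, 0, dosage)
        return SiteCallMatrix(samples, np.asarray(chroms), np.asarray(poss),
                              called, alt, clusters=cl)
    return GenotypeMatrix(samples, np.asarray(chroms), np.asarray(poss),
                          np.asarray(refs), np.asarray(alts), dosage,
                          clusters=cl,
                          provenance={"source": str(path), "multiallelic_skipped": n_multi})


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(obj, path) -> None:
    """Write a GenotypeMatrix or SiteCallMatrix as VCF 4.2 text."""
    if isinstance(obj, SiteCallMatrix):
        dosage = np.where(obj.called == 0, MISSING, obj.alt)
        refs = np.full(obj.n_sites, "A", dtype=object)
        alts = np.where((obj.alt.sum(axis=0) > 0), "T", ".")
        g = GenotypeMatrix(obj.samples, obj.chrom, obj.pos, refs, alts, dosage)
    else:
        g = obj
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom.astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        ref = np.asarray(g.ref, dtype=object)
        alt = np.asarray(g.alt, dtype=object)
        for j in range(g.n_loci):
            gts = "\t".join(_GT[int(d)] for d in g.dosage[:, j])
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t.\t{ref[j]}\t{alt[j]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    dropped: dict

    def __str__(self):
        parts = ", ".join(f"{k}={v}" for k, v in self.dropped.items())
        return f"{self.n_kept}/{self.n_input} sites kept (dropped: {parts})"


#: the two filtering stages used for resequencing panels
PRESETS = {
    "variant-calling": dict(max_het_pct=3.6, max_missing=0.20, min_mac=0),
    "neutral-panel": dict(max_het_pct=100.0, max_missing=0.10, min_mac=3),
}


def filter_sites(g: GenotypeMatrix, max_het_pct: float = 3.6,
                 max_missing: float = 0.20, min_mac: int = 3,
                 biallelic_only: bool = True):
    """Apply per-site genotype filters; returns (filtered, FilterReport).

    Heterozygosity is the percentage of heterozygous calls among called
    genotypes at the site; missingness the fraction of missing genotypes;
    MAC the minor allele count over called alleles.  A dropped site is
    attributed to the first failing rule in the order
    biallelic > heterozygosity > missingness > MAC.
    """
    if not (0 <= max_het_pct <= 100):
        raise ValueError("max_het_pct must be in [0, 100]")
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must be in [0, 1]")
    d = g.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_pct = 100.0 * (d == 1).sum(axis=0) / np.maximum(n_called, 1)
        miss = 1.0 - n_called / d.shape[0]
    alt_count = np.where(called, d, 0).sum(axis=0)
    mac = np.minimum(alt_count, 2 * n_called - alt_count)

    bad_bi = np.zeros(g.n_loci, dtype=bool)
    if biallelic_only:
        bad_bi = np.asarray(g.alt, dtype=object) == "."
    bad_het = het_pct >= max_het_pct
    bad_miss = miss >= max_missing
    bad_mac = mac < min_mac

    keep = ~(bad_bi | bad_het | bad_miss | bad_mac)
    attributed = np.zeros(g.n_loci, dtype=bool)
    dropped = {}
    for name, bad in [("biallelic", bad_bi), ("heterozygosity", bad_het),
                      ("missingness", bad_miss), ("mac", bad_mac)]:
        first = bad & ~attributed
        dropped[name] = int(first.sum())
        attributed |= bad
    report = FilterReport(g.n_loci, int(keep.sum()), dropped)
    out = g.take_loci(keep)
    out.provenance = dict(g.provenance, filtered=True)
    return out, report


def subset_by_regions(g: GenotypeMatrix, regions: RegionSet,
                      mode: str = "exclude") -> GenotypeMatrix:
    """Keep or exclude sites by region membership (0-based half-open).

    Sites on chromosomes absent from ``regions`` are retained in exclude
    mode and dropped in keep mode, with a warning.
    """
    if mode not in ("keep", "exclude"):
        raise ValueError("mode must be 'keep' or 'exclude'")
    known = regions.chrom_names()
    unknown = set(g.chrom.astype(str)) - known
    if unknown:
        log.warning("subset_by_regions: chromosomes %s absent from region set",
                    sorted(unknown))
    inside = regions.contains(g.chrom, g.pos - 1)
    keep = inside if mode == "keep" else ~inside
    out = g.take_loci(keep)
    out.provenance = dict(g.provenance, region_mode=mode,
                          region_label=regions.label)
    return out


# ---------------------------------------------------------------------------
# GFF3 / gene features
# ---------------------------------------------------------------------------

def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 into a frame with chrom/source/type/start/end/strand/id/parent."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"chrom": str})
    df["id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    df["parent"] = df["attributes"].str.extract(r"Parent=([^;]+)")
    return df


def promoter_regions(features: pd.DataFrame, length: int = 2000) -> RegionSet:
    """Proximal promoters: ``length`` bp upstream of each gene's TSS.

    For + strand genes [TSS-length, TSS) in 0-based half-open coordinates
    (TSS = 1-based gene start); for - strand [gene_end, gene_end+length).
    Truncated at the chromosome start.
    """
    genes = features[features["type"] == "gene"]
    if genes["strand"].isin([".", "?"]).any() or genes["strand"].isna().any():
        raise ValueError("promoter_regions requires known gene strands")
    plus = genes["strand"] == "+"
    start = np.where(plus, np.maximum(genes["start"] - 1 - length, 0),
                     genes["end"])
    end = np.where(plus, genes["start"] - 1, genes["end"] + length)
    ok = start < end
    return RegionSet(genes["chrom"].to_numpy()[ok], start[ok], end[ok],
                     label="promoter")


def gene_feature_intervals(features: pd.DataFrame,
                           promoter_length: int = 2000) -> pd.DataFrame:
    """Per-gene intervals for CDS, intron, UTRs, promoter and the gene body.

    Introns are the gaps between a gene's exons.  Returns a frame with
    columns gene/feature/chrom/start/end (0-based half-open).
    """
    rows = []
    genes = features[features["type"] == "gene"]
    mrna = features[features["type"] == "mRNA"]
    gene_of_mrna = dict(zip(mrna["id"], mrna["parent"]))

    def gene_id(parent):
        return gene_of_mrna.get(parent, parent)

    for _, gn in genes.iterrows():
        rows.append((gn["id"], "gene", gn["chrom"], gn["start"] - 1, gn["end"]))
    fmap = {"CDS": "CDS", "five_prime_UTR": "5'-UTR",
            "three_prime_UTR": "3'-UTR"}
    for ftype, fname in fmap.items():
        for _, r in features[features["type"] == ftype].iterrows():
            rows.append((gene_id(r["parent"]), fname, r["chrom"],
                         r["start"] - 1, r["end"]))
    exons = features[features["type"] == "exon"]
    for parent, grp in exons.groupby("parent"):
        grp = grp.sort_values("start")
        for (_, a), (_, b) in zip(grp.iterrows(), grp.iloc[1:].iterrows()):
            if b["start"] - 1 > a["end"]:
                rows.append((gene_id(parent), "intron", a["chrom"],
                             a["end"], b["start"] - 1))
    prom = promoter_regions(features, promoter_length)
    gid = genes["id"].to_numpy()
    strand_plus = (genes["strand"] == "+").to_numpy()
    # promoter_regions keeps gene order after its internal sort; recompute
    # directly here to keep the gene id association.
    for g, ch, s, e, pl in zip(gid, genes["chrom"], genes["start"],
                               genes["end"], strand_plus):
        if pl:
            a, b = max(s - 1 - promoter_length, 0), s - 1
        else:
            a, b = e, e + promoter_length
        if a < b:
            rows.append((g, "promoter", ch, a, b))
    return pd.DataFrame(rows, columns=["gene", "feature", "chrom",
                                       "start", "end"])


# ---------------------------------------------------------------------------
# BED / TSV helpers
# ---------------------------------------------------------------------------

def read_bed(path, label: str = "") -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    return RegionSet(df["chrom"].to_numpy(), df["start"].to_numpy(),
                     df["end"].to_numpy(), label=label)


def write_bed(regions: RegionSet, path) -> None:
    pd.DataFrame({"chrom": regions.chrom, "start": regions.start,
                  "end": regions.end}).to_csv(path, sep="\t", header=False,
                                              index=False)


def write_matrix_tsv(values: np.ndarray, index, columns, path,
                     index_name: str = "id") -> None:
    df = pd.DataFrame(values, index=index, columns=columns)
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
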