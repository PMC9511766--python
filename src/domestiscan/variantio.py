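"""Genotype and interval I/O, site filters, and functional site classification.

Coordinate conventions: VCF positions are 1-based at the file boundary and kept
1-based in :class:`SiteTable` (``pos`` column); gene/exon intervals are 0-based
half-open internally (BED convention). Every function that crosses the boundary
says which convention it uses.

Genotypes are diploid and unphased; the allele-index pair for a sample at a
site references the REF (index 0) and ALT alleles (1, 2, ...) of that site.
Missing calls are stored as ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

WILD = "wild"
INBRED = "classical_inbred"


class LabelingError(ValueError):
    """A VCF sample has no group assignment."""


@dataclass
class GeneModel:
    """A gene span with exon sub-intervals, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty span")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")


class GenotypeMatrix:
    """Samples x sites diploid allele indices with group labels.

    ``gt`` has shape (n_samples, n_sites, 2), dtype int16, missing = -1.
    """

    def __init__(self, samples: list[str], groups: dict[str, str], gt: np.ndarray):
        gt = np.asarray(gt, dtype=np.int16)
        if gt.ndim != 3 or gt.shape[2] != 2 or gt.shape[0] != len(samples):
            raise ValueError("gt must have shape (n_samples, n_sites, 2)")
        missing = set(samples) - set(groups)
        if missing:
            raise LabelingError(f"samples without group label: {sorted(missing)}")
        self.samples = list(samples)
        self.groups = {s: groups[s] for s in samples}
        self.gt = gt

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    @property
    def n_sites(self) -> int:
        return self.gt.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.groups, self.gt[:, mask, :])


def make_site_table(chrom, pos, ref, alts, ids=None) -> pd.DataFrame:
    """Build a SiteTable DataFrame (columns chrom, pos, id, ref, alts).

    ``pos`` is 1-based (VCF). ``alts`` entries are tuples of allele strings.
    Input must already be sorted by (chrom, pos).
    """
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "id": pd.Series(ids, dtype=object) if ids is not None else ".",
            "ref": pd.Series(ref, dtype=str),
            "alts": pd.Series([tuple(a) for a in alts], dtype=object),
        }
    )
    if (df["pos"] < 1).any():
        raise ValueError("VCF positions are 1-based")
    key = df[["chrom", "pos"]].apply(tuple, axis=1)
    if not key.is_monotonic_increasing:
        raise ValueError("sites must be sorted by (chrom, pos)")
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, group_map: dict[str, str]):
    """Read a GT-only VCF into (GenotypeMatrix, SiteTable).

    Missing genotypes ("./.") become -1; phasing is discarded; multi-allelic
    sites are retained with all alleles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in group_map]
    if unknown:
        raise LabelingError(f"samples absent from group map: {unknown}")

    chroms, poss, ids, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or ".")
        refs.append(var.REF)
        alts.append(tuple(var.ALT))
        g = np.asarray(var.genotypes, dtype=np.int16)[:, :2]
        rows.append(g)
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    gt = np.stack(rows, axis=1)  # (n_samples, n_sites, 2)
    gt[gt < 0] = MISSING
    sites = make_site_table(chroms, poss, refs, alts, ids)
    gm = GenotypeMatrix(samples, {s: group_map[s] for s in samples}, gt)
    return gm, sites


def write_vcf(path: str, gm: GenotypeMatrix, sites: pd.DataFrame) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT (unphased)."""
    chrom_max = sites.groupby("chrom", sort=True)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, m in chrom_max.items():
            fh.write(f"##contig=<ID={c},length={int(m) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        gt = gm.gt
        for j, rec in enumerate(sites.itertuples(index=False)):
            alt = ",".join(rec.alts) if rec.alts else "."
            calls = []
            for i in range(gm.n_samples):
                a, b = gt[i, j]
                calls.append("./." if a == MISSING or b == MISSING else f"{a}/{b}")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED12 genes
# ---------------------------------------------------------------------------

def read_genes_bed(path: str) -> list[GeneModel]:
    """Read genes with exon blocks from BED12 (0-based half-open)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            exons: list[tuple[int, int]] = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + s, start + s + z) for s, z in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, start, end, exons))
    return genes


def write_genes_bed(path: str, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - g.start) for s, e in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t+\t{g.start}\t{g.end}"
                f"\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Filters and tallies
# ---------------------------------------------------------------------------

def filter_sites(
    gm: GenotypeMatrix,
    sites: pd.DataFrame,
    biallelic_only: bool = True,
    max_missing: float = 0.1,
):
    """Keep bi-allelic SNPs with missing-genotype fraction strictly < max_missing.

    Missingness is computed over the merged sample set. A SNP must have a
    single ALT and single-base REF/ALT when ``biallelic_only``.
    """
    n_alt = sites["alts"].map(len).to_numpy()
    snp = (
        (sites["ref"].str.len() == 1).to_numpy()
        & sites["alts"].map(lambda a: all(len(x) == 1 for x in a)).to_numpy()
    )
    miss = (gm.gt[:, :, 0] == MISSING) | (gm.gt[:, :, 1] == MISSING)
    miss_frac = miss.mean(axis=0)
    keep = (miss_frac < max_missing) & snp
    if biallelic_only:
        keep &= n_alt == 1
    return gm.subset_sites(keep), sites.loc[keep].reset_index(drop=True)


def group_allele_counts(gm: GenotypeMatrix, sites: pd.DataFrame, group: str):
    """Per-site allele counts and frequencies over called alleles in a group.

    Returns a DataFrame with columns ``n_called``, ``counts`` (tuple indexed by
    allele), ``freqs`` (tuple, sums to 1 over called alleles), and
    ``undefined`` (True when the group has zero called alleles at the site).
    """
    idx = gm.group_indices(group)
    gt = gm.gt[idx]  # (g, sites, 2)
    n_sites = gm.n_sites
    max_allele = int(sites["alts"].map(len).max())
    counts = np.zeros((n_sites, max_allele + 1), dtype=np.int64)
    for a in range(max_allele + 1):
        counts[:, a] = (gt == a).sum(axis=(0, 2))
    n_called = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / n_called[:, None]
    n_alleles = 1 + sites["alts"].map(len).to_numpy()
    return pd.DataFrame(
        {
            "n_called": n_called,
            "counts": [tuple(counts[j, : n_alleles[j]]) for j in range(n_sites)],
            "freqs": [tuple(freqs[j, : n_alleles[j]]) for j in range(n_sites)],
            "undefined": n_called == 0,
        }
    )


def biallelic_group_counts(gm: GenotypeMatrix, group: str):
    """Fast path for bi-allelic sites: (alt allele count, called allele count)."""
    idx = gm.group_indices(group)
    gt = gm.gt[idx]
    called = gt != MISSING
    m = ((gt == 1) & called).sum(axis=(0, 2))
    n = called.sum(axis=(0, 2))
    return m.astype(np.int64), n.astype(np.int64)


def classify_sites(sites: pd.DataFrame, genes: list[GeneModel], warn=None):
    """Classify each site as exonic / intronic / intergenic (that precedence).

    A site (1-based ``pos``) falls in a 0-based half-open interval [s, e) when
    s < pos <= e, i.e. 0-based coordinate pos-1 in [s, e).
    Returns (Series of classes, dict tally). Sites on chromosomes absent from
    the gene set are intergenic (a warning callback may be supplied).
    """
    classes = np.full(len(sites), "intergenic", dtype=object)
    gene_chroms = {g.chrom for g in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, sub in sites.groupby("chrom", sort=False):
        if chrom not in gene_chroms:
            if warn is not None:
                warn(f"chromosome {chrom!r} not in gene annotation")
            continue
        pos0 = sub["pos"].to_numpy() - 1
        cls = np.full(len(sub), "intergenic", dtype=object)
        for g in by_chrom[chrom]:
            in_span = (pos0 >= g.start) & (pos0 < g.end)
            cls[in_span & (cls == "intergenic")] = "intronic"
            for s, e in g.exons:
                cls[(pos0 >= s) & (pos0 < e)] = "exonic"
        classes[sub.index.to_numpy()] = cls
    out = pd.Series(classes, index=sites.index, name="site_class")
    tally = {
        "exonic": int((out == "exonic").sum()),
        "intronic": int((out == "intronic").sum()),
        "intergenic": int((out == "intergenic").sum()),
    }
    return out, tally
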