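"""Synthetic wild/inbred genotype panels with planted selective sweeps.

The generator emulates the statistical structure a domestication scan
assumes, at desk scale and without a coalescent engine:

* a diverse, heterozygous *wild* group whose per-site derived-allele
  frequency is drawn i.i.d. from a neutral-SFS-weighted law
  (weight of allele count i proportional to 1/i**sfs_shape);
* a near-fully-homozygous *classical_inbred* panel: each strain is a
  homozygous mosaic of a small number of founder haplotypes sampled from the
  wild panel (founder bottleneck + complete inbreeding);
* planted sweep regions in which every inbred strain carries one shared
  founder haplotype, with a per-site escape probability that grows with
  distance d from the sweep centre as 1 - exp(-d/half_width) — the same
  functional form the scan's composite-likelihood model assumes, so the scan
  is testable against recorded truth;
* gene models on a regular grid, a gene x tissue RPKM matrix with a
  brain-enriched designated subset, per-tissue differential-expression
  tables, and qPCR Ct tables.

Linkage exists only through the founder-mosaic block structure; there is no
recombination-map or demographic realism (see the package methods note).
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import expression as expr_mod
from .variantio import (
    INBRED,
    MISSING,
    WILD,
    GeneModel,
    GenotypeMatrix,
    make_site_table,
    write_genes_bed,
    write_vcf,
)
from .scan import make_windows

_NUC = np.array(list("ACGT"))

#: Documented fixture seed: the seed under which the planted-sweep recovery
#: properties of this generator are asserted in the test suite.
FIXTURE_SEED = 20_220_806


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions of the default fixture.

    2 chromosomes x 2 Mb, ~20,000 SNPs, 20 wild + 20 inbred samples derived
    from 4 founders, 100 genes of 20 kb on a 40-kb grid, and 3 sweeps of
    half-width 40 kb whose region edges lie on the 20-kb window grid (so
    shoulder windows overlap a region by at most half a window).
    """

    n_chrom: int = 2
    chrom_length_bp: int = 2_000_000
    n_sites: int = 20_000
    n_wild: int = 20
    n_inbred: int = 20
    n_founders: int = 4
    sweep_specs: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("chr1", 500_000, 40_000),
            ("chr1", 1_500_000, 40_000),
            ("chr2", 1_000_000, 40_000),
        ]
    )
    sfs_shape: float = 1.0
    sweep_escape_factor: float = 10.0
    n_genes: int = 100
    gene_length_bp: int = 20_000
    missing_rate: float = 0.01
    het_residual_rate: float = 0.002
    seed: int = FIXTURE_SEED

    def __post_init__(self) -> None:
        counts = dict(
            n_chrom=self.n_chrom,
            chrom_length_bp=self.chrom_length_bp,
            n_sites=self.n_sites,
            n_wild=self.n_wild,
            n_inbred=self.n_inbred,
            n_founders=self.n_founders,
            n_genes=self.n_genes,
            gene_length_bp=self.gene_length_bp,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_founders > 2 * self.n_wild:
            raise ConfigError("n_founders exceeds available wild haplotypes")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        chroms = set(self.chrom_names())
        for chrom, center, hw in self.sweep_specs:
            if chrom not in chroms:
                raise ConfigError(f"sweep chromosome {chrom!r} unknown")
            if hw <= 0 or center - hw < 0 or center + hw > self.chrom_length_bp:
                raise ConfigError(
                    f"sweep ({chrom},{center},{hw}) outside chromosome bounds"
                )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}


@dataclass
class TruthTable:
    """Ground truth of a simulated panel, for recovery tests.

    sweep_genes: genes overlapping a declared sweep region.
    sweep_windows: unmasked (chrom, start, end) windows fully inside a region.
    wild_freqs: per-site derived-allele frequency used in generation.
    """

    sweep_regions: list[tuple[str, int, int]]
    sweep_genes: list[str]
    sweep_windows: list[tuple[str, int, int]]
    wild_freqs: list[float]


# ---------------------------------------------------------------------------
# Wild panel
# ---------------------------------------------------------------------------

def _sfs_frequencies(rng, n_sites: int, n_hap: int, shape: float) -> np.ndarray:
    i = np.arange(1, n_hap)
    w = 1.0 / i.astype(float) ** shape
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / n_hap


def expected_sfs_heterozygosity(n_hap: int, shape: float) -> float:
    """Closed-form E[2p(1-p)] under the SFS-weighted frequency law."""
    i = np.arange(1, n_hap)
    w = 1.0 / i.astype(float) ** shape
    p = i / n_hap
    return float(np.sum(w * 2 * p * (1 - p)) / w.sum())


def simulate_wild(config: SimConfig):
    """Wild diploid panel: returns (GenotypeMatrix, SiteTable, wild_freqs).

    Per-site derived (alt) allele frequencies follow the SFS-weighted law;
    genotypes are Binomial(2, p) per sample; positions are uniform without
    replacement per chromosome. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    per_chrom = config.n_sites // config.n_chrom
    chroms, poss = [], []
    for c in config.chrom_names():
        p = rng.choice(np.arange(1, config.chrom_length_bp + 1), per_chrom, replace=False)
        p.sort()
        chroms.extend([c] * per_chrom)
        poss.extend(p.tolist())
    n_sites = len(poss)

    freqs = _sfs_frequencies(rng, n_sites, 2 * config.n_wild, config.sfs_shape)
    dosage = rng.binomial(2, freqs[None, :], size=(config.n_wild, n_sites))
    gt = np.zeros((config.n_wild, n_sites, 2), dtype=np.int16)
    gt[:, :, 0] = (dosage >= 1).astype(np.int16)
    gt[:, :, 1] = (dosage == 2).astype(np.int16)

    ref_idx = rng.integers(0, 4, n_sites)
    alt_off = rng.integers(1, 4, n_sites)
    ref = _NUC[ref_idx]
    alt = _NUC[(ref_idx + alt_off) % 4]
    sites = make_site_table(chroms, poss, ref, [(a,) for a in alt])

    samples = [f"wild_{i:02d}" for i in range(config.n_wild)]
    gm = GenotypeMatrix(samples, {s: WILD for s in samples}, gt)
    return gm, sites, freqs


# ---------------------------------------------------------------------------
# Inbred panel
# ---------------------------------------------------------------------------

def _founder_haplotypes(rng, wild: GenotypeMatrix, freqs, n_founders: int):
    """One haplotype per founder, lifted from distinct wild samples.

    Missing alleles (none are generated, but tolerated) are imputed from the
    generating frequency.
    """
    pick = rng.choice(wild.n_samples, size=n_founders, replace=False)
    # draw one of the two (unordered) alleles per site so the founder
    # haplotype is an unbiased draw from the sample's genotype
    coin = rng.integers(0, 2, size=(n_founders, wild.n_sites))
    haps = np.take_along_axis(
        wild.gt[pick], coin[:, :, None], axis=2
    )[:, :, 0].astype(np.int16)
    miss = haps == MISSING
    if miss.any():
        haps[miss] = (rng.random(miss.sum()) < np.broadcast_to(freqs, haps.shape)[miss]).astype(np.int16)
    return haps


def _mosaic_assignment(rng, n_sites: int, positions, n_founders: int, block_bp: float):
    """Founder index per site for one strain: exponential-length blocks."""
    founder = np.empty(n_sites, dtype=np.int16)
    start = 0
    cur = rng.integers(n_founders)
    next_break = positions[0] + rng.exponential(block_bp)
    for j in range(n_sites):
        if positions[j] > next_break:
            cur = rng.integers(n_founders)
            next_break = positions[j] + rng.exponential(block_bp)
        founder[j] = cur
    return founder


def derive_inbred(
    wild: GenotypeMatrix,
    sites: pd.DataFrame,
    config: SimConfig,
    wild_freqs: np.ndarray,
    genes: list[GeneModel] | None = None,
    block_bp: float = 50_000.0,
):
    """Inbred panel as homozygous founder mosaics with planted sweeps.

    Inside each sweep region [center-hw, center+hw) all strains carry the
    sweep founder's haplotype except for per-site escapes with probability
    1 - exp(-d / (sweep_escape_factor * half_width)) at distance d from the
    centre; outside the region, each strain follows its own mosaic. The
    escape length scale is deliberately longer than the region half-width so
    the declared region is strongly swept throughout while hitchhiking decay
    still grows with distance, mirroring the scan's own sweep model.
    Returns (GenotypeMatrix, TruthTable).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_sites = wild.n_sites
    chrom_arr = sites["chrom"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1

    haps = _founder_haplotypes(rng, wild, wild_freqs, config.n_founders)
    sweep_founder = 0

    alleles = np.empty((config.n_inbred, n_sites), dtype=np.int16)
    for s in range(config.n_inbred):
        fa = np.empty(n_sites, dtype=np.int16)
        for c in dict.fromkeys(chrom_arr):
            m = chrom_arr == c
            fa[m] = _mosaic_assignment(
                rng, int(m.sum()), pos0[m], config.n_founders, block_bp
            )
        alleles[s] = haps[fa, np.arange(n_sites)]

    # plant sweeps: shared founder haplotype with distance-decaying escape
    for chrom, center, hw in config.sweep_specs:
        in_region = (chrom_arr == chrom) & (pos0 >= center - hw) & (pos0 < center + hw)
        idx = np.nonzero(in_region)[0]
        if idx.size == 0:
            warnings.warn(f"sweep region ({chrom},{center},{hw}) contains no sites")
            continue
        scale = config.sweep_escape_factor * hw
        escape = 1.0 - np.exp(-np.abs(pos0[idx] - center) / scale)
        for s in range(config.n_inbred):
            keep_own = rng.random(idx.size) < escape
            swept = idx[~keep_own]
            alleles[s, swept] = haps[sweep_founder, swept]

    gt = np.stack([alleles, alleles], axis=2)

    # residual heterozygosity and missing calls at bi-allelic sites
    het = rng.random(gt.shape[:2]) < config.het_residual_rate
    gt[:, :, 1][het] = 1 - gt[:, :, 1][het]
    miss = rng.random(gt.shape[:2]) < config.missing_rate
    gt[miss] = MISSING

    samples = [f"inbred_{i:02d}" for i in range(config.n_inbred)]
    gm = GenotypeMatrix(samples, {s: INBRED for s in samples}, gt)

    truth = build_truth(config, genes or [], wild_freqs)
    return gm, truth


def build_truth(config: SimConfig, genes: list[GeneModel], wild_freqs) -> TruthTable:
    regions = [(c, ctr - hw, ctr + hw) for c, ctr, hw in config.sweep_specs]
    sweep_genes = sorted(
        g.gene_id
        for g in genes
        if any(g.chrom == c and g.start < e and s < g.end for c, s, e in regions)
    )
    win = make_windows(config.chrom_lengths())
    sweep_windows = [
        (w.chrom, int(w.start), int(w.end))
        for w in win.itertuples(index=False)
        if not w.short
        and any(w.chrom == c and w.start >= s and w.end <= e for c, s, e in regions)
    ]
    return TruthTable(
        sweep_regions=regions,
        sweep_genes=sweep_genes,
        sweep_windows=sweep_windows,
        wild_freqs=np.asarray(wild_freqs, dtype=float).tolist(),
    )


def merge_panels(wild: GenotypeMatrix, inbred: GenotypeMatrix) -> GenotypeMatrix:
    gt = np.concatenate([wild.gt, inbred.gt], axis=0)
    samples = wild.samples + inbred.samples
    groups = {**wild.groups, **inbred.groups}
    return GenotypeMatrix(samples, groups, gt)


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def make_genes(config: SimConfig) -> list[GeneModel]:
    """Gene models on a regular grid: 20-kb genes every 40 kb, 3 exons each."""
    genes: list[GeneModel] = []
    spacing = 2 * config.gene_length_bp
    per_chrom = int(np.ceil(config.n_genes / config.n_chrom))
    gid = 0
    for chrom in config.chrom_names():
        for k in range(per_chrom):
            if gid >= config.n_genes:
                break
            start = k * spacing + spacing // 4
            end = start + config.gene_length_bp
            if end > config.chrom_length_bp:
                break
            third = config.gene_length_bp // 5
            exons = [
                (start, start + third),
                (start + 2 * third, start + 3 * third),
                (end - third, end),
            ]
            genes.append(GeneModel(f"gene{gid:03d}", chrom, start, end, exons))
            gid += 1
    return genes


# ---------------------------------------------------------------------------
# Expression / DE / qPCR fixtures
# ---------------------------------------------------------------------------

def simulate_expression(
    gene_ids: list[str],
    designated: list[str],
    brain_effect: float,
    seed: int,
    categories: dict[str, str] | None = None,
    sigma_log: float = 0.3,
    de_base_rate: float = 0.10,
    de_designated_rate: float = 0.35,
    phen_base_rate: float = 0.30,
    phen_designated_rate: float = 0.55,
):
    """Gene x tissue RPKM matrix plus DE tables and phenotype flags.

    RPKM is log-normal per gene x tissue; the designated subset is multiplied
    by ``brain_effect`` in the brain-related tissue columns. DE tables (one
    per profiled tissue) carry gene, padj, fpkm with an enriched DE rate for
    the designated set in hippocampus and frontal lobe. Phenotype flags mark
    genes with nervous-system/behavioural mouse-model phenotypes at an
    elevated rate in the designated set. Deterministic given seed.
    """
    if brain_effect <= 0:
        raise ConfigError("brain_effect must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    mapping = categories or expr_mod.DEFAULT_CATEGORY_MAP
    tissues = list(mapping)
    desig = set(designated)
    unknown = desig - set(gene_ids)
    if unknown:
        raise ConfigError(f"designated genes not in gene list: {sorted(unknown)}")

    mu = rng.normal(1.0, 1.0, size=len(gene_ids))
    log_rpkm = mu[:, None] + rng.normal(0.0, sigma_log, (len(gene_ids), len(tissues)))
    rpkm = np.exp(log_rpkm)
    brain_cols = [t for t in tissues if mapping[t] in expr_mod.BRAIN_CATEGORIES]
    dmask = np.array([g in desig for g in gene_ids])
    for t in brain_cols:
        rpkm[dmask, tissues.index(t)] *= brain_effect
    expr = pd.DataFrame(rpkm, index=pd.Index(gene_ids, name="gene"), columns=tissues)

    de_tables: dict[str, pd.DataFrame] = {}
    for tissue in expr_mod.DE_TISSUES:
        enriched = tissue in ("hippocampus", "frontal lobe")
        rate = np.where(dmask & enriched, de_designated_rate, de_base_rate)
        is_de = rng.random(len(gene_ids)) < rate
        padj = np.where(
            is_de, rng.uniform(1e-6, 0.049, len(gene_ids)),
            rng.uniform(0.05, 1.0, len(gene_ids)),
        )
        fpkm = np.exp(rng.normal(1.0, 1.0, len(gene_ids)))
        fpkm[is_de] = np.maximum(fpkm[is_de], 1.01)  # DE genes are expressed
        de_tables[tissue] = pd.DataFrame(
            {"gene": gene_ids, "padj": padj, "fpkm": fpkm}
        )

    phen_rate = np.where(dmask, phen_designated_rate, phen_base_rate)
    phenotype_flags = pd.Series(
        rng.random(len(gene_ids)) < phen_rate, index=gene_ids, name="nervous_phenotype"
    )
    return expr, de_tables, phenotype_flags


def simulate_ct_tables(seed: int, n_per_group: int = 5, effect_log2: float = 1.0):
    """qPCR Ct fixtures: a target-vs-Gapdh table and an isoform a/b table.

    The treatment group's target gene is shifted by ``-effect_log2`` cycles
    (a 2**effect_log2 fold-change); triplicate technical replicates with 0.1
    cycles of noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for grp, shift in (("control", 0.0), ("treatment", -effect_log2)):
        for i in range(n_per_group):
            sample = f"{grp}_{i}"
            base_ref = rng.normal(18.0, 0.3)
            base_tgt = rng.normal(24.0, 0.3) + shift
            for rep in range(3):
                rows.append((sample, grp, "target", base_tgt + rng.normal(0, 0.1), rep))
                rows.append((sample, grp, "Gapdh", base_ref + rng.normal(0, 0.1), rep))
    ct = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct", "replicate"])

    rows = []
    for grp, shift in (("control", 0.0), ("treatment", 0.41)):
        for i in range(n_per_group):
            sample = f"{grp}_{i}"
            a = rng.normal(25.0, 0.3) + shift
            b = rng.normal(25.5, 0.3)
            for rep in range(3):
                rows.append((sample, grp, "isoform_a", a + rng.normal(0, 0.1), rep))
                rows.append((sample, grp, "isoform_b", b + rng.normal(0, 0.1), rep))
    iso = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct", "replicate"])
    return ct, iso


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def generate_bundle(config: SimConfig, brain_effect: float = 4.0):
    """Generate every component of the fixture in memory.

    The designated brain-enriched / DE-enriched gene subset is the planted
    sweep genes (so downstream enrichment mirrors the scan's truth).
    """
    wild, sites, freqs = simulate_wild(config)
    genes = make_genes(config)
    inbred, truth = derive_inbred(wild, sites, config, freqs, genes)
    gm = merge_panels(wild, inbred)
    expr, de_tables, phen = simulate_expression(
        [g.gene_id for g in genes], truth.sweep_genes, brain_effect, config.seed
    )
    ct, iso = simulate_ct_tables(config.seed)
    return {
        "config": config,
        "gm": gm,
        "sites": sites,
        "genes": genes,
        "truth": truth,
        "expression": expr,
        "de_tables": de_tables,
        "phenotype_flags": phen,
        "ct": ct,
        "ct_isoform": iso,
    }


def write_fixture_bundle(bundle: dict, directory: str) -> dict[str, str]:
    """Write a generated bundle to disk; returns the path map.

    Files: genotypes.vcf, genes.bed (BED12), expression.tsv, de_<tissue>.tsv,
    ct.tsv, ct_isoform.tsv, groups.tsv, truth.json, sim_config.json.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(directory, name)
        return paths[name]

    write_vcf(p("genotypes.vcf"), bundle["gm"], bundle["sites"])
    write_genes_bed(p("genes.bed"), bundle["genes"])
    bundle["expression"].to_csv(p("expression.tsv"), sep="\t")
    for tissue, df in bundle["de_tables"].items():
        df.to_csv(p(f"de_{tissue.replace(' ', '_')}.tsv"), sep="\t", index=False)
    bundle["ct"].to_csv(p("ct.tsv"), sep="\t", index=False)
    bundle["ct_isoform"].to_csv(p("ct_isoform.tsv"), sep="\t", index=False)
    gm = bundle["gm"]
    with open(p("groups.tsv"), "w") as fh:
        fh.write("sample\tgroup\n")
        for s in gm.samples:
            fh.write(f"{s}\t{gm.groups[s]}\n")
    truth = bundle["truth"]
    with open(p("truth.json"), "w") as fh:
        json.dump(
            {
                "sweep_regions": truth.sweep_regions,
                "sweep_genes": truth.sweep_genes,
                "sweep_windows": truth.sweep_windows,
                "n_sweeps": len(truth.sweep_regions),
            },
            fh,
            indent=1,
        )
    with open(p("sim_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(bundle["config"]), fh, indent=1)
    return paths
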