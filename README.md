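# domestiscan

Selection scans for domesticated inbred panels: given genotypes of a diverse
**wild** group and a near-homozygous **classical_inbred** group, find genomic
regions where the inbred lineage lost diversity and diverged — the signature
of selection during domestication — and run the downstream enrichment
arithmetic used to interpret the resulting gene list.

Intended for population geneticists who want a desk-scale, fully seeded
re-implementation of the classic three-statistic sweep scan on laboratory
mouse panels (or any wild/inbred contrast), with a synthetic-data generator
so every step is testable without external sequencing data.

## What it computes

For sliding windows (40 kb, 20 kb step by default) over bi-allelic SNPs:

* **π ratio** — per-window nucleotide diversity π_wild / π_classical_inbred,
  with π the window sum of unbiased per-site heterozygosity
  h = n/(n−1)·(1 − Σₐ pₐ²) per bp. Fixation in the inbred panel gives a
  +∞ sentinel that ranks first.
* **Fst** — the ANOVA (Akey-style) estimator per site,
  Fst = (MSP − MSG) / (MSP + (n_c − 1)·MSG), averaged per window without
  clipping negative values.
* **XP-CLR score** — a composite likelihood ratio
  CLR = max(0, 2·max_θ Σ_sites (log L₁ − log L₀)), contrasting a sweep model
  (lineages dragged to fixation, escaping with probability
  c = 1 − e^(−d/θ) at distance d from the window centre) against neutral
  drift (frequency perturbation with variance ω·p(1−p), truncated to (0,1)
  with boundary point masses; ω is calibrated from genome-wide Fst as
  ω = F̄/(1−F̄)).

The top 5% of windows per statistic are mapped to overlapping genes and the
three gene sets intersected into the **PSG list** (positively selected
genes). Companion modules provide: neighbor-joining trees on allele-sharing
distances (wild/inbred separation check), tissue-category expression
enrichment (the inclusive 2-fold "highly expressed" rule over 17 organ
categories, one-sided brain-vs-other rank-sum test, phenotype fold
enrichment), candidate-SNP rules (strict homozygosity rule and the relaxed
f_wild < 0.2·f_inbred frequency rule, allelicity classes), and 2^−ΔΔCt qPCR
fold changes.

## Worked example

Generate the documented synthetic fixture (2 chromosomes × 2 Mb, ~20,000
SNPs, 20 wild + 20 inbred strains from 4 founders, 3 planted sweeps) and
scan it:

```bash
domestiscan sim --seed 123 --out fixture/
domestiscan scan --vcf fixture/genotypes.vcf --groups fixture/groups.tsv \
    --genes fixture/genes.bed --chrom-lengths chr1:2000000,chr2:2000000 \
    --out scanout
# -> 8 PSGs -> scanout.psgs.tsv
```

The 8 PSGs are exactly the 8 genes overlapping the three planted sweep
regions (`fixture/truth.json`). The same run from Python:

```python
from domestiscan import SimConfig, run_scan, filter_sites
from domestiscan.simdata import generate_bundle

bundle = generate_bundle(SimConfig(seed=123))
gm, sites = filter_sites(bundle["gm"], bundle["sites"])
res = run_scan(gm, sites, bundle["genes"], {"chr1": 2_000_000, "chr2": 2_000_000})
print(res["venn"])   # {'n_pi': 8, 'n_fst': 8, 'n_xpclr': 8, ..., 'n_all': 8}
print(res["psgs"])   # ['gene011', 'gene012', 'gene013', 'gene036', ..., 'gene075']
```

`run_scan` returns the per-window statistics table (chrom, start, end,
n_snps, pi_wild, pi_inbred, pi_ratio, fst, xpclr, masked), the three top-5%
window tables, the per-statistic gene sets, and the PSG intersection with
Venn counts. The full pipeline (filter → scan → tree → enrichment →
candidates → qPCR) runs from one YAML config:

```bash
domestiscan run --config run.yaml
```

and writes `report.json` with window counts, top-set sizes, Venn counts, the
PSG list, sweep recall against the generator's truth table, the
monophyly check, enrichment ratios and candidate-SNP counts.

## Enrichment arithmetic

The expression module reproduces the standard reporting conventions: for a
gene set of 286 with 97 genes flagged in one category the reported ratio is
33.9%; a phenotype hit rate of 125/245 against a 30.1% database background
is 51.0% and 1.7-fold enrichment; a site with reference-allele frequency
0.0417 in wild and 0.793 in inbred passes the relaxed candidate rule
(0.0417 < 0.2 × 0.793) while failing the strict rule (not every inbred
sample is homozygous-reference).

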