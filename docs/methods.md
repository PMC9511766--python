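# Methods

## The scan

The package contrasts two labelled sample groups at bi-allelic SNPs: a
diverse *wild* group (the reference population) and a *classical_inbred*
group (the object population, hypothesised to have experienced selection
during domestication). Sites are filtered to single-base REF/ALT with a
single ALT and a missing-genotype fraction strictly below 0.1 over the
merged sample set; genotypes are treated as unphased diploids. Coordinates
are 1-based at the VCF boundary and 0-based half-open internally (BED
convention); every interface that crosses the boundary documents which
convention it uses.

Windows are 40 kb with a 20 kb step, anchored at 0 per chromosome. Window
starts advance while `start + step <= L` (start 0 is always emitted) and the
final windows are clipped at the chromosome end; clipped ("short") windows
are emitted but masked from ranking, as are windows with fewer than
`min_snps` (default 10) SNPs. Interior base pairs are covered by exactly
size/step = 2 windows.

**Nucleotide diversity.** Per site, the unbiased heterozygosity
h = n/(n−1)·(1 − Σₐ pₐ²) over the group's called alleles (sites with fewer
than two called alleles contribute 0); per window, π = Σ h / window length.
This equals the mean pairwise difference per bp over all haplotype pairs,
which is the brute-force oracle used in the tests. The per-window ratio
π_wild/π_inbred is the first ranking statistic. When the inbred panel is
invariant in a window (π_inbred = 0) with π_wild > 0 the ratio is a +∞
sentinel ranked above all finite values — complete fixation is the strongest
possible diversity-loss signal, so it must not be discarded. Windows with
both π = 0 carry no information and are excluded for this statistic only.

**Fst.** The two-population ANOVA estimator per site: with allele counts
n₁, n₂ and frequencies p₁, p₂, p̄ = (n₁p₁+n₂p₂)/(n₁+n₂),
MSP = Σ nᵢ(pᵢ−p̄)², MSG = Σ nᵢpᵢ(1−pᵢ)/Σ(nᵢ−1),
n_c = Σnᵢ − Σnᵢ²/Σnᵢ, and Fst = (MSP−MSG)/(MSP+(n_c−1)·MSG). Sites
monomorphic in both groups are undefined and skipped; raw (possibly
negative) values are averaged arithmetically per window. The alternative
ratio-of-sums window estimator was considered and not used: the mean of raw
per-site values keeps the per-site estimator exactly testable against
longhand evaluation, and at 40-kb windows with ≥ 10 SNPs the two differ
little in rank order, which is all the top-fraction selection consumes.

**XP-CLR-style composite likelihood.** A deliberately simplified variant of
the cross-population composite likelihood ratio. Per window the sweep
position is fixed at the window centre and, for each site at distance d,

* neutral model L₀: the reference frequency p₁ (clamped to
  [1/(2n₁), 1−1/(2n₁)]) drifts to a latent frequency
  q ~ Normal(p₁, ω·p₁(1−p₁)) truncated to (0,1), with the out-of-range
  probability collapsed to point masses at 0 and 1; the object counts are
  then binomial: L₀ = ∫ P(q)·Binom(m₂|n₂,q) dq, evaluated on a 200-cell
  midpoint grid plus the two boundary masses.
* selected model L₁: with escape probability c = 1 − e^(−d/θ), a fraction c
  of lineages escapes the sweep and behaves neutrally, while the remainder
  is dragged to fixation of one allele (the alt allele with probability p₁).
  Because the drift kernel applied to a point mass at 0 or 1 has zero
  variance, L₁ reduces analytically to
  c·L₀ + (1−c)·(p₁·[m₂=n₂] + (1−p₁)·[m₂=0]).

The window score is CLR = max(0, 2·max_θ Σ (log L₁ − log L₀)) over a grid of
15 log-spaced sweep scales θ from 10² to 10⁷ bp. The smallest θ makes c → 1
and L₁ = L₀ exactly, so the neutral model is nested in the grid and CLR ≥ 0
without clipping doing any real work. The drift scale ω is estimated from
the data as F̄/(1−F̄), where F̄ is the mean positive per-site Fst clamped to
[10⁻³, 0.99] — a moment-matching calibration that makes neutral
differentiation score near zero. There is no LD-based SNP down-weighting and
no scan over sweep positions within a window; scores are comparable within a
run, not to the original C implementation. Sites whose likelihood underflows
to zero under either model are skipped with a warning (with the distance
floor of 1 bp this does not occur in practice).

**Ranking and intersection.** Per statistic, the top ceil(0.05 × eligible)
unmasked windows are taken, ordered by statistic descending with ties broken
by (chrom, start) — fully deterministic, +∞ sentinels first. A gene enters a
statistic's gene set iff its span overlaps any selected window by ≥ 1 bp
(gene spans, not transcript bodies; genes straddling several windows count
once). The PSG list is the three-way intersection, reported with all Venn
counts.

## Neighbor joining

The separation check uses the allele-sharing distance: per co-called site,
two diploid genotypes share 0, ½ or 1 (the maximal allele matching over the
two pairings, halved), and d = 1 − mean sharing. Pairs with no co-called
sites are an error naming the pair. The tree is classical Saitou–Nei NJ with
Q-matrix minimisation; ties are broken by the smallest (i, j) pair in the
current node ordering so output is byte-deterministic, and negative branch
lengths are clamped to zero with a warning. No bootstrap — the pipeline only
asks whether the inbred panel forms one side of a bipartition of the
(unrooted) tree.

## Expression and enrichment arithmetic

Tissue columns are merged into organ categories by arithmetic mean. The
default mapping carries the six standard merged groups (immature brain =
embryonic CNS E11.5/E14/E18; brain = cerebellum, cortex, frontal lobe;
immature liver; bowel; immune system; fat) plus eleven singleton organs,
giving 17 categories over 28 tissue columns. A gene is "highly expressed" in
a category when its value is **at least** (inclusive) twice its own mean
over all categories; an all-zero gene gets no flags. Reported fractions are
rounded half-up to one decimal (decimal arithmetic, so printed halves like
1.65 round to 1.7).

The brain-vs-other comparison is a one-sided Mann–Whitney test (brain
greater) with the tie-corrected normal approximation; one-sided because the
question asked of the data is specifically elevated brain expression, and no
multiple-testing correction is applied since raw per-gene counts are
reported. All-tied input returns p = 0.5, flagged. Differential-expression
flags are padj < 0.05 (strict) and FPKM > 1 (strict), where FPKM is the
larger group mean; per tissue the module reports the DE fraction among all
genes, among the gene set, their difference in percentage points, and the
fold (undefined when the background is zero).

## Candidate-SNP rules

The strict rule passes a site iff no wild sample is homozygous-reference and
every classical-inbred sample is homozygous-reference; any missing genotype
in either group makes the site ineligible — conservative and reproducible,
since an unobserved genotype could overturn either clause. The relaxed rule
passes iff f_ref(wild) < 0.2·f_ref(inbred), strictly, with frequencies over
called allele copies (not per strain); f_ref(inbred) = 0 fails. Allelicity
(single/bi/tri) counts distinct alleles among called genotypes per group and
never decreases as samples are added. Note the strict rule does not imply
the relaxed rule in general (wild panels of heterozygotes have
f_ref = 0.5 ≥ 0.2); the implication holds in the special case where all wild
genotypes are non-reference homozygotes.

## qPCR

ΔCt = Ct(target) − Ct(reference) per sample, technical replicates averaged
in Ct space first; ΔΔCt subtracts the **arithmetic mean** ΔCt of the control
group, so the geometric mean of control-group folds is exactly 1 (the
centering statistic is a convention; arithmetic-in-ΔCt was chosen because Ct
is already a log-scale quantity). Fold = 2^−ΔΔCt. Exact invariances, tested
to machine precision: adding a constant to every Ct changes nothing;
swapping target and reference inverts every fold. The isoform a/b ratio
index is the same arithmetic with isoform a as target and isoform b as
reference.

## The synthetic generator

The generator emulates the statistical structure the scan assumes, not the
demographic history of any real panel:

* **Wild panel** — per-site derived-allele frequencies drawn i.i.d. from a
  neutral-SFS-weighted law (allele count i with weight ∝ 1/i^shape,
  default shape 1), genotypes Binomial(2, p) per sample, positions uniform
  per chromosome. There is no linkage within the wild panel.
* **Inbred panel** — each strain is a fully homozygous mosaic of founder
  haplotypes (default 4 founders, one unbiased haplotype lifted from each of
  4 wild samples), with exponentially distributed mosaic blocks of mean
  50 kb. Linkage therefore exists only through the founder-block structure.
  Residual heterozygosity (default 0.2%) and missing calls (default 1%) are
  injected to exercise the filters.
* **Planted sweeps** — inside each declared region [centre−hw, centre+hw)
  every strain carries the sweep founder's haplotype, except per-site
  escapes with probability 1 − e^(−d/(k·hw)) at distance d, k = 10 by
  default. The escape length scale is deliberately longer than the region
  half-width: the package's own planted-contrast requirement (mean π_inbred
  over sweep windows below one tenth of the non-sweep mean) needs the region
  strongly swept throughout, while escape still increases with distance, the
  same functional form the scan's selected model assumes.

Default fixture: 2 chromosomes × 2 Mb, ~20,000 SNPs, 20 wild + 20 inbred
samples, 100 genes of 20 kb on a 40-kb grid (3 exons each), 3 sweeps of
half-width 40 kb with centres on the 20-kb window grid, seed 20220806
(`FIXTURE_SEED`). The geometry is deliberate: region edges on the window
grid mean a shoulder window overlaps a sweep by at most half a window, so
the nine fully-swept windows (three per sweep) outrank all shoulders in
every statistic and fit inside the top-5% budget of ceil(0.05·198) = 10
windows; the recovery property (100% sweep-gene recall, ≤ 5% non-sweep
genes in the PSG list) is then structural rather than seed-dependent, and
holds for every seed tried.

Expression fixtures are log-normal RPKM (gene-level mean ~ N(1,1), tissue
noise σ = 0.3 in log space) with a designated gene subset multiplied by a
brain effect (default 4×) in the six brain-related tissue columns; DE tables
carry elevated DE rates for the designated set in hippocampus and frontal
lobe; Ct tables simulate a 2-fold target induction and a 0.41-cycle isoform
shift with 0.1-cycle technical noise. Everything is a pure function of
(config, seed); all seeds derive from the config seed via SeedSequence.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no coalescent genealogy or recombination map, no
population structure within the wild group (real wild mice span three
subspecies), no LD in the wild panel, no ascertainment or genotyping error
beyond uniform missingness, equilibrium-free SFS (frequencies i.i.d. across
sites), and sweep regions with known, planted boundaries. Recovery rates on
this fixture validate the statistical machinery, not performance on real
resequencing panels, whose headline gene counts depend on data not shipped
here.

## Problem sizes and determinism

The shipped fixture scale (~20,000 SNPs, 40 samples, ~200 windows) was
chosen so the full pipeline — generation, filtering, all three statistics,
tree, enrichment — completes in seconds while every window still carries
~200 SNPs, comfortably above the masking threshold. The acceptance script
reruns the complete study from scratch at this scale under an arbitrary
seed. Scores, rankings, trees and reports are deterministic given (config,
seed); ranking ties and NJ ties have fixed, documented tie-breaks.

## Known limitations

* The XP-CLR variant fixes the sweep position at the window centre and
  ignores LD between sites, so absolute scores are not comparable to the
  original implementation; only within-run ranks are used.
* Window Fst as a mean of raw per-site values is noisier than ratio-of-sums
  at low SNP counts; windows below `min_snps` are masked rather than
  shrunk.
* The site classifier collapses annotation to exonic/intronic/intergenic
  with that precedence; UTR/splice/up-downstream classes are out of scope.
* The strict candidate rule's missing-genotype policy (ineligible) is
  conservative; panels with high missingness will under-report strict
  passes.
* `category_ratio` and the DE-ratio module consume whatever tables they are
  given; they do not recompute differential expression.
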