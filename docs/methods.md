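# Methods

This note documents the models, estimators, and design choices behind
`intronret`, and what the synthetic cohort does and does not emulate.

## Intron units and the IR ratio

Introns are the gaps between adjacent exons of a transcript, deduplicated
per gene by (chrom, start, end, strand). Because other transcripts' exons
can overlap an intron, each unit carries *exclusion zones* — the union of
all annotated exons genome-wide intersected with the intron — and only the
remaining *measurable* positions contribute to intronic depth. Coordinates
are 0-based half-open internally; GTF I/O is 1-based inclusive and
BED/bedGraph 0-based half-open, matching each format's convention.

For one intron in one sample:

- `junction_count` — reads containing a splice gap whose endpoints equal
  the intron boundaries exactly. Partially overlapping gaps are ignored so
  other isoforms' junctions are not credited.
- `intronic_depth` — the **median** per-base depth over measurable
  positions, counting only contiguous aligned blocks. The median is robust
  to pile-ups at exclusion-zone edges; it is the depth statistic throughout
  and is deliberately simple rather than a trimmed mean.
- `ir_ratio = intronic_depth / (intronic_depth + junction_count)`,
  undefined (and flagged) when both are zero.

Reads on either strand are counted (unstranded mode); 5'/3' splice-site
identity is always strand-aware (on the − strand the 5' site is the higher
coordinate). An *IR event* is an intron with ratio ≥ `t_ratio` (0.1),
depth ≥ `t_depth` (3), and depth + junctions ≥ `t_total` (10); the
thresholds are exposed because event counts are threshold-dependent by
nature. Cross-sample comparisons of event counts first subsample every
sample's alignments, uniformly without replacement, to the smallest
fragment count so depth differences cannot masquerade as biology.

## Two-group negative-binomial Wald test

All differential analyses test counts `K_ij ~ NB(E_ij · m_g, α_i)` where
`E` is a per-sample exposure and `m_g` the group rate. Group rates are
estimated as `Σ K / Σ E`; the per-feature dispersion is a pooled
within-group method-of-moments estimate floored at 1e-4, with no
empirical-Bayes shrinkage — a transparent estimator that costs some power
relative to shrinkage-based packages but keeps the test self-contained.
The Wald statistic is the log rate difference over its delta-method
standard error. Because the plug-in dispersion is noisy at typical group
sizes (n around 6), p-values use a **t reference with nA + nB − 2 degrees
of freedom** rather than a normal: in simulation at n = 6 vs 6, µ = 100,
α = 0.1, the normal reference gives a type-I error near 0.078 at α = 0.05
while the t reference sits near 0.05 with no measurable power loss at
4-fold effects. Zero-total features are flagged with p = 1. BH adjustment
is applied within each feature family (genes, introns, exons) separately.

Exposure choices:

- **genes**: median-of-ratios size factors (geometric-mean reference;
  total-count fallback when no feature is present in all samples);
- **introns**: per-sample `intronic + junction` evidence, so the null is
  "equal retention fraction", not "equal intronic abundance". ΔIR is
  reported as the difference of group-mean per-sample IR ratios
  (first-named group minus second);
- **exons**: host-gene counts, testing relative usage
  `with / (with + without)`; direction is the sign of the usage change in
  the first-named condition.

Log2 fold changes are first-named over second-named group throughout, so
"diagnosis vs control" reads the usual way.

## Methylation

DMR calling is a deliberately simple Fisher-plus-merge procedure, not an
HMM: per CpG, counts are pooled within each group and compared by Fisher's
exact test; BH runs across CpGs; CpGs with q < α (0.05) and per-site
|delta| ≥ 0.1 merge into a region while consecutive significant CpGs are
≤ 250 bp apart and share a direction; regions need ≥ 5 significant CpGs.
The region delta is the coverage-weighted mean per-site difference, a
proportion in [−1, 1]. Its validation surface is planted-region recovery
(interval Jaccard), not any particular genome-wide DMR count. DMR-to-
feature assignment for density summaries uses the region midpoint against
a per-base feature map with fixed priority
exon > 5'UTR > 3'UTR > promoter > intron > intergenic (promoter = 2 kb
upstream of the transcript start, strand-aware); a fixed priority makes
densities reproducible where annotations overlap.

Metaprofiles aggregate `Σ methylated / Σ total` per strand-oriented offset
in ±200 bp windows at the 5' and 3' splice sites and a 200 bp centre
window. Introns shorter than 600 bp shrink the centre window to the region
between the two splice-site windows; below 20 bp the intron drops out of
the centre anchor. Offsets with no CpG carry zero weight rather than a
zero methylation value. The retained vs non-retained group test is a
binomial GLM of per-intron aggregated counts on the group indicator
(realizing a general linear hypothesis test), with a permutation
alternative (intron labels shuffled) for calibration checks.

## Chromatin and integration

Peak enrichment counts peaks (not covered bases) overlapping the
strand-oriented splice-site windows and the intron body; a peak touching
two zones counts in each. Genes with TPM > 0 split into four expression
quartiles (stable order breaks ties) and retained vs non-retained
per-intron counts are compared per quartile by a Mann–Whitney U test
(exact for group sizes ≤ 8 without ties), so an enrichment that merely
tracks expression would surface as a quartile-dependent effect.

TPM is `1e6 · (count/length) / Σ (count/length)` with spliced transcript
length as the effective length. The inverse-relationship screen flags
introns with |ΔIR| ≥ 0.1 whose host gene has |log2FC| ≥ 1 with the
opposite sign; the fold-change threshold is interpreted in log base 2. The
IR-frequency correlation is a per-gene Spearman rho between TPM and
per-sample IR event counts; published figures of this kind print the
coefficient with a "p =" label, which is read here as rho (a negative
p-value being impossible).

## Synthetic cohort

The generator emulates the statistical structure the analyses assume, with
defaults chosen as a realistic small bulk cohort: 20 genes × 3 exons
(300 bp) on one contig, single-end 100 nt fragments, NB dispersion 0.1,
10/10/6 diagnosis/remission/control samples, gene means log-uniform in
[100, 1000] expected fragments. Ten introns are "affected": retention
rises from 0.05 to 0.30 at diagnosis and 0.35 in remission (remission at
least as high as diagnosis, mirroring the cohort pattern the design
targets); affected introns are shorter (400 vs 800 bp) and GC-richer
(0.60 vs 0.45), the intrinsic features of retained introns. The host genes
of five affected introns drop expression 4-fold at diagnosis, planting
inverse IR/expression relationships; keeping expression changes a minority
of genes is required for median-of-ratios normalization to hold, and an
early all-hosts-changed variant measurably biased every fold change.

Fragments sample a transcript molecule (retained or spliced per intron)
with probability proportional to molecule abundance × start positions,
then a uniform start. Under this model the retaining fraction of
boundary-spanning fragments is exactly r, which is the quantity the IR
ratio estimates; junction reads arise only from spliced molecules whose
read crosses the boundary. Methylomes are Poisson-coverage (mean 30) /
binomial-methylation tracks at every genomic CpG, level 0.8 dipped by 0.3
inside retained introns; the dip does not extend into exons so exonic
flanks act as internal negative controls. Peaks are a Poisson process with
rate 0.02/bp in ±200 bp splice-site windows of retained introns vs
0.005/bp elsewhere, width 50 bp.

Not emulated: sequencing error, base quality, paired ends,
fragment-length distributions, bisulfite conversion inefficiency, isoform
mixtures beyond binary retention, batch effects, and cell-type
composition. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to those real-data
phenomena.

## Determinism and numerical choices

Every stochastic routine takes a seed; stage-level generators derive from
the run seed via a stable SHA-256-salted SeedSequence, so stages are
individually reproducible and a rerun of the pipeline is byte-identical
(the manifest records parameter values and SHA-256 hashes of all outputs).
Ties in quartile assignment break by stable gene order; intron IDs encode
gene, contig, and coordinates so joins are unambiguous. Degenerate inputs
(zero-evidence introns, all-zero features, constant expression vectors,
empty groups) are flagged or rejected with named errors rather than
produce silent NaNs. Test and acceptance problem sizes (for example 40–50
replicates per retention level, 2000 null features, 120 permutation
replicates) are chosen so Monte-Carlo error is comfortably inside each
assertion's tolerance while a full run stays in the tens of seconds.

## Known limitations

- The dispersion estimator is per-feature; at very low counts the
  floor dominates and the test is conservative.
- The DMR caller has no beta-binomial layer, so biological replicate
  overdispersion would inflate its CpG-level significance on real data.
- Gene counting assigns a read by its start position, which undercounts
  reads of overlapping genes; the synthetic genome has none.
- The offset-based differential-IR design tests retention fraction; it
  does not model isoform-specific intron sharing across transcripts.
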