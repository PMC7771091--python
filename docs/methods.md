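# Methods

This note documents the statistical model, the conventions and numerical
choices behind `paretoseq`, what the synthetic generator does and does not
emulate, and the known limitations.

## Coordinates and gene models

GTF input is 1-based with inclusive ends; every internal interval is
0-based half-open. The TSS of a transcript is its start field on the '+'
strand and its end field on the '−' strand; transcripts sharing a start
contribute a single TSS, so a gene has one promoter window per *distinct*
TSS (identical windows would otherwise be double-weighted by the
weighted-mean matcher). The gene body is the genomic span from the gene's
minimal start to maximal end over all its transcripts, not the exon union:
body-mode counting is meant to capture broad co-transcriptional marks such
as H3K36me3, which cover introns as well as exons.

The promoter window for a 1-based TSS *t* is `[t−1−w/2, t−1+w/2)` with
`w = promoter_size` (default 5000 bp, configurable, must be even),
clipped at position 0. Every unclipped window has length exactly *w*. The
window is placed by the same formula on both strands; because an
even-length half-open window is necessarily asymmetric about its center
base (w/2 bases left of the TSS, w/2−1 right), strand-mirroring a gene
mirrors the window up to that one-base offset. Overlapping windows of the
same gene are kept separate — the *highest* strategy needs per-promoter
values — and a read overlapping two windows is counted in both.

## Read counting

A ChIP-Seq read counts toward every region its aligned span overlaps by at
least 1 bp. Unmapped, secondary and supplementary alignments are always
excluded; mapping-quality and duplicate-flag filters are off by default
(min_mapq = 0, duplicates kept) and configurable. Paired-end mates are
counted as independent segments; no fragment reconstruction or read
extension is attempted. Counting is strand-agnostic (ChIP fragments carry
no strand information about the mark). These choices make counting
deterministic, additive over files, and invariant to read order.

## Gene-level expression

Transcript-level `est_counts` are summed per gene and rounded half away
from zero only after summation, so per-transcript rounding error does not
accumulate. TPM values are carried through but not used by the
differential stage, which operates on counts.

## Differential estimates and Z scores

All layers are normalized with median-of-ratios size factors: the
reference for gene *g* is the geometric mean of its counts across samples
(genes with any zero count are excluded from the reference); the factor
for sample *s* is the median over those genes of count/reference. A gene
with identical counts in every sample contributes a ratio of exactly 1 by
construction, so identical samples get factors of exactly 1. If no gene is
positive everywhere (sparse data), an optional positive-counts reference
(`allow_pseudo_reference`) uses each gene's positive entries only.

For each layer, with normalized counts *n* and pseudocount *pc* (default
0.5, the standard half-count continuity correction):

* `logfc_g = log2((mean_B n + pc) / (mean_A n + pc))` — moderated by the
  pseudocount, antisymmetric under condition swap;
* `se_g` = Welch-pooled standard error of the per-condition means of
  `log2(n + pc)`, floored at `se_min` (default 0.05). The floor keeps the
  standardized fold change finite; with a single replicate in either
  condition no variance is estimable and `se_g = se_min` uniformly, which
  is logged prominently because every Z score then degenerates to a
  rescaled product of fold changes.
* Optional shrinkage multiplies `logfc` by `tau² / (tau² + se_g²)`, with
  the prior variance `tau² = max(0, var(logfc) − mean(se²))` estimated
  across genes (method-of-moments; a fixed `prior_scale` can be supplied
  instead). Shrinkage attenuates noisy, low-replicate estimates toward 0,
  never increases a magnitude, never flips a sign, and preserves the
  ordering of |logfc| at equal SE. It is applied to both the RNA and the
  ChIP layers before combination. This deliberately simple estimator keeps
  the qualitative contract of a count-model differential fit — a moderated
  logFC with a per-gene uncertainty that grows when counts are low,
  dispersion high, or replicates few — while remaining fully transparent;
  users who want a full negative-binomial GLM fit can import its
  (logFC, SE) table directly via `DiffResult.from_tsv`.

The per-gene, per-mark Z score is the product of the two standardized fold
changes, `Z = (logfc_RNA/se_RNA) · (logfc_ChIP/se_ChIP)`. The
"sd(logFC)" entering the standardization is the per-gene standard error of
the estimate, not an across-gene standard deviation: an across-gene
constant could not reflect gene-specific uncertainty and would make Z a
mere rescaling of the fold-change product. Z is invariant under swapping
the condition labels (both fold changes negate), and its sign follows the
table (up,up) → +, (up,down) → −, (down,down) → +, (down,up) → −.

Genes missing from any layer (e.g. no promoter counts for one mark) are
dropped before Z computation and ranking, with the drop count logged; a
missing objective would leave dominance undefined, and imputation would
manufacture evidence.

## Pareto ranking

Mark direction enters in exactly one place: repressive marks' Z scores are
negated so that every objective is maximized. Gene *a* dominates gene *b*
iff *a* ≥ *b* in every signed objective and > in at least one; front 1 is
the non-dominated set, and successive fronts are obtained by removing the
current front and repeating. Identical vectors never dominate each other
and share a front. Fronts are invariant under any strictly increasing
per-objective transform, and with a single mark they reduce to the rank
order of the signed Z (ties sharing a front). The production
implementation peels a vectorized O(n²) pairwise dominance matrix (n²k
booleans; fine for the tens of thousands of genes of a mammalian
annotation in the k ≤ 6 regime this tool targets); an independent naive
pure-Python peeling loop is kept as a test oracle. Output rows are ordered
by ascending front, then gene id, for deterministic files.

## Correlation QC

The sample × sample matrix uses Spearman rank correlation over the gene-id
intersection of all layers, on log2(x+1)-transformed values (rank
correlation is invariant to strictly monotone transforms; the transform
matters only through ties). A constant sample column has no defined rank
correlation and is reported as NaN, not 0.

## Enrichment

The enrichment score of a gene set G for a term *i* is the exact fraction
|G ∩ GO_i| / |G|, computed cumulatively over pooled fronts 1..i. Term
membership comes from a user-supplied two-column table; no ontology
propagation or significance testing is performed — the score describes a
ranking, it does not test a hypothesis.

## Synthetic experiments

The generator emulates a replicated two-condition design on a single
synthetic chromosome: genes of 8 kb spaced 30 kb apart (so promoter
windows of different genes never collide), 1–3 TSSs per gene 1.5 kb apart,
alternating strands. Counts are negative-binomial with size (dispersion)
parameter 10 and per-feature lognormal baseline means (RNA: meanlog 5.0,
sdlog 1.0; promoter ChIP: meanlog 4.5, sdlog 0.8; gene-body ChIP: meanlog
5.5) — overdispersion and mean ranges typical of moderately sequenced
experiments. Planted genes multiply the condition-B mean by
2^(±effect_size) (default effect 2.0) in each layer according to their
class: concordant-up (expression up, activating marks up, repressive marks
down), concordant-down (the mirror image), discordant (expression up but
every mark moving the inconsistent way), null. Defaults plant 10 genes per
class among 500 genes with 2 replicates per condition. Gene counts are
split over transcripts with per-gene Dirichlet weights so the abundance
files exercise real aggregation; SAM emission (optional) places ungapped
reads uniformly *inside* their target window, so counting them back
recovers the targets exactly whenever windows are disjoint (single-TSS
configurations guarantee this; overlapping same-gene windows double-count
boundary-spanning reads by design).

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: baseline covariation between expression
and mark abundance (each layer's baselines are independent, so the QC
correlation matrix is near zero on synthetic data, unlike real
chromatin); peak-shaped read pile-ups, input/IgG background, duplicate
and mapping artifacts; enhancer signal; partial concordance (a gene whose
marks respond heterogeneously); library-size imbalance beyond what NB
noise induces.

The end-to-end validation ("planted-signal recovery") plants 10
concordant-up and 10 discordant genes among 500 and requires, in ≥ 95% of
20 seeded runs, that at least 8 of the 10 concordant-up genes land in the
first 3 Pareto fronts, with discordant genes no more frequent in front 1
than null genes. Concordant-down genes are deliberately *not* planted in
this benchmark: the method rewards consistency in either direction, so
down-class genes correctly share the early fronts with the up class and
would make "up-class recovery within a fixed number of fronts"
ill-defined rather than measure anything about sensitivity.

## Numerical and degenerate-input conventions

* Rounding of aggregated counts and of real-valued matched signal: half
  away from zero.
* *highest* matching ties: the promoter with the smallest TSS coordinate;
  the selection statistic (mean raw count across all samples of the mark)
  is an across-sample quantity, so one consistent promoter represents the
  gene in both conditions — a per-sample argmax would conflate promoter
  switching with abundance change.
* weighted.mean with all-zero weights: unweighted mean (all-zero
  promoters give 0).
* Genes with all-zero counts in both conditions are excluded from
  differential estimates.
* `tau² = 0` in auto shrinkage (fold-change variance below average
  squared SE): every logFC is shrunk to 0, with a warning — the data
  carry no detectable signal beyond noise.
* Empty inputs (no genes, no regions, empty gene-set) raise validation
  errors rather than returning empty results silently.

## Limitations

Promoter windows attribute signal by proximity only; enhancer–gene
assignment is out of scope (published target-gene predictors disagree too
much to build on). The built-in differential estimator is a transparent
approximation, not a full NB GLM; for publication-grade fold changes,
import them from a dedicated tool. The ranking is relative — Pareto fronts
carry no significance level, and front sizes depend on the number of marks
(more objectives mean larger fronts). Reported fronts cover all genes; the
`max_front` option merely truncates the output list.
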