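# Methods

This note documents the models and procedures implemented in `lncsynt`, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical and design choices made where the problem was
genuinely open.

## Coordinate model and file formats

All internal coordinates are 0-based half-open on a single convention;
1-based closed GTF/GFF3 (and 1-based wiggle) coordinates are converted only
at the parse/write boundary. The GTF/GFF3 reader is deliberately small and
line-addressable: a malformed attribute column raises an error naming the
offending line, and write → parse → write reproduces byte-identical GTF,
which the test suite uses as a round-trip oracle. UCSC chains are validated
on parse: the block sizes plus target/query gap sums must equal the header
spans, and the last block must close both gaps.

Conservation tracks expand to per-base arrays with NaN for uncovered bases.
Uncovered bases count as 0 when averaging (UCSC tracks leave unalignable
bases uncovered, and an unalignable base is evidence of non-conservation);
`missing="exclude"` restricts the mean to covered bases instead.

## The five conservation assessments

* **Symbol.** Case-normalized symbol equality (human upper case, mouse
  title case collapse to one key) intersected with a whitelist of
  previously established conserved lncRNAs. Duplicated symbols within a
  species pair all combinations and log a warning.
* **Global synteny.** `lift_interval` maps each base of a span through the
  blocks of every chain on that chromosome, takes the chain mapping the
  most bases, and returns the envelope of the mapped bases in forward query
  coordinates; spans mapping less than `min_map_fraction` (default 0.5, the
  chain coverage required before a lift counts) return nothing. A pair is
  globally syntenic when the lift-over overlaps the partner by at least
  `min_liftover_overlap` (default 1 bp, strand-agnostic) in **both**
  directions. Both defaults are configurable because the underlying
  literature specifies neither.
* **Local synteny.** Nearest non-overlapping coding genes left and right of
  the lncRNA within 500 kb (genomic left/right, not transcription-relative,
  matching how local-synteny diagrams are drawn). A flank absent from the
  ortholog table counts as non-conserved and disqualifies the lncRNA. Flank
  keys are orientation-normalized (sorted ortholog pair) so an inverted
  segment still matches. One lncRNA per interval in both species pairs
  directly; several pair by reciprocal best alignment hits at the same
  identity threshold (0.8) as the sequence method.
* **Sequence.** Reciprocal best local alignments of the exonic (spliced)
  sequences; identity ≥ 0.8 on both legs and E ≤ 1e-5 on the mouse-to-human
  leg. Surviving pairs are kept only if the maximum 200 bp / 50 bp-step
  sliding-window mean of the per-base conservation score over the lncRNA's
  exonic bases exceeds 0.58 in **either** species (the source method is
  ambiguous about which species' track is decisive; either-passes is the
  permissive reading and is evaluated on the lncRNA's exonic span, not the
  alignment region).
* **Promoter.** Reciprocal best plus-strand alignments of the 500 bp
  strand-aware promoters, identity ≥ 0.8, E ≤ 1e-10. The promoter length
  reuses the 500 bp definition of the TF-binding analysis.

Merging takes the union of per-method pairs; a pair's tier is `conserved`
with one flag and `high_confidence` with two or more, and a gene's tier is
the maximum over its pairs (all pairs are kept and multi-pair genes are
logged).

### Alignment engine

Alignments use Biopython's `PairwiseAligner` in local mode
(match +2, mismatch −3, gap open −5, extend −2, blastn-like). A candidate
pair is only aligned if the two sequences share an exact 11-mer
(seed-and-extend in spirit; planted homologs at ≥ 80% identity share many
11-mers, random 500-mers rarely do, so this is a pure speedup at fixture
scale). E-values use Karlin–Altschul-style scaling with fixed constants
(λ = 0.625, K = 0.41, configured and documented rather than fitted): bit
score b = (λS − ln K)/ln 2, E = m·n·2^(−b) with n the summed target length.
These E-values rank and threshold correctly at fixture scale but are not
BLAST-calibrated; all planted/random separations the tests rely on are
orders of magnitude wide.

`window_max_mean` evaluates windows at offsets 0, 50, 100, … < length;
windows reaching past the end (and arrays shorter than one window) are
averaged over the available bases, so a short terminal stretch of high
conservation still counts. The suite checks equality with a naive
enumeration over random arrays.

## Positional classes, structure, repeats, disease

Positional classification follows FEELnc-style rules with precedence
antisense → intronic → divergent → intergenic/other: antisense is
exon–exon overlap with a coding gene on the opposite strand; intronic is
full containment in one coding intron (either strand); divergent is
non-overlapping, opposite strand, head-to-head, TSS-to-TSS ≤ 1,000 bp (the
FEELnc-style default; configurable); sense overlap falls into `other`.

Exon number per gene is the maximum over transcripts (configurable to
union-exon count) — gene-level aggregation is never specified in the
source literature, and the maximum tracks the "most complete isoform"
reading. TE content is the fraction of region bases covered by the union
of repeat intervals (exonic, intronic, or whole-span), undefined (NaN) for
empty regions. Disease linkage is exonic SNP containment (half-open) or
membership in ≥ 1 eQTL row; the per-(category, group) proportion is
n(category ∩ group) / (N(category) · N(group)), which normalizes away both
category prevalence and group size and therefore does not sum to 1 over
categories. Balanced resampling draws n = 500 per group, 1,000 times
(seeded), and reports the fraction of replicates in which group a's
statistic exceeds group b's.

## Expression

CPM is raw library-size scaling (counts × 1e6 / column sum); TMM-style
factors are deliberately not applied because only "CPM" is specified.
Detectability is mean tissue CPM strictly greater than 0.5. Fractional
expression divides each tissue's mean CPM by the gene's summed mean CPM;
its maximum is the tissue-specificity score, and the tissue-specific
percentage curve is the survival function of that score over thresholds
0.1–0.6. Neighbor pairs are all lncRNA–coding pairs whose spans overlap or
lie within 50 kb; pair distance is the span gap (0 when overlapping).
Correlation is Spearman over samples on CPM (rank-based, so the CPM vs
log-CPM question is immaterial).

The distance-matched null samples an observed pair, then a random
lncRNA–mRNA pair from the same distance bin (default 5 kb; empty bins widen
symmetrically with a warning). The observed pairs themselves are excluded
from the candidate pool by default: a null that can re-draw the pairs under
test inherits their correlation, which at fixture scale (where most
same-bin pairs are planted) would put the null's upper tail at the planted
effect — and a reference null centered at zero is only obtainable from
non-observed pairs. Fixture tests match at 500 bp bins because the
fixture's distances compress into ~12 kb where real genomes spread over
50 kb; the relative resolution is the same.

## TF-motif enrichment

Promoters are 500 bp strand-aware upstream windows (minus-strand promoters
reverse-complemented, contig-edge truncation logged). Scanning is a
log₂-odds scanner over both strands with pseudocount 0.25 per PFM cell and
an order-0 background (uniform by default; `set_background_from_promoters`
mirrors FIMO's promoter-frequency background). Log-odds are rounded onto an
integer lattice (granularity 1e-4 score units); the null distribution of
the integer window score under the i.i.d. background is computed by exact
convolution across motif columns, so the reported p-values are exactly the
tail probabilities of the scores actually assigned — the test suite checks
equality against exhaustive 4^w enumeration for widths ≤ 8. The occurrence
threshold is the smallest integer score with tail probability ≤ the p-value
threshold (default 1e-4, FIMO's default). Note a hard floor: a width-w
motif on a uniform background cannot produce p below 4^(−w), so width-8
motifs can only ever report near-consensus words at 1e-4.

The percentage screen computes AB, CD per motif, R as the median of the
pooled {AB} ∪ {CD} over all motifs (computed once globally, not per
subset), PR = |(AB+R)/(CD+R)| and PM = |AB−CD|; the density screen does the
same with per-promoter mean occurrences M, N. The rendered source formula
for DR is read as |(M+R)/(N+R)| by parallel with PR. Flags require three
conditions: the 90th-percentile screen on PR/PM (resp. DR/DM) across the
current run's motifs, a direction guard AB > CD (resp. M > N) so depletion
cannot be reported as preference, and BH-adjusted significance
(two-proportions z with pooled variance; Mann–Whitney U on the count
vectors) at q < 0.05. The percentile screen structurally caps the flaggable
fraction near 10% of the panel — consistent with genome-scale runs that
flag ~50 of ~580 motifs — which is why the default synthetic panel holds
50 motifs with 4 planted (8%). TF-level peak counting deduplicates TF
names for "TF types" but sums sites across experiments of the same TF
(both behaviors switchable).

## Perturbation validation

The default differential-expression engine is a self-contained exact
conditional test: per gene, conditioned on the pooled count, the treated
count is Binomial(total, s) with s the treated library share; the p-value
doubles the smaller exact tail (capped at 1), and BH gives q. This test is
exact under Poisson sampling and anti-conservative under overdispersion;
the `nb_wald` option fits a within-arm moment-matched negative binomial
(dispersion estimated per arm so the treatment effect is not absorbed into
the variance) and tests the log-ratio of CPM means by a Wald z. Dispersion
moderation as in dedicated DE packages is out of scope; planted-signal
recovery and error control, not p-value matching, are the validated
properties.

log₂ fold changes come from mean CPM with pseudocount 0.5. The
abundance adjustment regresses log₂FC on log₂ pooled mean CPM (OLS) over
genes above 0.5 CPM in both arms and keeps the residual; the pooled mean
(rather than control-arm mean) is used because the source is silent and
the pooled mean is symmetric under arm exchange. Group shifts compare
adjusted values between conserved and non-conserved lncRNAs by two-sided
Mann–Whitney U. Response proportions compare the regulated fraction per
group by the two-proportions z-test. The binding null is the empirical
quantile of each focal TF's conserved-binding proportion in the all-TF
distribution, flagged at the top 5%. Overexpression/knockout concordance
is the Spearman correlation of log₂FC over shared genes above the CPM
floor in both arms of both experiments.

## The synthetic data generator

`generate_genome_pair` lays out orthologous coding genes (two exons,
10 kb span) in identical order on two 2 Mb chromosomes per species and
plants one lncRNA per inter-ortholog interval. Default study conditions:
72 coding pairs (enough intervals for 10 lncRNAs in each of the six
classes with one interval per lncRNA), substitution-only divergence at
95% exonic identity for the sequence class and 90% for promoter-class
promoters, conservation-track levels 0.9 (conserved classes) vs 0.1
(non-conserved), TE coverage 0.3 vs 0.1, and a positional-style mix of
60% intergenic / 20% antisense / 10% divergent / 10% intronic.

Two construction rules keep the per-method confusion matrix clean:

* The local class is planted off-chain (chains cover only coding genes and
  global-class lncRNAs), so the local-synteny method is its only detector.
* Every **non**-local lncRNA receives an adjacent species-specific "guard"
  coding gene absent from the ortholog table (plus an overlapping "host"
  gene for antisense/intronic styles), so its nearest flanks are never an
  orthologous pair and local synteny cannot fire on it. Guard distances
  are randomized (2–13 kb by style) so planted neighbor pairs and their
  non-planted analogues share distance distributions. Local-class lncRNAs
  keep intergenic or divergent styles: an antisense/intronic local lncRNA
  would widen its flanking interval across a neighboring slot and break
  the one-lncRNA-per-interval planting rule.

Expression: negative-binomial counts (dispersion 0.1) over a 16-tissue
body-map-style panel with 6 replicates each (96 samples) and ±30% library
sizes. Sixteen tissues matter: with fewer, a uniformly expressed gene's
maximum fractional expression (1/T) sits above the lowest specificity
threshold (0.1) and the specific/broad curves cannot separate there.
Non-conserved lncRNAs concentrate 90% of their expression in one tissue;
conserved lncRNAs are broad. Planted neighbor pairs follow a Gaussian
copula with latent correlation 2·sin(π·ρ/6) for target Spearman ρ = 0.9
and flat tissue profiles (tissue-profile noise would attenuate the rank
correlation below target). Perturbation arms (4 replicates each) multiply
planted-TF targets — all conserved lncRNAs — by 2^1.0; neutral TFs hit a
random 15% of genes irrespective of conservation; the knockout experiment
has its **own** control arm (sharing one control correlates the two
fold-change vectors through the control noise and would mask the planted
anti-correlation, and the emulated knockout is an independent experiment).

Motifs: 50 random informative PFMs (width 8, 85/5/5/5 columns), 4 planted
as enriched; embedded sites are the consensus word (high-affinity sites —
necessarily, given the 4^(−w) p-value floor above) at Poisson rate 0.05
background plus 0.8 in conserved-class promoters. Per-TF peak files cover
the human embeddings (200 bp peaks) plus 30 uniform noise peaks. Disease
catalogs plant exonic SNPs and eQTL links in 30% of conserved vs 10% of
non-conserved lncRNAs over a four-category vocabulary.

Everything is a pure function of (config, seed): re-running with the same
seed writes byte-identical files.

### What the generator does not emulate

Indels and rearrangements (substitution-only divergence keeps the
alignment oracle exact), realistic repeat families, isochores and GC
heterogeneity, splice-site sequence, multi-isoform complexity beyond exon
counts, batch effects across pooled cohorts, and genome-scale annotation
sizes. Consequently, passing tests demonstrate correctness of the
*procedures* and recoverability of *planted* signal under controlled
conditions — not that real GENCODE/FANTOM5-scale analyses would reproduce
any particular published count, which depends on external database
releases.

## Problem sizes

The default fixture (120 lncRNAs, 213 genes/species, 2 × 2 Mb) runs the
full five-method classification in ~10 s on one CPU. Test and acceptance
problem sizes: 1,000 random intervals for the lift-over oracle, 1,000
random arrays for the window oracle, 20 random PFMs (widths 4–8) for
scanner exactness, 200 replicate null datasets (500 promoters/group, 50
motifs) plus 50 power replicates for the enrichment screens, 10,000 null
replicates for test calibration, and 20 seeded replicates of the
perturbation-recovery analysis.

## Known limitations

* E-values are internally consistent but not BLAST-calibrated; porting
  thresholds to real BLAST runs requires re-tuning.
* The exact conditional DE test assumes Poisson sampling; use `nb_wald`
  for overdispersed designs (the generator's arms are overdispersed).
* The 90th-percentile enrichment screens are relative to the analyzed
  motif panel; a panel consisting mostly of truly enriched motifs would
  mask itself.
* `binding_null_quantile`'s top-5% flag needs a TF panel large enough that
  single ranks move quantiles by < 5% (≥ 20 enforced with a warning; the
  default 50-TF panel gives rank-resolution 2%).
* Genes with multiple annotated loci (patch scaffolds) keep their first
  locus; the generator never emits such cases.
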