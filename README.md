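# lncsynt

Multidimensional human–mouse lncRNA conservation analysis with a fully
ground-truthed synthetic data generator.

Long noncoding RNAs evolve fast at the sequence level, so no single signal
identifies their conserved subset reliably. `lncsynt` implements a
five-dimensional classification of human–mouse lncRNA pairs and the
downstream characterizations that distinguish conserved from non-conserved
lncRNAs, for computational biologists who want a tested, reusable version of
this pipeline that runs on standard file formats (GTF/GFF3, UCSC chain,
bedGraph/wiggle, FASTA, BED/narrowPeak, JASPAR PFM, TSV count matrices).

## The method

A human lncRNA *h* and mouse lncRNA *m* form a conserved pair if they pass
any of five assessments; pairs passing **≥ 2** are *high-confidence*:

1. **Shared symbol** — same case-normalized gene symbol, restricted to a
   whitelist of previously established conserved lncRNAs.
2. **Global synteny** — the genomic span of each lncRNA, lifted through the
   whole-genome alignment chains in *both* directions, overlaps the partner
   (reciprocal ≥ 1 bp overlap).
3. **Local synteny** — the nearest flanking protein-coding genes within
   500 kb are orthologous between species; single lncRNAs per interval pair
   directly, multiple candidates pair by reciprocal best alignment.
4. **Sequence** — reciprocal best local alignment (identity ≥ 80%, E ≤ 1e-5
   on the mouse-to-human leg) *and* a sliding-window phastCons score
   (200 bp window, 50 bp step) exceeding 0.58 in at least one window.
5. **Promoter** — reciprocal best plus-strand alignment of the 500 bp
   promoters (identity ≥ 80%, E ≤ 1e-10).

Downstream modules compare conserved vs non-conserved groups: gene
structure and transposable-element content (with 1,000× balanced resampling
at n = 500), disease linkage through exonic GWAS SNPs and eQTLs,
expression breadth (detectable at > 0.5 CPM), tissue specificity (maximum
fractional expression), and lncRNA–neighbor Spearman correlation within
50 kb against a distance-matched random-pair null.

Promoter TF-motif preference uses, per motif, the contingency counts
*A*/*B* (conserved promoters with the motif / total) and *C*/*D*
(non-conserved), with *AB = A/B*, *CD = C/D*, and *R* the median of the
pooled {*AB*, *CD*}:

```
PR = |(AB + R) / (CD + R)|      PM = |AB − CD|
DR = |(M + R') / (N + R')|      DM = |M − N|
```

where *M*, *N* are mean occurrences per promoter and *R'* the pooled median
density. A motif is preferentially enriched when PR or PM (resp. DR or DM)
exceeds its 90th percentile across motifs, the conserved side is larger,
and the BH-adjusted two-proportions z-test (resp. Mann–Whitney U) gives
q < 0.05. Motifs passing both screens are conserved-lncRNA-binding TFs
(CLB_TFs); these are validated against overexpression/knockout RNA-seq by
abundance-adjusted log₂ fold-change shifts between conserved and
non-conserved lncRNAs.

Because every real-data input depends on external database releases, the
`synthetic_data` module generates a complete paired-genome fixture — two
2 Mb × 2-chromosome genomes with orthologous coding genes, one planted
lncRNA class per conservation dimension, consistent chain files,
conservation tracks, repeats, motifs, ChIP peaks, disease catalogs, and
negative-binomial count matrices — all a pure function of the seed.

## Worked example

```python
from lncsynt import synthetic_data as sd, conservation as cons

cfg = sd.SimulationConfig(seed=1)
fix = sd.generate_genome_pair(cfg)
lnc_h, lnc_m = fix.lnc("human"), fix.lnc("mouse")
seqs_h, seqs_m = fix.lnc_sequences("human"), fix.lnc_sequences("mouse")

method_pairs = {
    "symbol": cons.classify_by_symbol(lnc_h, lnc_m, fix.truth.symbol_whitelist),
    "global": cons.classify_global(lnc_h, lnc_m, fix.chains_h2m, fix.chains_m2h),
    "local": cons.classify_local(lnc_h, lnc_m, fix.coding("human"),
                                 fix.coding("mouse"), fix.orthologs,
                                 seqs_h, seqs_m),
    "sequence": cons.classify_sequence(lnc_h, lnc_m, seqs_h, seqs_m,
                                       fix.track_h, fix.track_m),
    "promoter": cons.classify_promoter(lnc_h, lnc_m, fix.genome_h, fix.genome_m),
}
calls, tiers = cons.merge_calls(method_pairs, lnc_h, lnc_m)
print({m: len(p) for m, p in method_pairs.items()})
print(cons.calls_to_table(calls).head(5).to_string(index=False))
```

prints

```
{'symbol': 10, 'global': 10, 'local': 10, 'sequence': 10, 'promoter': 10}
human_id mouse_id  symbol  global  local  sequence  promoter  n_methods      tier
 HLNC000  MLNC000       0       0      0         1         0          1 conserved
 HLNC001  MLNC001       1       0      0         0         0          1 conserved
 HLNC002  MLNC002       1       0      0         0         0          1 conserved
 HLNC004  MLNC004       0       1      0         0         0          1 conserved
 HLNC005  MLNC005       1       0      0         0         0          1 conserved
```

Each of the five methods recovers exactly its ten planted pairs (50
conserved pairs, 100 of 120 lncRNAs conserved): on the noiseless default
fixture every classifier attains precision = recall = 1.0 against the
planted ground truth. Because the planted classes are mutually exclusive by
construction, no pair collects two flags and the high-confidence tier is
empty here; `merge_calls` promotes any pair with ≥ 2 flags.

The same pipeline runs from the shell on files:

```bash
lncsynt simulate --out fixture/
lncsynt conserve --annot-h fixture/human.gtf --annot-m fixture/mouse.gtf \
    --chains-h2m fixture/human_to_mouse.chain --chains-m2h fixture/mouse_to_human.chain \
    --track-h fixture/human.phastcons.bedgraph --track-m fixture/mouse.phastcons.bedgraph \
    --genome-h fixture/human.fa --genome-m fixture/mouse.fa \
    --orthologs fixture/orthologs.tsv --out calls.tsv
```

Subcommands `features`, `express`, `tfenrich` and `perturb` cover the
remaining stages.

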