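# earlinc

Discovery, classification and prioritization of long non-coding RNAs
(lncRNAs) in inner-ear transcriptomes.

lncRNAs — transcripts > 200 nt with no recognizable protein-coding
capacity — are sparsely annotated in the auditory and vestibular sensory
epithelia, yet many sit next to genes whose disruption causes deafness and
are plausible *cis*-regulators of them. `earlinc` is a library for the
bioinformatic half of such a study: it takes an assembled transcriptome
(GTF), a reference annotation, count matrices and cross-species evidence,
and carries them through transcript filtering, positional classification,
novelty calling, expression profiling, differential-expression and
correlation screens, sequence+synteny orthology and deafness-gene
candidate prioritization. A synthetic-study generator with planted ground
truth ships as first-class, tested code, so every stage can be validated
end to end without any external data.

It is aimed at computational biologists who want a small, fully testable
model of this analysis — for method development, teaching, or as scaffolding
to swap real data into.

## The analysis in brief

- **Filtering cascade** (per transcript, fixed decision order): mature
  length ≤ 200 nt → excluded; max FPKM below an expression floor →
  excluded; coding potential (longest ORF ≥ 100 codons, protein homology,
  or an external codon-substitution score above cutoff) → excluded;
  opposite-strand exonic overlap with a coding gene → *antisense*;
  contained in a coding gene's intron on the same strand → excluded;
  hosting a small RNA → *small-RNA host*; otherwise *lincRNA* (intergenic).
- **Novelty**: a lncRNA gene is novel iff it has zero exonic overlap with
  every gene in a reference lncRNA annotation.
- **Expression**: FPKM_gs = c_gs · 10⁹ / (N_s · L_g); tissue specificity =
  #{panel samples with FPKM ≥ 1}; DE screen = median-of-ratios
  normalization + moderated t on log₂(normalized+1) + Benjamini–Hochberg,
  calling |log₂FC| ≥ 1 at adjusted P < 0.05; qRT-PCR quantification by
  2^−ΔΔCt; sample structure by Euclidean average-linkage clustering and PCA
  on log₂(FPKM+1).
- **Orthology**: candidates from BLAST-tabular sequence hits (identity and
  E-value thresholds, best bit score per pair) and from synteny — a human
  lncRNA lying between the human orthologs of the two coding genes flanking
  the mouse lncRNA, with conserved anchor adjacency and orientation; merged
  candidates are resolved to a 1:1 matching by a deterministic greedy rank
  and clustered into k = 3 expression groups (group 1 = high in human).
- **Prioritization**: all lncRNA × disease-gene pairs within 4 Mb, labeled
  (within / contains / antisense / overlapping-divergent / host / proximal)
  and screened for expression correlation across the 12 samples (positive:
  R > 0.3, P < 0.05; negative: R < −0.3, P < 0.05); human deafness loci map
  to mouse coordinates by interpolation inside ortholog anchor blocks.

## Worked example

`examples/` holds one short script per capability. The first one generates
a synthetic transcriptome and classifies it:

```bash
$ python examples/01_classify_transcripts.py
64 candidate transcripts classified:
  antisense                        12
  excluded_coding                  6
  excluded_intronic_same_strand    5
  excluded_short                   5
  lincRNA                          30
  small_rna_host                   6

mismatches against the planted ground truth: 0
```

Every planted class is recovered exactly: the generator lays genes out with
≥ 1 kb margins so the labels are geometrically unambiguous. The expression
example prints the calibrated order-of-magnitude gap between coding genes
and lncRNAs and a DE screen that finds the planted effects:

```bash
$ python examples/02_expression_screens.py
median FPKM: coding 5.8 vs lincRNA 0.58 (lncRNAs sit an order of magnitude lower)
DE screen (adjusted P < 0.05, fold change >= 2): 20 genes called; 19/20 planted effects recovered
specificity panel (66 samples): 46% of lncRNA genes below 1 FPKM everywhere
2^-ddCt relative expression (calibrator cochlea_P0 = 1):
cochlea_P0      1.00
cochlea_P8      2.00
vestibule_P0    5.28
```

`examples/03_orthology.py` recovers all 15 planted mouse–human pairs and
shows that shuffling the human anchor order abolishes every synteny call;
`examples/04_prioritize_candidates.py` finds the 8 planted cis-regulated
lncRNA–deafness-gene pairs among 528 proximity candidates and maps a human
deafness locus into mouse coordinates; `examples/05_full_pipeline.py` runs
everything from one config and prints the summary JSON with a
per-file manifest.

A thin CLI wraps the same calls:

```bash
earlinc simulate --seed 0 --out study/        # write a synthetic input bundle
earlinc run --config cfg.yaml                 # full pipeline from YAML
earlinc annot validate study/mouse_candidates.gtf
```

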