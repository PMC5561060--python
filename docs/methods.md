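# Methods

This note records what each stage of `earlinc` computes, the assumptions
behind it, the parameters that matter, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was open.

## Coordinates and interval primitives

All internal coordinates are 0-based half-open. GTF I/O converts the
format's 1-based inclusive convention on input and output; BED is consumed
natively. This removes the usual off-by-one ambiguity: a printed position
like `chr2:9,883,041-9,889,540` becomes `[9883040, 9889540)` internally.

Exonic overlap between two transcripts is the summed intersection of their
exon sets, gated by a strand mode (`same`, `opposite`, `ignore`). A strand
of `.` is accepted on input but treated as incomparable in strand-aware
tests (overlap 0, with a logged warning). Gene distance is the gap between
spans (0 for any overlap, `None` across chromosomes); under half-open
coordinates the gap between disjoint intervals is `right.start − left.end`,
which is what makes a printed "249 bp" distance exact.

Gene grouping is the transitive closure of an overlap relation, computed by
union-find over a sweep. The default relation is same-strand exonic overlap,
which keeps antisense pairs as separate genes — the distinction the
lincRNA/antisense taxonomy depends on. An `any_overlap` mode (span overlap,
strand-blind) exists for conservative novelty-style comparisons. Gene ids
are assigned deterministically in (chrom, start, first transcript id)
order, so equal inputs produce byte-identical outputs.

## The filtering cascade

Transcripts pass a coding-potential filter and then a positional
classifier with a fixed decision order (each transcript receives exactly
one category; counts are conserved):

1. mature length ≤ `min_length_nt` (default 200 nt) → `excluded_short`;
2. max FPKM across the study samples < `min_expression_fpkm` (default
   0.1) → `excluded_low_expression` (skipped when no expression is given);
3. exonic overlap with a coding gene on the opposite strand → `antisense`;
4. contained in a coding gene's span on the same strand with no exonic
   overlap (intron-contained) → `excluded_intronic_same_strand`;
5. a small RNA contained in the transcript's span → `small_rna_host`;
6. otherwise → `lincRNA`.

Coding potential is consumed as a precomputed per-transcript table
(longest ORF in codons, an optional external coding score such as a
codon-substitution or protein-homology score, and a homology-hit flag);
the drop rule is ORF ≥ `orf_max_aa` (default 100 codons) OR homology OR
score ≥ `score_cutoff` (default 50, score-scale dependent and
config-exposed). These thresholds are declared defaults, not values taken
from any single published pipeline. A transcript with no assessment is
routed to a `needs_assessment` report and conservatively excluded — never
silently kept. `find_orfs` itself scans the three sense frames for
ATG-to-stop ORFs (stop required, not counted).

Same-strand exonic overlap with a coding gene is the coding filter's
business (such transcripts are coding-gene fragments), so the positional
classifier assumes its input already passed that filter.

Gene-level categories use the precedence host > antisense > lincRNA; a
gene whose transcripts are all excluded is excluded. Novelty is zero
exonic overlap against the reference lncRNA annotation, strand-blind by
default (the conservative reading; a strand-aware mode exists).

## Expression

`compute_fpkm` is the textbook fragments-per-kilobase-per-million:
`c·10⁹ / (N·L)` with N the per-sample column sum. Tissue specificity
counts panel samples at FPKM ≥ 1.0, threshold inclusive (where wording
varies between ≥ and >, the inclusive reading was fixed once and recorded).

The DE screen is a documented stand-in for a negative-binomial GLM, not a
reimplementation of one: median-of-ratios size factors, log₂(normalized+1)
with pseudocount 1, a moderated t-test, BH adjustment, and a significance
call of adjusted P < α (0.05) AND |log₂FC| ≥ log₂(min_fold) (fold 2). The
moderated t shrinks per-gene pooled variances toward the cohort median with
`prior_df = 8` pseudo-observations and refers the statistic to t with
prior_df + residual df. The shrinkage is the load-bearing choice: at 3
replicates per group a pure per-gene Welch t has ~4 df, its p-values cannot
get small enough to survive BH at 10% planted effects, and measured
sensitivity collapses to a few percent; sharing variance across genes is
exactly what the field's NB tools do via dispersion shrinkage. prior_df was
set by null calibration (the pooled p < 0.05 rate under the global null
sits within three binomial standard errors of 0.05 at prior_df 8; smaller
priors are conservative, larger ones anticonservative). A plain Welch t
(`method="welch"`) and arbitrary callables remain available. Fold changes
are raw normalized-mean ratios with the pseudocount — no shrinkage.
All-zero genes are reported with p = NA, untested, never dropped.

Correlation is Pearson with a two-sided t-test p-value, computed on the
expression vectors as given (the screens run on FPKM; Spearman was
considered and not chosen — the thresholds ±0.3 are stated for R). A
constant vector raises a typed error and is reported as a flag, never as
R = 0.

Sample structure: pairwise Euclidean distances and average-linkage
clustering on log₂(FPKM+1), PCA on samples (genes as features, centering
only, no scaling) with variance fractions from the squared singular
values. 2^−ΔΔCt follows the standard form: ΔCt = Ct_target − Ct_reference,
ΔΔCt relative to a calibrator sample whose value is exactly 1.

## Orthology

Sequence evidence: BLAST tabular (outfmt 6) rows filtered at
`min_identity = 60`, `max_evalue = 1e-5` (declared defaults,
config-exposed), deduplicated to the best bit score per (query, subject).

Synteny evidence uses anchor blocks — interval pairs tied by 1:1
orthologous coding genes. For a mouse lncRNA, the nearest anchored coding
genes upstream and downstream are found; a human lncRNA is a candidate iff
it lies in the gap between the human orthologs of those two anchors, the
two orthologs are on one chromosome, **adjacent** (no third anchor maps
between them), and ordered consistently with their shared orientation
(reflected order for inverted blocks). The adjacency requirement is this
package's operationalization of conserved gene order; without it, a
permuted ("synteny-broken") genome could still leave stray lncRNAs between
two now-distant anchors and the broken-synteny control would not be clean.
`synteny_score = 1/(1 + other human lncRNAs in the gap)`.

Resolution to 1:1 merges per-pair evidence (union, best score per route)
and greedily selects by a total deterministic rank: evidence
{sequence,synteny} > {sequence} > {synteny}, then similarity score, then
synteny score, then lexicographic ids. Greedy on a total order yields the
rank-lexicographically minimal maximal matching; an exhaustive enumeration
oracle verifies this on all random instances up to 8 genes per side. An
optimal-assignment solver was deliberately not used: at screen scale the
greedy rule is transparent, reproducible and provably maximal.

Resolved pairs are clustered into k = 3 groups on the concatenated
log₂(FPKM+1) mouse and human profiles, each feature standardized across
pairs, with average-linkage Euclidean clustering. Standardizing per
feature (rather than z-scoring each gene's profile) retains expression
*level*, which is what separates the groups of interest — high in both
species, high in mouse only, low in both; per-profile z-scoring would make
the first and last of those literally identical. Cluster labels are
reordered by descending mean human expression so group 1 is "high in
human". Pairs missing expression are reported separately, never dropped.

## Prioritization

Relationship labels use a fixed precedence: a small-RNA disease feature
inside the lncRNA span → `host_in_intron`; span containment → `within` /
`contains` (both directions are labeled, since "within" alone is ambiguous);
opposite-strand exonic overlap → `antisense`; opposite strands with 5′ ends
within `divergent_window_bp` (default 1 kb — head-to-head promoters, a
declared operationalization) → `overlapping_divergent`; otherwise
`proximal` with the span-to-span distance. The proximity search keeps all
pairs within `max_distance = 4 Mb` and is monotone in that radius. The
correlation screen fills Pearson R and p per record and calls positive
(R > 0.3, P < 0.05), negative (R < −0.3, P < 0.05) or none; records with a
gene absent from the matrix are flagged `no_expression`.

Locus liftover maps each endpoint by linear interpolation inside its
containing anchor block (reversed for inverted blocks), snapping endpoints
outside all blocks to the nearest block with a warning, and flags loci
whose endpoints land on different chromosomes as split. This replaces
chain-file liftover with a deterministic, dependency-free equivalent that
is exact where it matters here: with equal-length block sides the
round trip is invertible to ≤ 1 bp. For unequal sides the rounding error
grows with the length ratio — a known limitation; the generator emits
equal-length blocks.

## The synthetic generator

The generator emulates the *structure* of a two-tissue (cochlea,
vestibule) × two-stage (E16.5, P0) × three-replicate inner-ear study on a
toy genome pair, with planted truth serialized beside every file:

- **Geometry.** One mouse chromosome, genes laid out sequentially with
  ≥ 1 kb margins (default 2 kb) so planted class labels are unambiguous:
  48 coding genes (4–5 exons) doubling as synteny anchors, 30 lincRNAs and
  12 antisense transcripts (2–3 exons), 6 small-RNA hosts (4–5 exons, a
  small RNA planted in the first intron), plus planted exclusion classes
  (5 short, 5 intron-contained, 6 coding-like removed by the coding
  filter). Exon-count ranges follow the observed architecture: lincRNA and
  antisense transcripts typically 2–3 exons, coding genes and hosts 4–5.
  A configurable fraction (0.4) of surviving lncRNA genes also appears in
  the known-lncRNA reference (jittered copies), defining novelty truth.
  Adversarial geometry (touching/nested features) is exercised separately
  in oracle-equivalence tests, not in the planted-truth default.
- **Human mirror.** Anchors are mirrored with equal-length intervals in
  the same order; orthologous human lncRNAs are placed in the gap matching
  their mouse partner (synteny evidence), on a different chromosome
  (sequence-only evidence), or both; decoy human lncRNAs occupy gaps whose
  mouse occupant is an excluded class. `shuffle_anchor_order` permutes the
  human anchor positions under the constraint that no originally-adjacent
  pair stays adjacent, giving an exactly-zero synteny control.
- **Counts.** Negative binomial (dispersion 0.1) over log-normal per-gene
  levels with medians calibrated to 5.9 (coding) vs 0.3 (lncRNA) FPKM and
  σ = 0.8; lncRNA levels are floored at 0.1 so planted survivors stay above
  the discovery expression floor. A single Poisson background row
  (`BG0001`, 2×10⁷ expected counts) carries the library mass of the rest
  of the transcriptome, putting computed FPKM on the level scale — without
  it a 112-gene library would inflate FPKM by ~10³. Library sizes vary
  ±30%. 20 planted DE genes (half coding, half lncRNA) get a 2² multiplier
  in the cochlea; 8 planted cis pairs (a lincRNA, raised to coding-level
  expression, and its right-flanking coding gene) share a per-sample
  log-normal factor with σ = 1.05, sized so the implied Pearson
  correlation is ≈ 0.9 given the NB noise floor.
- **Panel.** 66 samples; 46% of lncRNA genes are silent everywhere
  (< 1 FPKM), 10% ubiquitous (≥ 1 everywhere), the rest expressed in a
  random handful of samples.
- **Hits and assessments.** Planted sequence-evidence pairs get outfmt-6
  rows passing the default thresholds; decoys fail by E-value or identity.
  Coding-like candidates carry long ORFs, high external scores or homology
  flags; true lncRNAs stay below every cutoff. ORF test sequences are
  generated stop-rich in all three frames for noncoding, or with one
  planted ATG-to-stop ORF of known length.
- **Disease annotation.** The cis-pair coding partners (plus a few extras)
  form the deafness-gene list with alternating MGI-style terms
  (MP:0006325, MP:0001967); two human loci span several anchor blocks, and
  the truth records which planted lncRNA genes their mapped mouse
  intervals contain.

What the generator does **not** emulate: read-level noise and mapping
artifacts, isoform complexity within genes, dispersion–mean trends,
batch effects, sequence evolution, or annotation errors. Passing the
planted-truth suite therefore demonstrates the correctness of the
implemented rules and the calibration of the screens under the stated
noise model — not robustness to the full messiness of real RNA-seq.

Everything is deterministic given the seed (integer-driven geometry, one
documented NumPy generator per product, derived seeds seed+1…seed+5 for
counts, panel, hits, assessments and disease annotation).

## Problem sizes and runtime

The validation suite uses desk-scale sizes chosen as this package's own
benchmark conditions: 2,000 random transcripts for oracle equivalence,
50 DE replicates of 200 genes (20 planted) plus 100 null replicates,
100 correlation replicates at n = 12, 50 planted orthologs, 1,000 liftover
round trips, and a 12-sample 4-condition structure recovery. The full
pytest suite runs in well under a minute and `scripts/acceptance.py` in a
few seconds on one CPU.

## Known limitations

- The DE stand-in assumes roughly mean-independent log-scale variance;
  with strong dispersion–mean trends the single shrinkage target is
  misspecified (a trended prior would be the next step).
- Liftover accuracy degrades with unequal anchor-side lengths (see above).
- Synteny requires flanking anchors on both sides; lncRNAs at chromosome
  ends or inside anchor intervals report no candidates rather than
  guessing.
- The correlation screen tests marginal association only; shared library
  or condition structure (e.g., two genes both responding to tissue) will
  produce biologically real but non-causal positive calls, as in any
  cis-correlation screen.
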