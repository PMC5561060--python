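"""lncRNA filtering and classification.

Implements the standard discovery cascade for assembled transcripts:
a length floor (>200 nt mature length), an expression floor, coding-potential
filtering (ORF length, protein homology, external codon-substitution score),
the positional taxonomy (lincRNA / antisense / small-RNA host), the
same-strand-intron exclusion, gene-level category calls, and novelty calling
against a reference lncRNA annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    exonic_overlap,
    gene_exonic_overlap,
)

logger = logging.getLogger(__name__)

CATEGORIES = (
    "lincRNA",
    "antisense",
    "small_rna_host",
    "excluded_coding",
    "excluded_short",
    "excluded_low_expression",
    "excluded_intronic_same_strand",
)

EXCLUDED = tuple(c for c in CATEGORIES if c.startswith("excluded"))

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class LncRNAClassification:
    transcript_id: str
    category: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def excluded(self) -> bool:
        return self.category in EXCLUDED


@dataclass(frozen=True)
class CodingAssessment:
    """Per-transcript coding-potential evidence, consumed precomputed.

    ``longest_orf_aa`` is None when no sequence was available (unknown, not
    zero). ``external_coding_score`` holds e.g. a codon-substitution or
    protein-homology score from an external scan.
    """

    transcript_id: str
    longest_orf_aa: int | None
    external_coding_score: float | None = None
    homology_hit: bool = False

    def __post_init__(self) -> None:
        if self.longest_orf_aa is not None and self.longest_orf_aa < 0:
            raise ValueError("longest_orf_aa must be >= 0")


@dataclass(frozen=True)
class CodingFilterConfig:
    orf_max_aa: int = 100
    score_cutoff: float = 50.0


def find_orfs(sequence: str) -> int:
    """Longest ATG-to-stop ORF, in codons, scanning all 3 sense frames.

    The stop codon is not counted. Returns 0 when no complete ORF exists.
    Codons containing N are neither start nor stop.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def coding_filter(
    t: TranscriptModel,
    assess: CodingAssessment | None,
    config: CodingFilterConfig = CodingFilterConfig(),
) -> tuple[str, str]:
    """Apply the coding-potential filter to one transcript.

    Returns ``(decision, reason)`` where decision is ``keep``, ``drop`` or
    ``needs_assessment``. A transcript with no assessment is never silently
    kept; it is routed to the needs_assessment report.
    """
    if assess is None or assess.longest_orf_aa is None:
        return "needs_assessment", "no coding assessment available"
    reasons = []
    if assess.longest_orf_aa >= config.orf_max_aa:
        reasons.append(f"ORF {assess.longest_orf_aa} aa >= {config.orf_max_aa}")
    if assess.homology_hit:
        reasons.append("protein homology hit")
    if (
        assess.external_coding_score is not None
        and assess.external_coding_score >= config.score_cutoff
    ):
        reasons.append(
            f"coding score {assess.external_coding_score:g} >= {config.score_cutoff:g}"
        )
    if reasons:
        return "drop", "; ".join(reasons)
    return "keep", "passed coding filter"


def classify_lncrna(
    t: TranscriptModel,
    coding: Sequence[GeneModel],
    small_rnas: Sequence[GenomicInterval] = (),
    min_length_nt: int = 200,
    min_expression_fpkm: float = 0.1,
    max_fpkm: float | None = None,
) -> LncRNAClassification:
    """Classify one candidate transcript against the coding annotation.

    The decision order is fixed:

    1. mature length <= ``min_length_nt`` -> excluded_short
    2. max FPKM across samples < ``min_expression_fpkm`` -> excluded_low_expression
       (skipped when ``max_fpkm`` is None, i.e. no expression supplied)
    3. exonic overlap with a coding gene on the opposite strand -> antisense
    4. contained in a coding gene's span on the same strand with no exonic
       overlap (intron-contained) -> excluded_intronic_same_strand
    5. a small RNA inside the transcript's span -> small_rna_host
    6. otherwise -> lincRNA

    The transcript is assumed to have already passed the coding filter.
    """
    if t.mature_length <= min_length_nt:
        return LncRNAClassification(
            t.transcript_id, "excluded_short", f"mature length {t.mature_length} nt"
        )
    if max_fpkm is not None and max_fpkm < min_expression_fpkm:
        return LncRNAClassification(
            t.transcript_id,
            "excluded_low_expression",
            f"max FPKM {max_fpkm:g} < {min_expression_fpkm:g}",
        )
    span = t.span
    for g in coding:
        if g.chrom != span.chrom or not g.span.overlaps(span):
            continue
        for ct in g.transcripts:
            if exonic_overlap(t, ct, "opposite") > 0:
                return LncRNAClassification(
                    t.transcript_id, "antisense", f"antisense to {g.gene_id}"
                )
    for g in coding:
        if g.chrom != span.chrom or t.strand == "." or g.strand != t.strand:
            continue
        if g.span.contains(span) and gene_exonic_overlap_with(t, g) == 0:
            return LncRNAClassification(
                t.transcript_id,
                "excluded_intronic_same_strand",
                f"inside intron of {g.gene_id}",
            )
    for srna in small_rnas:
        if span.contains(srna):
            return LncRNAClassification(
                t.transcript_id,
                "small_rna_host",
                f"hosts small RNA at {srna.chrom}:{srna.start}-{srna.end}",
            )
    return LncRNAClassification(t.transcript_id, "lincRNA", "intergenic")


def gene_exonic_overlap_with(t: TranscriptModel, g: GeneModel) -> int:
    """Max same-strand exonic overlap of a transcript with any transcript of g."""
    return max(exonic_overlap(t, ct, "same") for ct in g.transcripts)


GENE_PRECEDENCE = ("small_rna_host", "antisense", "lincRNA")


def classify_gene(
    g: GeneModel, transcript_calls: Mapping[str, LncRNAClassification]
) -> str:
    """Gene-level category under the precedence host > antisense > lincRNA.

    A gene whose transcripts are all excluded is ``excluded``.
    """
    cats = set()
    for t in g.transcripts:
        call = transcript_calls.get(t.transcript_id)
        if call is None:
            raise KeyError(f"{g.gene_id}: transcript {t.transcript_id} not classified")
        cats.add(call.category)
    for cat in GENE_PRECEDENCE:
        if cat in cats:
            return cat
    return "excluded"


@dataclass
class NoveltyResult:
    flags: dict[str, bool]
    n_novel: int
    n_known: int
    unmatched_chroms: tuple[str, ...] = ()


def call_novelty(
    lnc_genes: Sequence[GeneModel],
    reference: Sequence[GeneModel],
    strand_mode: str = "ignore",
) -> NoveltyResult:
    """Flag genes with zero exonic overlap against a reference lncRNA set.

    Default comparison is any-strand exonic overlap (conservative novelty);
    ``strand_mode="same"`` restricts to same-strand overlap. Chromosomes
    present in the query but absent from the reference are reported.
    """
    ref_chroms = {g.chrom for g in reference}
    query_chroms = {g.chrom for g in lnc_genes}
    unmatched = tuple(sorted(query_chroms - ref_chroms))
    if unmatched:
        logger.warning("chromosomes absent from reference: %s", ", ".join(unmatched))
    flags: dict[str, bool] = {}
    for g in lnc_genes:
        novel = True
        for r in reference:
            if gene_exonic_overlap(g, r, strand_mode) > 0:
                novel = False
                break
        flags[g.gene_id] = novel
    n_novel = sum(flags.values())
    return NoveltyResult(
        flags=flags,
        n_novel=n_novel,
        n_known=len(flags) - n_novel,
        unmatched_chroms=unmatched,
    )


# ---------------------------------------------------------------------------
# Assessment table I/O and the full cascade

def read_assessments(path: str | Path) -> dict[str, CodingAssessment]:
    """Read the coding-assessment TSV (transcript_id, longest_orf_aa,
    external_coding_score, homology_hit)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        orf = None if pd.isna(row.longest_orf_aa) else int(row.longest_orf_aa)
        score = None if pd.isna(row.external_coding_score) else float(row.external_coding_score)
        out[row.transcript_id] = CodingAssessment(
            transcript_id=row.transcript_id,
            longest_orf_aa=orf,
            external_coding_score=score,
            homology_hit=bool(row.homology_hit),
        )
    return out


@dataclass
class ClassificationReport:
    calls: dict[str, LncRNAClassification]
    needs_assessment: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": c.transcript_id, "category": c.category, "evidence": c.evidence}
            for c in self.calls.values()
        ]
        return pd.DataFrame(rows).sort_values("transcript_id").reset_index(drop=True)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.calls.values():
            out[c.category] = out.get(c.category, 0) + 1
        return out


def classify_transcripts(
    candidates: Sequence[TranscriptModel],
    coding: Sequence[GeneModel],
    small_rnas: Sequence[GenomicInterval] = (),
    assessments: Mapping[str, CodingAssessment] | None = None,
    max_fpkm: Mapping[str, float] | None = None,
    min_length_nt: int = 200,
    min_expression_fpkm: float = 0.1,
    coding_config: CodingFilterConfig = CodingFilterConfig(),
) -> ClassificationReport:
    """Run the full cascade over a candidate set.

    Every input transcript receives exactly one category (conservation);
    transcripts lacking a coding assessment when assessments are supplied go
    to the needs_assessment report and are excluded_coding-safe (not kept).
    """
    report = ClassificationReport(calls={})
    for t in candidates:
        if assessments is not None:
            decision, reason = coding_filter(t, assessments.get(t.transcript_id), coding_config)
            if decision == "needs_assessment":
                report.needs_assessment.append(t.transcript_id)
                report.calls[t.transcript_id] = LncRNAClassification(
                    t.transcript_id, "excluded_coding", "needs_assessment: " + reason
                )
                continue
            if decision == "drop":
                report.calls[t.transcript_id] = LncRNAClassification(
                    t.transcript_id, "excluded_coding", reason
                )
                continue
        fp = None if max_fpkm is None else max_fpkm.get(t.transcript_id, 0.0)
        report.calls[t.transcript_id] = classify_lncrna(
            t,
            coding,
            small_rnas,
            min_length_nt=min_length_nt,
            min_expression_fpkm=min_expression_fpkm,
            max_fpkm=fp,
        )
    return report
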