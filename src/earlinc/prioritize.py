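"""Candidate lncRNA prioritization against deafness genes and loci.

Labels the positional relationship of a lncRNA to a disease gene
(within / contains / antisense / overlapping divergent / small-RNA host /
proximal), searches for lncRNAs up to 4 Mb from a gene of interest, screens
candidate pairs for expression correlation across the inner-ear samples
(positive call R > 0.3, negative R < -0.3, both at P < 0.05), and maps human
deafness loci to mouse coordinates by interpolation inside anchor blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .annotation import (
    GeneModel,
    GenomicInterval,
    gene_distance,
    gene_exonic_overlap,
)
from .expression import ConstantInputError, ExpressionMatrix, correlate
from .orthology import AnchorBlock

logger = logging.getLogger(__name__)

RELATIONSHIPS = (
    "within",
    "contains",
    "antisense",
    "overlapping_divergent",
    "host_in_intron",
    "proximal",
)

POSITIVE_R = 0.3
NEGATIVE_R = -0.3
CORRELATION_ALPHA = 0.05


@dataclass(frozen=True)
class CandidateRecord:
    lncrna_gene: str
    disease_gene: str
    relationship: str
    distance_bp: int
    correlation_R: float | None = None
    correlation_p: float | None = None
    correlation_call: str = "none"

    def __post_init__(self) -> None:
        if self.relationship not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship {self.relationship!r}")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")
        if self.correlation_call not in ("positive", "negative", "none", "no_expression"):
            raise ValueError(f"bad correlation_call {self.correlation_call!r}")


@dataclass
class DiseaseLocus:
    """A mapped human deafness interval (e.g., a DFNA/DFNB locus)."""

    locus_id: str
    human_interval: GenomicInterval
    mouse_interval: GenomicInterval | None = None
    split: bool = False


def label_relationship(
    lnc: GeneModel, gene: GeneModel, divergent_window_bp: int = 1000
) -> str | None:
    """Positional relationship of a lncRNA to a disease gene; None when the
    two sit on different chromosomes.

    Precedence: (1) host_in_intron when the disease feature is a small RNA
    contained in the lncRNA's span; (2) within / contains by span
    containment; (3) antisense by opposite-strand exonic overlap;
    (4) overlapping_divergent for head-to-head opposite-strand genes with 5'
    ends within the window; (5) proximal otherwise.
    """
    if lnc.chrom != gene.chrom:
        return None
    gspan, lspan = gene.span, lnc.span
    is_small = all(t.biotype == "small_rna" for t in gene.transcripts)
    if is_small and lspan.contains(gspan):
        return "host_in_intron"
    if gspan.contains(lspan):
        return "within"
    if lspan.contains(gspan):
        return "contains"
    if gene_exonic_overlap(lnc, gene, "opposite") > 0:
        return "antisense"
    if (
        lnc.strand in "+-"
        and gene.strand in "+-"
        and lnc.strand != gene.strand
        and abs(lnc.five_prime - gene.five_prime) <= divergent_window_bp
    ):
        return "overlapping_divergent"
    return "proximal"


def candidates_near_genes(
    lncs: Sequence[GeneModel],
    disease_genes: Sequence[GeneModel],
    max_distance: int = 4_000_000,
    divergent_window_bp: int = 1000,
) -> list[CandidateRecord]:
    """All (lncRNA, disease gene) pairs within ``max_distance`` bp, labeled.

    Distance is between gene spans (0 for any overlap). Sorted by distance
    then ids.
    """
    if not disease_genes:
        logger.warning("empty disease-gene list: no candidates to report")
        return []
    records = []
    for lnc in lncs:
        for gene in disease_genes:
            d = gene_distance(lnc.span, gene.span)
            if d is None or d > max_distance:
                continue
            rel = label_relationship(lnc, gene, divergent_window_bp)
            records.append(
                CandidateRecord(
                    lncrna_gene=lnc.gene_id,
                    disease_gene=gene.gene_id,
                    relationship=rel,
                    distance_bp=d,
                )
            )
    records.sort(key=lambda r: (r.distance_bp, r.lncrna_gene, r.disease_gene))
    return records


def correlation_screen(
    records: Sequence[CandidateRecord],
    expr: ExpressionMatrix,
    positive_r: float = POSITIVE_R,
    negative_r: float = NEGATIVE_R,
    alpha: float = CORRELATION_ALPHA,
) -> list[CandidateRecord]:
    """Fill correlation fields for candidate records.

    Pearson R across the expression samples; positive call when R > 0.3 and
    p < 0.05, negative when R < -0.3 and p < 0.05. Pairs with either gene
    absent from the matrix are flagged ``no_expression``, not dropped; a
    constant expression vector yields call ``none`` with R unset.
    """
    out = []
    for rec in records:
        if (
            rec.lncrna_gene not in expr.values.index
            or rec.disease_gene not in expr.values.index
        ):
            out.append(replace(rec, correlation_call="no_expression"))
            continue
        x = expr.values.loc[rec.lncrna_gene].to_numpy(dtype=float)
        y = expr.values.loc[rec.disease_gene].to_numpy(dtype=float)
        try:
            r, p = correlate(x, y)
        except ConstantInputError:
            out.append(replace(rec, correlation_call="none"))
            continue
        if r > positive_r and p < alpha:
            call = "positive"
        elif r < negative_r and p < alpha:
            call = "negative"
        else:
            call = "none"
        out.append(replace(rec, correlation_R=r, correlation_p=p, correlation_call=call))
    return out


# ---------------------------------------------------------------------------
# Anchor-block interval liftover

def _map_point(p: int, src: GenomicInterval, dst: GenomicInterval, orientation: str) -> int:
    frac = (p - src.start) / (src.end - src.start)
    if orientation == "inverted":
        frac = 1.0 - frac
    return dst.start + int(round(frac * (dst.end - dst.start)))


def _containing_block(
    p: int, chrom: str, anchors: Sequence[AnchorBlock], genome: str
) -> tuple[AnchorBlock, bool]:
    """Block whose interval on ``genome`` contains p; nearest block otherwise
    (snapped=True)."""
    best = None
    best_dist = None
    for a in anchors:
        iv = a.human_interval if genome == "human" else a.mouse_interval
        if iv.chrom != chrom:
            continue
        if iv.start <= p < iv.end:
            return a, False
        d = min(abs(p - iv.start), abs(p - (iv.end - 1)))
        if best_dist is None or d < best_dist:
            best, best_dist = a, d
    if best is None:
        raise ValueError(f"no anchor block on chromosome {chrom!r}")
    return best, True


def map_interval(
    interval: GenomicInterval,
    anchors: Sequence[AnchorBlock],
    direction: str = "human_to_mouse",
) -> tuple[GenomicInterval, bool]:
    """Map an interval across genomes by interpolation within anchor blocks.

    Each endpoint is mapped linearly inside its containing block (reversed
    for inverted blocks); endpoints outside every block snap to the nearest
    block with a warning. Returns ``(mapped_interval, split)`` where split
    means the endpoints landed on different target chromosomes and the hull
    could not be formed (the mapped interval then covers only the start
    endpoint's block side).
    """
    if direction not in ("human_to_mouse", "mouse_to_human"):
        raise ValueError(f"bad direction {direction!r}")
    src_genome = "human" if direction == "human_to_mouse" else "mouse"

    def endpoints(a: AnchorBlock) -> tuple[GenomicInterval, GenomicInterval]:
        if direction == "human_to_mouse":
            return a.human_interval, a.mouse_interval
        return a.mouse_interval, a.human_interval

    mapped = []
    for p in (interval.start, interval.end - 1):
        block, snapped = _containing_block(p, interval.chrom, anchors, src_genome)
        if snapped:
            logger.warning(
                "endpoint %d outside all anchor blocks; snapped to nearest block", p
            )
            src, _ = endpoints(block)
            p = min(max(p, src.start), src.end - 1)
        src, dst = endpoints(block)
        mapped.append((dst.chrom, _map_point(p, src, dst, block.orientation)))
    (c1, p1), (c2, p2) = mapped
    if c1 != c2:
        logger.warning("interval endpoints map to different chromosomes (%s vs %s)", c1, c2)
        return GenomicInterval(c1, p1, p1 + 1, interval.strand), True
    lo, hi = min(p1, p2), max(p1, p2)
    return GenomicInterval(c1, lo, hi + 1, interval.strand), False


def map_locus_and_intersect(
    locus: DiseaseLocus,
    anchors: Sequence[AnchorBlock],
    lncs: Sequence[GeneModel],
) -> tuple[DiseaseLocus, list[GeneModel]]:
    """Map a human deafness locus to mouse coordinates and intersect with
    lncRNA gene spans."""
    mouse_iv, split = map_interval(locus.human_interval, anchors, "human_to_mouse")
    mapped = replace_locus(locus, mouse_iv, split)
    overlapping = [g for g in lncs if g.span.overlaps(mouse_iv)]
    overlapping.sort(key=lambda g: (g.span.start, g.gene_id))
    return mapped, overlapping


def replace_locus(locus: DiseaseLocus, mouse_iv: GenomicInterval, split: bool) -> DiseaseLocus:
    return DiseaseLocus(
        locus_id=locus.locus_id,
        human_interval=locus.human_interval,
        mouse_interval=mouse_iv,
        split=split,
    )


def records_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_gene": r.lncrna_gene,
                "disease_gene": r.disease_gene,
                "relationship": r.relationship,
                "distance_bp": r.distance_bp,
                "correlation_R": r.correlation_R,
                "correlation_p": r.correlation_p,
                "correlation_call": r.correlation_call,
            }
            for r in records
        ]
    )
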