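"""Genomic interval and transcript data model with GTF/BED I/O.

Coordinates are 0-based half-open internally. GTF I/O converts the format's
1-based inclusive convention on the way in and out; BED is native 0-based
half-open. All overlap and distance primitives used by the classification,
orthology and prioritization modules live here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

logger = logging.getLogger(__name__)

Strand = Literal["+", "-", "."]
VALID_STRANDS = ("+", "-", ".")

BIOTYPES = ("protein_coding", "small_rna", "lncRNA_candidate", "known_lncRNA")


class GTFParseError(ValueError):
    """Raised for malformed GTF rows; message carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : chromosome name.
    start, end : 0-based half-open bounds, ``0 <= start < end``.
    strand : one of ``+``, ``-``, ``.`` (``.`` = unstranded; treated as
        incomparable by strand-aware overlap tests).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def _hull(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    first = intervals[0]
    return GenomicInterval(
        first.chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
        first.strand,
    )


@dataclass(frozen=True)
class TranscriptModel:
    """A multi-exon stranded transcript; the unit of classification.

    Exons are stored sorted by start, non-overlapping, all on one
    chromosome and strand. ``span`` is the exon hull; ``mature_length``
    is the summed exon length (the spliced transcript length).
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "lncRNA_candidate"

    def __post_init__(self) -> None:
        if not self.transcript_id or not self.gene_id:
            raise ValueError("transcript_id and gene_id must be non-empty")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs at least one exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons must share chrom and strand")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} / {b}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return _hull(self.exons)

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def five_prime(self) -> int:
        """5' end position (start for +, end for -; start for unstranded)."""
        return self.span.end if self.strand == "-" else self.span.start

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class GeneModel:
    """A group of overlapping transcripts sharing one locus."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs at least one transcript")
        if len({t.chrom for t in self.transcripts}) != 1:
            raise ValueError(f"{self.gene_id}: transcripts must share a chromosome")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        strands = {t.strand for t in self.transcripts}
        return strands.pop() if len(strands) == 1 else "."

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )

    @property
    def five_prime(self) -> int:
        return self.span.end if self.strand == "-" else self.span.start


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon rows from a GTF file into transcript models.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Rows other than ``exon`` features are ignored; malformed exon rows raise
    :class:`GTFParseError` naming the offending line.
    """
    path = Path(path)
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_of_tx: dict[str, str] = {}
    biotype_of_tx: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GTFParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GTFParseError(f"{path}:{lineno}: end {end1} < start {start1}")
            if strand not in VALID_STRANDS:
                raise GTFParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attributes = _parse_attributes(attrs)
            if "transcript_id" not in attributes or "gene_id" not in attributes:
                raise GTFParseError(
                    f"{path}:{lineno}: exon row lacks transcript_id/gene_id attributes"
                )
            tid = attributes["transcript_id"]
            exons_by_tx.setdefault(tid, []).append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )
            gene_of_tx[tid] = attributes["gene_id"]
            if "gene_biotype" in attributes:
                biotype_of_tx[tid] = attributes["gene_biotype"]
    transcripts = []
    for tid, exons in exons_by_tx.items():
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of_tx[tid],
                exons=tuple(exons),
                biotype=biotype_of_tx.get(tid, "lncRNA_candidate"),
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon rows (1-based inclusive coordinates).

    Output order is deterministic (chrom, start, transcript_id) so equal
    transcript sets serialize byte-identically.
    """
    path = Path(path)
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    with path.open("w") as fh:
        for t in ordered:
            for e in t.exons:
                attrs = (
                    f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_id}"; '
                    f'gene_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\tearlinc\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>=3 columns; strand from column 6 when present)."""
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED row needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    if names is None:
        names = [f"iv{i}" for i in range(len(intervals))]
    with Path(path).open("w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Overlap / distance primitives

def _strand_compatible(a: str, b: str, strand_mode: str) -> bool:
    if strand_mode == "ignore":
        return True
    if a == "." or b == ".":
        logger.warning("unstranded feature in strand-aware overlap test; treating as 0")
        return False
    if strand_mode == "same":
        return a == b
    if strand_mode == "opposite":
        return a != b
    raise ValueError(f"strand_mode must be same/opposite/ignore, got {strand_mode!r}")


def exonic_overlap(a: TranscriptModel, b: TranscriptModel,
                   strand_mode: str = "same") -> int:
    """Total exonic overlap in bp between two transcripts.

    Returns the sum over exon pairs of intersection lengths; 0 when the
    chromosomes differ or the strand relation is not satisfied. Symmetric.
    """
    if a.chrom != b.chrom:
        return 0
    if not _strand_compatible(a.strand, b.strand, strand_mode):
        return 0
    total = 0
    for ea in a.exons:
        if ea.start >= b.span.end:
            break
        for eb in b.exons:
            if eb.start >= ea.end:
                break
            total += ea.overlap_len(eb)
    return total


def gene_exonic_overlap(a: GeneModel, b: GeneModel, strand_mode: str = "ignore") -> int:
    """Maximum transcript-pair exonic overlap between two genes."""
    if a.chrom != b.chrom or not a.span.overlaps(b.span):
        return 0
    return max(
        exonic_overlap(ta, tb, strand_mode)
        for ta in a.transcripts
        for tb in b.transcripts
    )


def gene_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if they overlap.

    Returns ``None`` ("unlinked") when the intervals sit on different
    chromosomes. Under half-open coordinates the gap between disjoint
    intervals is ``right.start - left.end``.
    """
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


# ---------------------------------------------------------------------------
# Gene grouping

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_transcripts_into_genes(
    transcripts: Sequence[TranscriptModel],
    mode: str = "same_strand_exonic",
    gene_id_prefix: str = "G",
) -> list[GeneModel]:
    """Group transcripts into genes by the transitive closure of overlap.

    ``mode="same_strand_exonic"`` merges transcripts whose exons overlap on
    the same strand (the default: keeps antisense pairs separate, matching
    the lincRNA/antisense distinction). ``mode="any_overlap"`` merges on any
    span overlap regardless of strand. Gene ids are deterministic, assigned
    in (chrom, start, first transcript_id) order.
    """
    if mode not in ("same_strand_exonic", "any_overlap"):
        raise ValueError(f"unknown grouping mode {mode!r}")
    ts = list(transcripts)
    n = len(ts)
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: (ts[i].chrom, ts[i].span.start, ts[i].span.end))
    # sweep: compare each transcript with actives whose span may still overlap
    active: list[int] = []
    for i in order:
        si = ts[i].span
        still = []
        for j in active:
            sj = ts[j].span
            if sj.chrom == si.chrom and sj.end > si.start:
                still.append(j)
                if mode == "any_overlap":
                    uf.union(i, j)
                elif (
                    ts[i].strand == ts[j].strand
                    and ts[i].strand != "."
                    and exonic_overlap(ts[i], ts[j], "same") > 0
                ):
                    uf.union(i, j)
        active = still + [i]
    groups: dict[int, list[TranscriptModel]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(ts[i])
    keyed = []
    for members in groups.values():
        members.sort(key=lambda t: (t.span.start, t.transcript_id))
        keyed.append(((members[0].chrom, members[0].span.start, members[0].transcript_id), members))
    keyed.sort(key=lambda km: km[0])
    genes = [
        GeneModel(gene_id=f"{gene_id_prefix}{idx:06d}", transcripts=tuple(members))
        for idx, (_, members) in enumerate(keyed, start=1)
    ]
    return genes


def genes_from_annotation(transcripts: Sequence[TranscriptModel]) -> list[GeneModel]:
    """Build genes directly from the gene_id attribute (reference annotations)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [
        GeneModel(gene_id=gid, transcripts=tuple(sorted(members, key=lambda t: t.transcript_id)))
        for gid, members in sorted(by_gene.items())
    ]
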