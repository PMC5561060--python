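"""Cross-species lncRNA orthology by sequence similarity and synteny.

Sequence evidence enters as a BLAST tabular (outfmt 6) hit table; synteny
evidence uses anchor blocks — pairs of intervals tied by 1:1 orthologous
coding genes. A mouse lncRNA and a human lncRNA are syntenic candidates
when the human lncRNA lies between the human orthologs of the two coding
genes flanking the mouse lncRNA, those two orthologs are adjacent on the
human chromosome (no third anchor between them) and their order respects
block orientation. Candidates from both routes are merged and resolved to a
1:1 matching by a deterministic greedy rank, then clustered by their joint
expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .annotation import GeneModel, GenomicInterval
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityHit:
    """One local alignment from a BLAST tabular (outfmt 6) row."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("hit ids must be non-empty")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity must be in [0, 100]")
        if self.e_value < 0 or self.bit_score < 0:
            raise ValueError("e_value and bit_score must be >= 0")


@dataclass(frozen=True)
class AnchorBlock:
    """A pair of corresponding intervals tied by a 1:1 coding ortholog pair."""

    mouse_interval: GenomicInterval
    human_interval: GenomicInterval
    mouse_gene: str
    human_gene: str
    orientation: str = "same"

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"orientation must be same/inverted, got {self.orientation!r}")


@dataclass(frozen=True)
class OrthologPair:
    mouse_gene: str
    human_gene: str
    evidence: frozenset[str]
    similarity_score: float | None = None
    synteny_score: float | None = None
    expression_group: int | None = None

    def __post_init__(self) -> None:
        if not self.evidence or not self.evidence <= {"sequence", "synteny"}:
            raise ValueError("evidence must be a non-empty subset of {sequence, synteny}")


def parse_blast_hits(path: str | Path) -> list[SimilarityHit]:
    """Parse a BLAST tabular (outfmt 6, 12-column) hit table."""
    hits = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                hits.append(
                    SimilarityHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def sequence_matches(
    hits: Sequence[SimilarityHit],
    min_identity: float = 60.0,
    max_evalue: float = 1e-5,
) -> list[OrthologPair]:
    """Threshold-filter hits and keep the best bit score per (query, subject)."""
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.percent_identity < min_identity or h.e_value > max_evalue:
            continue
        key = (h.query_id, h.subject_id)
        if key not in best or h.bit_score > best[key].bit_score:
            best[key] = h
    return [
        OrthologPair(
            mouse_gene=q,
            human_gene=s,
            evidence=frozenset({"sequence"}),
            similarity_score=h.bit_score,
        )
        for (q, s), h in sorted(best.items())
    ]


def _flanking_anchors(
    lnc: GeneModel, anchors: Sequence[AnchorBlock]
) -> tuple[AnchorBlock | None, AnchorBlock | None]:
    """Nearest anchored coding genes upstream and downstream of the lncRNA
    on the mouse genome (by coordinate, not transcription direction)."""
    span = lnc.span
    up = down = None
    for a in anchors:
        m = a.mouse_interval
        if m.chrom != span.chrom:
            continue
        if m.end <= span.start:
            if up is None or m.end > up.mouse_interval.end:
                up = a
        elif m.start >= span.end:
            if down is None or m.start < down.mouse_interval.start:
                down = a
    return up, down


def synteny_matches(
    mouse_lnc: GeneModel,
    human_lncs: Sequence[GeneModel],
    anchors: Sequence[AnchorBlock],
) -> list[OrthologPair]:
    """Synteny candidates for one mouse lncRNA.

    Requires flanking anchors on both sides whose human orthologs are on one
    chromosome, adjacent (no other anchor between them) and ordered
    consistently with their shared orientation. Every human lncRNA contained
    in the gap between the two human anchor intervals is a candidate;
    synteny_score = 1 / (1 + number of other human lncRNAs in the gap).
    """
    up, down = _flanking_anchors(mouse_lnc, anchors)
    if up is None or down is None:
        logger.warning("%s: no flanking anchors on both sides", mouse_lnc.gene_id)
        return []
    hu, hd = up.human_interval, down.human_interval
    if hu.chrom != hd.chrom:
        return []
    if up.orientation != down.orientation:
        return []
    left, right = (hu, hd) if hu.start <= hd.start else (hd, hu)
    if left.end > right.start:
        return []
    # orientation-consistent order: same keeps mouse order, inverted flips it
    expected_left = hu if up.orientation == "same" else hd
    if expected_left is not left:
        return []
    gap = GenomicInterval(hu.chrom, left.end, right.start) if right.start > left.end else None
    if gap is None:
        return []
    for a in anchors:
        if a is up or a is down:
            continue
        if a.human_interval.chrom == gap.chrom and a.human_interval.overlaps(gap):
            return []  # intervening anchor: gene order not conserved
    inside = [
        h for h in human_lncs if gap.contains(h.span)
    ]
    out = []
    for h in inside:
        score = 1.0 / (1.0 + (len(inside) - 1))
        out.append(
            OrthologPair(
                mouse_gene=mouse_lnc.gene_id,
                human_gene=h.gene_id,
                evidence=frozenset({"synteny"}),
                synteny_score=score,
            )
        )
    return sorted(out, key=lambda p: p.human_gene)


def synteny_matches_all(
    mouse_lncs: Sequence[GeneModel],
    human_lncs: Sequence[GeneModel],
    anchors: Sequence[AnchorBlock],
) -> list[OrthologPair]:
    out: list[OrthologPair] = []
    for lnc in mouse_lncs:
        out.extend(synteny_matches(lnc, human_lncs, anchors))
    return out


def merge_candidates(candidates: Sequence[OrthologPair]) -> list[OrthologPair]:
    """Merge per-(mouse, human) duplicates, taking the union of evidence and
    the best score on each route."""
    merged: dict[tuple[str, str], OrthologPair] = {}
    for c in candidates:
        key = (c.mouse_gene, c.human_gene)
        if key not in merged:
            merged[key] = c
        else:
            prev = merged[key]
            merged[key] = OrthologPair(
                mouse_gene=c.mouse_gene,
                human_gene=c.human_gene,
                evidence=prev.evidence | c.evidence,
                similarity_score=_max_opt(prev.similarity_score, c.similarity_score),
                synteny_score=_max_opt(prev.synteny_score, c.synteny_score),
            )
    return [merged[k] for k in sorted(merged)]


def _max_opt(a: float | None, b: float | None) -> float | None:
    if a is None:
        return b
    if b is None:
        return a
    return max(a, b)


_EVIDENCE_RANK = {
    frozenset({"sequence", "synteny"}): 0,
    frozenset({"sequence"}): 1,
    frozenset({"synteny"}): 2,
}


def _rank_key(p: OrthologPair) -> tuple:
    return (
        _EVIDENCE_RANK[p.evidence],
        -(p.similarity_score if p.similarity_score is not None else -np.inf),
        -(p.synteny_score if p.synteny_score is not None else -np.inf),
        p.mouse_gene,
        p.human_gene,
    )


def resolve_orthologs(candidates: Sequence[OrthologPair]) -> list[OrthologPair]:
    """Resolve multiple matching to a 1:1 set by deterministic greedy rank.

    Rank: evidence {sequence,synteny} > {sequence} > {synteny}, then higher
    similarity score, then higher synteny score, then lexicographic ids.
    Each gene is used at most once; the result is a maximal matching
    consistent with the rank order.
    """
    merged = merge_candidates(candidates)
    used_mouse: set[str] = set()
    used_human: set[str] = set()
    out = []
    for p in sorted(merged, key=_rank_key):
        if p.mouse_gene in used_mouse or p.human_gene in used_human:
            continue
        used_mouse.add(p.mouse_gene)
        used_human.add(p.human_gene)
        out.append(p)
    return out


def cluster_ortholog_expression(
    pairs: Sequence[OrthologPair],
    mouse_expr: ExpressionMatrix,
    human_expr: ExpressionMatrix,
    k: int = 3,
) -> tuple[list[OrthologPair], list[OrthologPair]]:
    """Cluster resolved pairs by joint expression into k groups.

    Feature vector per pair: the log2(FPKM+1) mouse profile concatenated
    with the human profile, each feature standardized across pairs (so
    expression *level* is retained — the groups of interest differ by level:
    high in both species, high in mouse only, low in both). Average-linkage
    hierarchical clustering on Euclidean distance, cut at k. Cluster labels
    are reordered by descending mean human log2 expression so group 1 is
    "high in human". Pairs missing expression in either matrix are returned
    separately, never silently dropped.
    """
    kept, excluded = [], []
    for p in pairs:
        if p.mouse_gene in mouse_expr.values.index and p.human_gene in human_expr.values.index:
            kept.append(p)
        else:
            excluded.append(p)
    if not kept:
        return [], excluded
    if k < 1:
        raise ValueError("k must be >= 1")

    def profile(expr: ExpressionMatrix, gene: str) -> np.ndarray:
        return np.log2(expr.values.loc[gene].to_numpy(dtype=float) + 1.0)

    feats, human_means = [], []
    for p in kept:
        pm = profile(mouse_expr, p.mouse_gene)
        ph = profile(human_expr, p.human_gene)
        feats.append(np.concatenate([pm, ph]))
        human_means.append(float(ph.mean()))
    X = np.vstack(feats)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    if len(kept) <= k:
        raw = np.arange(1, len(kept) + 1)
    elif k == 1:
        raw = np.ones(len(kept), dtype=int)
    else:
        Z = sch.linkage(pdist(X), method="average")
        raw = sch.fcluster(Z, t=k, criterion="maxclust")
    hm = np.asarray(human_means)
    order = sorted(set(raw), key=lambda c: -hm[raw == c].mean())
    relabel = {c: i + 1 for i, c in enumerate(order)}
    out = [replace(p, expression_group=relabel[int(c)]) for p, c in zip(kept, raw)]
    return out, excluded


# ---------------------------------------------------------------------------
# Anchor-table and pair-table I/O

ANCHOR_COLUMNS = [
    "mouse_chrom", "mouse_start", "mouse_end", "mouse_gene",
    "human_chrom", "human_start", "human_end", "human_gene", "orientation",
]


def read_anchor_table(path: str | Path) -> list[AnchorBlock]:
    df = pd.read_csv(path, sep="\t")
    return [
        AnchorBlock(
            mouse_interval=GenomicInterval(r.mouse_chrom, int(r.mouse_start), int(r.mouse_end)),
            human_interval=GenomicInterval(r.human_chrom, int(r.human_start), int(r.human_end)),
            mouse_gene=r.mouse_gene,
            human_gene=r.human_gene,
            orientation=r.orientation,
        )
        for r in df.itertuples(index=False)
    ]


def write_anchor_table(anchors: Iterable[AnchorBlock], path: str | Path) -> None:
    rows = [
        {
            "mouse_chrom": a.mouse_interval.chrom,
            "mouse_start": a.mouse_interval.start,
            "mouse_end": a.mouse_interval.end,
            "mouse_gene": a.mouse_gene,
            "human_chrom": a.human_interval.chrom,
            "human_start": a.human_interval.start,
            "human_end": a.human_interval.end,
            "human_gene": a.human_gene,
            "orientation": a.orientation,
        }
        for a in anchors
    ]
    pd.DataFrame(rows, columns=ANCHOR_COLUMNS).to_csv(path, sep="\t", index=False)


def pairs_to_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mouse_gene": p.mouse_gene,
                "human_gene": p.human_gene,
                "evidence": "+".join(sorted(p.evidence)),
                "similarity_score": p.similarity_score,
                "synteny_score": p.synteny_score,
                "expression_group": p.expression_group,
            }
            for p in pairs
        ]
    )
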