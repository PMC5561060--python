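"""Synthetic inner-ear study generator with planted ground truth.

Emulates the structure of a two-tissue (cochlea, vestibule), two-stage
(E16.5, P0), three-replicate RNA-seq experiment on two genomes: a mouse
chromosome carrying protein-coding genes, lincRNAs, antisense lncRNAs,
small-RNA hosts and planted exclusion classes, and a human chromosome
mirroring a subset of lncRNAs as orthologs placed syntenically between
mirrored coding-gene anchors. Counts are negative binomial over log-normal
baselines with a ~20x coding/lncRNA expression gap, mirroring the order-of-
magnitude difference seen between coding and non-coding transcripts; a
66-sample multi-tissue FPKM panel plants silent and ubiquitous genes; the
BLAST-style hit table plants sequence-evidence orthologs plus decoys.

Every emitted file round-trips through the package's own parsers, and the
planted truth is serialized to TSV alongside the data.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    genes_from_annotation,
    write_bed,
    write_gtf,
)
from .expression import ExpressionMatrix, SampleInfo, write_sample_sheet
from .orthology import AnchorBlock, write_anchor_table

STOPS = ("TAA", "TAG", "TGA")


@dataclass
class GeneratorConfig:
    """Study-design knobs for the synthetic generator.

    Defaults emulate the study conditions: a 2 tissue x 2 stage x 3
    replicate design (12 samples), a 66-sample specificity panel with 46%
    of lncRNAs silent everywhere, lincRNA/antisense transcripts with 2-3
    exons vs 4-5 for coding genes and hosts, NB dispersion 0.1, planted
    differential expression at |log2FC| = 2 and cis pairs at a target
    correlation near 0.9.
    """

    seed: int = 0
    # class sizes
    n_coding: int = 48
    n_linc: int = 30
    n_antisense: int = 12
    n_host: int = 6
    n_short: int = 5
    n_intronic: int = 5
    n_coding_like: int = 6  # candidates removed by the coding filter
    # geometry (bp)
    exon_range_lnc: tuple[int, int] = (150, 400)
    exon_range_coding: tuple[int, int] = (150, 400)
    exon_count_lnc: tuple[int, int] = (2, 3)
    exon_count_coding: tuple[int, int] = (4, 5)
    intron_range_coding: tuple[int, int] = (1000, 2000)
    intron_range_lnc: tuple[int, int] = (500, 1500)
    margin: int = 2000
    gap: int = 13000
    mouse_chrom: str = "chr1"
    human_chrom: str = "hchr1"
    # novelty / orthology
    fraction_known: float = 0.4
    n_ortho_synteny: int = 8
    n_ortho_both: int = 4
    n_ortho_sequence: int = 3
    n_human_decoys: int = 6
    inverted_anchor_fraction: float = 0.0
    # expression design
    tissues: tuple[str, str] = ("cochlea", "vestibule")
    stages: tuple[str, str] = ("E16.5", "P0")
    replicates: int = 3
    nb_dispersion: float = 0.1
    depth: float = 20.0  # expected counts for a 1-kb gene at FPKM-level 1
    coding_median_level: float = 5.9
    lnc_median_level: float = 0.3
    lnc_level_floor: float = 0.1
    level_sigma: float = 0.8
    # one Poisson "rest of the transcriptome" row absorbs this much library
    # mass so per-gene FPKM lands on the level scale (FPKM ~ level)
    background_library_counts: float = 2.0e7
    library_size_cv: float = 0.3
    n_de: int = 20
    de_log2fc: float = 2.0
    n_cis: int = 8
    cis_sigma: float = 1.05
    # panel
    n_panel_samples: int = 66
    fraction_silent: float = 0.46
    fraction_ubiquitous: float = 0.1
    # similarity hits
    n_decoy_hits: int = 20

    def design(self) -> list[SampleInfo]:
        out = []
        for tissue in self.tissues:
            for stage in self.stages:
                for rep in range(1, self.replicates + 1):
                    out.append(SampleInfo(f"{tissue}_{stage}_r{rep}", tissue, stage, rep))
        return out


@dataclass
class SyntheticTruth:
    """Planted ground truth for every stage of the pipeline."""

    transcript_classes: dict[str, str] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)
    novel_genes: dict[str, bool] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # evidence str
    silent_genes: set[str] = field(default_factory=set)
    ubiquitous_genes: set[str] = field(default_factory=set)
    disease_genes: list[str] = field(default_factory=list)
    locus_truth: dict[str, list[str]] = field(default_factory=dict)

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        pd.DataFrame(
            sorted(self.transcript_classes.items()), columns=["transcript_id", "category"]
        ).to_csv(outdir / "truth_transcript_classes.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.gene_classes.items()), columns=["gene_id", "category"]
        ).to_csv(outdir / "truth_gene_classes.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.novel_genes.items()), columns=["gene_id", "novel"]
        ).to_csv(outdir / "truth_novelty.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.de_genes.items()), columns=["gene_id", "log2fc"]
        ).to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
        pd.DataFrame(self.cis_pairs, columns=["lncrna_gene", "coding_gene"]).to_csv(
            outdir / "truth_cis_pairs.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            self.ortholog_pairs, columns=["mouse_gene", "human_gene", "evidence"]
        ).to_csv(outdir / "truth_orthologs.tsv", sep="\t", index=False)
        with (outdir / "truth_misc.json").open("w") as fh:
            json.dump(
                {
                    "silent_genes": sorted(self.silent_genes),
                    "ubiquitous_genes": sorted(self.ubiquitous_genes),
                    "disease_genes": self.disease_genes,
                    "locus_truth": self.locus_truth,
                },
                fh,
                indent=1,
            )


@dataclass
class SyntheticAnnotation:
    candidates: list[TranscriptModel]
    coding: list[TranscriptModel]
    small_rnas: list[GenomicInterval]
    known_lncs: list[TranscriptModel]
    human_lncs: list[TranscriptModel]
    anchors: list[AnchorBlock]
    truth: SyntheticTruth

    @property
    def coding_genes(self) -> list[GeneModel]:
        return genes_from_annotation(self.coding)

    @property
    def candidate_genes(self) -> list[GeneModel]:
        return genes_from_annotation(self.candidates)

    @property
    def human_lnc_genes(self) -> list[GeneModel]:
        return genes_from_annotation(self.human_lncs)


def _make_transcript(
    rng: np.random.Generator,
    tid: str,
    gid: str,
    chrom: str,
    start: int,
    strand: str,
    n_exons: int,
    exon_range: tuple[int, int],
    intron_range: tuple[int, int],
    biotype: str = "lncRNA_candidate",
) -> TranscriptModel:
    exons = []
    pos = start
    for i in range(n_exons):
        elen = int(rng.integers(exon_range[0], exon_range[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
    return TranscriptModel(tid, gid, tuple(exons), biotype)


def generate_annotation(cfg: GeneratorConfig) -> SyntheticAnnotation:
    """Lay out both genomes and plant every transcript class.

    Genes are placed sequentially along one mouse chromosome with >= 1 kb
    safety margins so the planted class labels are geometrically
    unambiguous. Coding genes double as synteny anchors; the human
    chromosome mirrors them with equal-length intervals in the same order,
    and planted syntenic human lncRNAs sit in the inter-anchor gap matching
    their mouse partner.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth()
    chrom = cfg.mouse_chrom

    coding: list[TranscriptModel] = []
    cursor = 10_000
    gap_bounds: list[tuple[int, int]] = []  # usable gap between consecutive coding genes
    prev_end: int | None = None
    for i in range(cfg.n_coding):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exon_count_coding[0], cfg.exon_count_coding[1] + 1))
        t = _make_transcript(
            rng, f"CT{i+1:04d}", f"CG{i+1:04d}", chrom, cursor, strand,
            n_ex, cfg.exon_range_coding, cfg.intron_range_coding, "protein_coding",
        )
        coding.append(t)
        if prev_end is not None:
            gap_bounds.append((prev_end, t.span.start))
        prev_end = t.span.end
        cursor = t.span.end + cfg.gap

    candidates: list[TranscriptModel] = []
    small_rnas: list[GenomicInterval] = []
    gap_of_gene: dict[str, int] = {}

    def place_in_gap(gap_idx: int, tid: str, gid: str, n_exons: int,
                     intron_range: tuple[int, int], single_exon_len: int | None = None
                     ) -> TranscriptModel:
        lo, hi = gap_bounds[gap_idx]
        strand = "+" if rng.random() < 0.5 else "-"
        start = lo + cfg.margin + int(rng.integers(0, 500))
        if single_exon_len is not None:
            t = TranscriptModel(
                tid, gid,
                (GenomicInterval(chrom, start, start + single_exon_len, strand),),
            )
        else:
            t = _make_transcript(
                rng, tid, gid, chrom, start, strand, n_exons,
                cfg.exon_range_lnc, intron_range,
            )
        if t.span.end > hi - cfg.margin:
            raise ValueError(
                "geometry overflow: gap too short for requested gene; increase cfg.gap"
            )
        gap_of_gene[gid] = gap_idx
        return t

    gap_idx = 0
    linc_ids: list[str] = []
    for i in range(cfg.n_linc):
        n_ex = int(rng.integers(cfg.exon_count_lnc[0], cfg.exon_count_lnc[1] + 1))
        gid, tid = f"LG{i+1:04d}", f"LT{i+1:04d}"
        candidates.append(place_in_gap(gap_idx, tid, gid, n_ex, cfg.intron_range_lnc))
        truth.transcript_classes[tid] = "lincRNA"
        truth.gene_classes[gid] = "lincRNA"
        linc_ids.append(gid)
        gap_idx += 1

    host_ids: list[str] = []
    for i in range(cfg.n_host):
        gid, tid = f"HG{i+1:04d}", f"HT{i+1:04d}"
        t = place_in_gap(gap_idx, tid, gid, int(rng.integers(4, 6)), cfg.intron_range_lnc)
        candidates.append(t)
        intron = t.introns()[0]
        mid = (intron.start + intron.end) // 2
        small_rnas.append(GenomicInterval(chrom, mid - 40, mid + 40, t.strand))
        truth.transcript_classes[tid] = "small_rna_host"
        truth.gene_classes[gid] = "small_rna_host"
        host_ids.append(gid)
        gap_idx += 1

    for i in range(cfg.n_short):
        gid, tid = f"SG{i+1:04d}", f"ST{i+1:04d}"
        candidates.append(place_in_gap(gap_idx, tid, gid, 1, cfg.intron_range_lnc,
                                       single_exon_len=int(rng.integers(80, 200))))
        truth.transcript_classes[tid] = "excluded_short"
        gap_idx += 1

    coding_like_ids: list[str] = []
    for i in range(cfg.n_coding_like):
        gid, tid = f"XG{i+1:04d}", f"XT{i+1:04d}"
        candidates.append(place_in_gap(gap_idx, tid, gid,
                                       int(rng.integers(2, 4)), cfg.intron_range_lnc))
        truth.transcript_classes[tid] = "excluded_coding"
        coding_like_ids.append(tid)
        gap_idx += 1

    # antisense: first exon overlapping a coding exon on the opposite strand,
    # second exon reaching into the margin before/after the coding gene
    for i in range(cfg.n_antisense):
        host_gene = coding[i % cfg.n_coding]
        gid, tid = f"AG{i+1:04d}", f"AT{i+1:04d}"
        strand = "-" if host_gene.strand == "+" else "+"
        ex0 = host_gene.exons[0]
        exon1 = GenomicInterval(chrom, ex0.start + 20, ex0.end + 150, strand)
        up_start = host_gene.span.start - 1200
        exon2 = GenomicInterval(chrom, up_start, up_start + 250, strand)
        candidates.append(TranscriptModel(tid, gid, (exon2, exon1)))
        truth.transcript_classes[tid] = "antisense"
        truth.gene_classes[gid] = "antisense"

    # intron-contained same-strand transcripts (planted exclusions)
    for i in range(cfg.n_intronic):
        host_gene = coding[(i * 3 + 1) % cfg.n_coding]
        gid, tid = f"IG{i+1:04d}", f"IT{i+1:04d}"
        intron = host_gene.introns()[0]
        start = intron.start + 150
        exon = GenomicInterval(chrom, start, start + 300, host_gene.strand)
        candidates.append(TranscriptModel(tid, gid, (exon,)))
        truth.transcript_classes[tid] = "excluded_intronic_same_strand"

    # novelty: a fraction of surviving lncRNA genes also exist in the known
    # reference annotation (overlapping copies with jittered bounds)
    lnc_gene_ids = linc_ids + host_ids + [f"AG{i+1:04d}" for i in range(cfg.n_antisense)]
    by_gid = {t.gene_id: t for t in candidates}
    n_known = int(round(cfg.fraction_known * len(lnc_gene_ids)))
    known_set = sorted(str(g) for g in rng.choice(lnc_gene_ids, size=n_known, replace=False))
    known_lncs: list[TranscriptModel] = []
    for j, gid in enumerate(known_set):
        src = by_gid[gid]
        exons = tuple(
            GenomicInterval(e.chrom, max(0, e.start - 10), e.end + 10, e.strand)
            for e in src.exons
        )
        known_lncs.append(
            TranscriptModel(f"KT{j+1:04d}", f"KG{j+1:04d}", exons, "known_lncRNA")
        )
    for gid in lnc_gene_ids:
        truth.novel_genes[gid] = gid not in known_set

    # human genome: anchors mirror coding genes (equal-length intervals,
    # same order); a fraction may be flagged inverted for liftover fixtures
    anchors: list[AnchorBlock] = []
    for i, t in enumerate(coding):
        orientation = (
            "inverted" if rng.random() < cfg.inverted_anchor_fraction else "same"
        )
        anchors.append(
            AnchorBlock(
                mouse_interval=GenomicInterval(chrom, t.span.start, t.span.end),
                human_interval=GenomicInterval(cfg.human_chrom, t.span.start, t.span.end),
                mouse_gene=t.gene_id,
                human_gene=f"h{t.gene_id}",
                orientation=orientation,
            )
        )

    # orthologs among lincs: synteny-only, both, sequence-only
    human_lncs: list[TranscriptModel] = []
    picked = [str(g) for g in rng.permutation(linc_ids)]
    syn_ids = picked[: cfg.n_ortho_synteny]
    both_ids = picked[cfg.n_ortho_synteny : cfg.n_ortho_synteny + cfg.n_ortho_both]
    seq_ids = picked[
        cfg.n_ortho_synteny + cfg.n_ortho_both :
        cfg.n_ortho_synteny + cfg.n_ortho_both + cfg.n_ortho_sequence
    ]
    h_idx = 0
    for gid in syn_ids + both_ids:
        src = by_gid[gid]
        h_idx += 1
        hgid, htid = f"hLG{h_idx:04d}", f"hLT{h_idx:04d}"
        exons = tuple(
            GenomicInterval(cfg.human_chrom, e.start + 37, e.end + 37, e.strand)
            for e in src.exons
        )
        human_lncs.append(TranscriptModel(htid, hgid, exons))
        evidence = "sequence+synteny" if gid in both_ids else "synteny"
        truth.ortholog_pairs.append((gid, hgid, evidence))
    for gid in seq_ids:
        h_idx += 1
        hgid, htid = f"hLG{h_idx:04d}", f"hLT{h_idx:04d}"
        start = 5_000_000 + h_idx * 20_000
        human_lncs.append(
            TranscriptModel(
                htid, hgid,
                (GenomicInterval("hchr2", start, start + 1500, "+"),),
            )
        )
        truth.ortholog_pairs.append((gid, hgid, "sequence"))
    # decoy human lncRNAs in gaps whose mouse occupant is an excluded class
    decoy_gaps = list(range(cfg.n_linc + cfg.n_host, len(gap_bounds)))
    for d in range(cfg.n_human_decoys):
        gidx = decoy_gaps[d % len(decoy_gaps)]
        lo, hi = gap_bounds[gidx]
        start = lo + cfg.margin + 600
        h_idx += 1
        human_lncs.append(
            TranscriptModel(
                f"hLT{h_idx:04d}", f"hLG{h_idx:04d}",
                (GenomicInterval(cfg.human_chrom, start, min(start + 1200, hi - cfg.margin), "+"),),
            )
        )

    return SyntheticAnnotation(
        candidates=candidates,
        coding=coding,
        small_rnas=small_rnas,
        known_lncs=known_lncs,
        human_lncs=human_lncs,
        anchors=anchors,
        truth=truth,
    )


def shuffle_anchor_order(
    anchors: Sequence[AnchorBlock], seed: int = 0
) -> list[AnchorBlock]:
    """Permute human anchor positions so no originally-adjacent pair of
    anchors remains adjacent — a synteny-broken control universe."""
    rng = np.random.default_rng(seed)
    n = len(anchors)
    ordered = sorted(anchors, key=lambda a: (a.human_interval.chrom, a.human_interval.start))
    positions = [a.human_interval for a in ordered]
    for _ in range(10_000):
        perm = rng.permutation(n)
        ok = True
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        for i in range(n - 1):
            if abs(int(inv[i]) - int(inv[i + 1])) == 1:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - n>=4 always terminates quickly
        raise RuntimeError("could not find adjacency-breaking permutation")
    out = []
    for i, a in enumerate(ordered):
        out.append(
            AnchorBlock(
                mouse_interval=a.mouse_interval,
                human_interval=positions[int(perm[i])],
                mouse_gene=a.mouse_gene,
                human_gene=a.human_gene,
                orientation=a.orientation,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Counts

def _gene_lengths(genes: Sequence[GeneModel]) -> pd.Series:
    return pd.Series(
        {g.gene_id: g.transcripts[0].mature_length for g in genes}, name="length"
    )


def generate_counts(
    annotation: SyntheticAnnotation, cfg: GeneratorConfig
) -> ExpressionMatrix:
    """NB counts for the 2x2x3 design with planted DE genes and cis pairs.

    Per-gene baseline levels are log-normal with medians calibrated to the
    5.9 (coding) vs 0.3 (lncRNA) FPKM gap; a single Poisson background row
    ("BG0001") carries the library mass of the rest of the transcriptome so
    computed FPKM sits on the level scale. Planted DE genes get a 2^log2fc
    multiplier in the first tissue; planted cis pairs share a per-sample
    log-normal latent factor sized to induce correlation near 0.9; library
    sizes vary +-30%.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = annotation.truth
    truth.de_genes.clear()  # idempotent across repeated calls
    truth.cis_pairs.clear()
    samples = cfg.design()
    coding_genes = annotation.coding_genes
    lnc_genes = annotation.candidate_genes
    genes = coding_genes + lnc_genes
    lengths = _gene_lengths(genes)
    gene_ids = list(lengths.index)
    is_coding = np.array([g.startswith("CG") for g in gene_ids])

    levels = np.where(
        is_coding,
        np.exp(rng.normal(np.log(cfg.coding_median_level), cfg.level_sigma, len(gene_ids))),
        np.maximum(
            np.exp(rng.normal(np.log(cfg.lnc_median_level), cfg.level_sigma, len(gene_ids))),
            cfg.lnc_level_floor,  # stays above the discovery expression floor
        ),
    )
    level = pd.Series(levels, index=gene_ids)

    # planted DE genes: half coding, half lncRNA, up in tissue[0]
    expressed_lnc = [g for g in gene_ids if g.startswith(("LG", "HG", "AG"))]
    coding_ids = [g for g in gene_ids if g.startswith("CG")]
    de_pool = (
        [str(g) for g in rng.choice(coding_ids, size=cfg.n_de // 2, replace=False)]
        + [str(g) for g in rng.choice(expressed_lnc, size=cfg.n_de - cfg.n_de // 2, replace=False)]
    )
    for g in de_pool:
        truth.de_genes[g] = cfg.de_log2fc

    # planted cis pairs: a linc and its right-flanking coding anchor share a
    # latent factor; the linc baseline is raised so NB noise does not drown it
    free_lincs = [g for g in expressed_lnc if g.startswith("LG") and g not in truth.de_genes]
    cis_lincs = [str(g) for g in rng.choice(free_lincs, size=cfg.n_cis, replace=False)]
    anchor_by_mouse_gene = {a.mouse_gene: a for a in annotation.anchors}
    coding_sorted = sorted(coding_genes, key=lambda g: g.span.start)
    linc_span = {g.gene_id: g.span for g in lnc_genes}
    cis_coding: list[str] = []
    used_coding: set[str] = set()
    for lg in cis_lincs:
        right = next(
            (c.gene_id for c in coding_sorted
             if c.span.start >= linc_span[lg].end
             and c.gene_id not in used_coding
             and c.gene_id not in truth.de_genes),
            coding_sorted[-1].gene_id,
        )
        used_coding.add(right)
        cis_coding.append(right)
        truth.cis_pairs.append((lg, right))
        level[lg] = float(np.exp(rng.normal(np.log(cfg.coding_median_level), 0.3)))

    lib_factors = rng.uniform(1 - cfg.library_size_cv, 1 + cfg.library_size_cv, len(samples))

    mean = np.outer(level.to_numpy() * lengths.to_numpy() / 1000.0 * cfg.depth, lib_factors)
    tissue0 = np.array([s.tissue == cfg.tissues[0] for s in samples])
    for g in truth.de_genes:
        i = gene_ids.index(g)
        mean[i, tissue0] *= 2.0 ** cfg.de_log2fc
    for lg, cg in truth.cis_pairs:
        factor = np.exp(rng.normal(0.0, cfg.cis_sigma, len(samples)))
        for g in (lg, cg):
            mean[gene_ids.index(g), :] *= factor

    mean = np.maximum(mean, 1e-8)
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)
    values = pd.DataFrame(counts, index=gene_ids, columns=[s.sample_id for s in samples])
    if cfg.background_library_counts > 0:
        bg = rng.poisson(cfg.background_library_counts * lib_factors)
        values.loc["BG0001"] = bg
        lengths = pd.concat([lengths, pd.Series({"BG0001": 1000})]).rename("length")
    return ExpressionMatrix(values=values, unit="counts", gene_lengths=lengths, samples=samples)


def generate_specificity_panel(
    annotation: SyntheticAnnotation, cfg: GeneratorConfig
) -> ExpressionMatrix:
    """66-sample multi-tissue FPKM panel for the planted lncRNA genes.

    A ``fraction_silent`` share of genes is < 1 FPKM everywhere, a
    ``fraction_ubiquitous`` share is >= 1 everywhere, and the rest are
    expressed in a random handful of samples.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    truth = annotation.truth
    gene_ids = sorted(truth.gene_classes)
    n = len(gene_ids)
    n_silent = int(round(cfg.fraction_silent * n))
    n_ubiq = int(round(cfg.fraction_ubiquitous * n))
    perm = [str(g) for g in rng.permutation(gene_ids)]
    silent = set(perm[:n_silent])
    ubiq = set(perm[n_silent : n_silent + n_ubiq])
    truth.silent_genes = silent
    truth.ubiquitous_genes = ubiq
    cols = [f"panel_s{i+1:02d}" for i in range(cfg.n_panel_samples)]
    values = np.zeros((n, cfg.n_panel_samples))
    for i, g in enumerate(gene_ids):
        if g in silent:
            values[i] = rng.uniform(0.0, 0.8, cfg.n_panel_samples)
        elif g in ubiq:
            values[i] = rng.uniform(1.5, 40.0, cfg.n_panel_samples)
        else:
            k = int(rng.integers(1, cfg.n_panel_samples // 2))
            idx = rng.choice(cfg.n_panel_samples, size=k, replace=False)
            row = rng.uniform(0.0, 0.8, cfg.n_panel_samples)
            row[idx] = rng.uniform(1.5, 20.0, k)
            values[i] = row
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=cols), unit="fpkm"
    )


def generate_similarity_hits(
    annotation: SyntheticAnnotation, cfg: GeneratorConfig
) -> pd.DataFrame:
    """BLAST tabular (outfmt 6) hit table: planted sequence-evidence pairs
    pass the default thresholds; decoys fail by e-value or identity."""
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []

    def row(q, s, ident, length, evalue, bits):
        return [q, s, round(ident, 2), length, 1, length, 1, length, 1, length,
                f"{evalue:.2e}", round(bits, 1)]

    for mouse_gene, human_gene, evidence in annotation.truth.ortholog_pairs:
        if "sequence" not in evidence:
            continue
        n_hits = int(rng.integers(1, 3))
        for _ in range(n_hits):
            rows.append(
                row(mouse_gene, human_gene,
                    rng.uniform(72, 95), int(rng.integers(200, 600)),
                    10.0 ** rng.uniform(-40, -10), rng.uniform(80, 300))
            )
    human_ids = [t.gene_id for t in annotation.human_lncs]
    mouse_ids = sorted({g for g, _, _ in annotation.truth.ortholog_pairs})
    true_pairs = {(m, h) for m, h, _ in annotation.truth.ortholog_pairs}
    made = 0
    while made < cfg.n_decoy_hits and mouse_ids and human_ids:
        q = str(rng.choice(mouse_ids))
        s = str(rng.choice(human_ids))
        if (q, s) in true_pairs:
            continue
        if rng.random() < 0.5:  # fails e-value
            rows.append(row(q, s, rng.uniform(72, 95), int(rng.integers(60, 200)),
                            10.0 ** rng.uniform(-4, 0), rng.uniform(20, 40)))
        else:  # fails identity
            rows.append(row(q, s, rng.uniform(30, 55), int(rng.integers(60, 200)),
                            10.0 ** rng.uniform(-20, -10), rng.uniform(40, 80)))
        made += 1
    return pd.DataFrame(rows)


def generate_coding_assessments(
    annotation: SyntheticAnnotation, cfg: GeneratorConfig
) -> pd.DataFrame:
    """Per-candidate coding-potential table: planted coding-like candidates
    carry long ORFs or homology hits; true lncRNAs stay below thresholds."""
    rng = np.random.default_rng(cfg.seed + 4)
    rows = []
    for t in annotation.candidates:
        truth_cat = annotation.truth.transcript_classes[t.transcript_id]
        if truth_cat == "excluded_coding":
            mode = rng.random()
            rows.append({
                "transcript_id": t.transcript_id,
                "longest_orf_aa": int(rng.integers(120, 400)) if mode < 0.7 else int(rng.integers(10, 60)),
                "external_coding_score": float(rng.uniform(60, 200)) if mode >= 0.7 else float(rng.uniform(0, 20)),
                "homology_hit": bool(mode >= 0.9),
            })
        else:
            rows.append({
                "transcript_id": t.transcript_id,
                "longest_orf_aa": int(rng.integers(5, 70)),
                "external_coding_score": float(rng.uniform(0, 20)),
                "homology_hit": False,
            })
    return pd.DataFrame(rows)


def generate_disease_annotation(
    annotation: SyntheticAnnotation, cfg: GeneratorConfig
) -> tuple[pd.DataFrame, list[tuple[str, GenomicInterval]]]:
    """Disease-gene table (MGI-style MP terms) and human deafness loci.

    Disease genes are the coding anchors flanking planted cis pairs plus a
    few extras; loci are human intervals spanning several anchor blocks, so
    the mapped mouse interval provably contains known planted lncRNAs.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    truth = annotation.truth
    cis_coding = [cg for _, cg in truth.cis_pairs]
    extra = [g.gene_id for g in annotation.coding_genes[:4] if g.gene_id not in cis_coding]
    disease = cis_coding + extra
    truth.disease_genes = disease
    terms = ["MP:0006325", "MP:0001967"]
    df = pd.DataFrame(
        {"gene_id": disease, "term": [terms[i % 2] for i in range(len(disease))]}
    )
    anchors = sorted(annotation.anchors, key=lambda a: a.human_interval.start)
    loci = []
    lnc_genes = [
        g for g in annotation.candidate_genes
        if truth.gene_classes.get(g.gene_id) in ("lincRNA", "antisense", "small_rna_host")
    ]
    for i, (lo_i, hi_i) in enumerate([(2, 8), (15, 25)]):
        a, b = anchors[lo_i], anchors[hi_i]
        start = a.human_interval.start + 50
        end = b.human_interval.end - 50
        iv = GenomicInterval(cfg.human_chrom, start, end)
        locus_id = f"DFNB_SYN{i+1}"
        # identity layout: the mouse interval equals the human one on chr1
        mouse_iv = GenomicInterval(cfg.mouse_chrom, start, end)
        truth.locus_truth[locus_id] = sorted(
            g.gene_id for g in lnc_genes if g.span.overlaps(mouse_iv)
        )
        loci.append((locus_id, iv))
    return df, loci


# ---------------------------------------------------------------------------
# Sequences for ORF exercises

def random_noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Stop-codon-rich random sequence: every reading frame carries a stop in
    every 60-bp window, so no frame holds an ORF anywhere near coding length."""
    seq = list(rng.choice(list("ACGT"), length))
    for window_start in range(0, max(length - 12, 0), 60):
        for frame in range(3):
            p = window_start + ((frame - window_start) % 3)
            p += 3 * int(rng.integers(0, 16))
            if p + 3 <= length:
                stop = STOPS[int(rng.integers(0, 3))]
                seq[p : p + 3] = list(stop)
    return "".join(seq)


def sequence_with_orf(rng: np.random.Generator, orf_codons: int, flank: int = 60) -> str:
    """Sequence carrying one planted ATG..stop ORF of the given codon count."""
    body = []
    safe = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
            if c not in STOPS and c != "ATG"]
    for _ in range(orf_codons - 1):
        body.append(safe[int(rng.integers(0, len(safe)))])
    left = random_noncoding_sequence(rng, flank)
    right = random_noncoding_sequence(rng, flank)
    return left + "ATG" + "".join(body) + "TAA" + right


# ---------------------------------------------------------------------------
# Bundle writer

def write_all(annotation: SyntheticAnnotation, cfg: GeneratorConfig, outdir: str | Path,
              counts: ExpressionMatrix | None = None,
              panel: ExpressionMatrix | None = None) -> dict[str, Path]:
    """Emit the full input bundle (GTFs, tables, truth) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def reg(name: str, fname: str) -> Path:
        paths[name] = outdir / fname
        return paths[name]

    write_gtf(annotation.candidates, reg("candidates_gtf", "mouse_candidates.gtf"))
    reference = list(annotation.coding)
    for i, s in enumerate(annotation.small_rnas):
        reference.append(
            TranscriptModel(f"sRT{i+1:04d}", f"sRG{i+1:04d}", (s,), "small_rna")
        )
    write_gtf(reference, reg("reference_gtf", "mouse_reference.gtf"))
    write_gtf(annotation.known_lncs, reg("known_lnc_gtf", "mouse_known_lncRNAs.gtf"))
    write_gtf(annotation.human_lncs, reg("human_lnc_gtf", "human_lncRNAs.gtf"))
    write_anchor_table(annotation.anchors, reg("anchors", "anchors.tsv"))

    if counts is None:
        counts = generate_counts(annotation, cfg)
    counts.to_tsv(reg("counts", "counts.tsv"))
    counts.gene_lengths.to_csv(reg("gene_lengths", "gene_lengths.tsv"), sep="\t",
                               index_label="gene_id")
    write_sample_sheet(counts.samples, reg("sample_sheet", "samples.tsv"))

    if panel is None:
        panel = generate_specificity_panel(annotation, cfg)
    panel.to_tsv(reg("panel", "panel_fpkm.tsv"))

    hits = generate_similarity_hits(annotation, cfg)
    hits.to_csv(reg("hits", "similarity_hits.tsv"), sep="\t", index=False, header=False)

    assess = generate_coding_assessments(annotation, cfg)
    assess.to_csv(reg("assessments", "coding_assessments.tsv"), sep="\t", index=False)

    disease_df, loci = generate_disease_annotation(annotation, cfg)
    disease_df.to_csv(reg("disease_genes", "disease_genes.tsv"), sep="\t", index=False)
    write_bed([iv for _, iv in loci], reg("loci_bed", "deafness_loci_hg.bed"),
              names=[lid for lid, _ in loci])

    annotation.truth.write(outdir)
    return paths
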