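"""End-to-end orchestration: validate a config, run every stage, write a
manifest and a summary.

Stage order: classification (coding filter + positional taxonomy), gene
grouping, novelty, FPKM + specificity, the DE screen, orthology (sequence +
synteny, resolution, expression clustering), candidate prioritization and
locus mapping. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotation as ann
from . import classify as cl
from . import expression as ex
from . import orthology as ortho
from . import prioritize as pri

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds for a full run."""

    # input paths
    candidates_gtf: str = ""
    reference_gtf: str = ""
    known_lnc_gtf: str = ""
    human_lnc_gtf: str = ""
    anchors: str = ""
    counts: str = ""
    gene_lengths: str = ""
    sample_sheet: str = ""
    panel: str = ""
    hits: str = ""
    assessments: str = ""
    disease_genes: str = ""
    loci_bed: str = ""
    out_dir: str = "earlinc_out"
    # thresholds
    min_length_nt: int = 200
    orf_max_aa: int = 100
    coding_score_cutoff: float = 50.0
    min_expression_fpkm: float = 0.1
    specificity_threshold: float = 1.0
    de_alpha: float = 0.05
    de_min_fold: float = 2.0
    max_distance: int = 4_000_000
    positive_r: float = 0.3
    negative_r: float = -0.3
    correlation_alpha: float = 0.05
    min_identity: float = 60.0
    max_evalue: float = 1e-5
    divergent_window_bp: int = 1000
    expression_groups_k: int = 3
    seed: int = 0

    PATH_KEYS = (
        "candidates_gtf", "reference_gtf", "known_lnc_gtf", "human_lnc_gtf",
        "anchors", "counts", "gene_lengths", "sample_sheet", "panel", "hits",
        "assessments", "disease_genes", "loci_bed",
    )


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; all errors reported at once.

    Unknown keys are rejected; defaults fill omitted keys; referenced input
    files must exist.
    """
    with Path(path).open() as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    return validate_config_dict(raw, base_dir=Path(path).parent)


def validate_config_dict(raw: dict[str, Any], base_dir: Path | None = None) -> PipelineConfig:
    errors: list[str] = []
    defaults = PipelineConfig()
    known = set(asdict(defaults))
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")
    merged = {**asdict(defaults), **{k: v for k, v in raw.items() if k in known}}

    def check_range(key: str, lo: float, hi: float) -> None:
        v = merged[key]
        if not isinstance(v, (int, float)) or not (lo <= v <= hi):
            errors.append(f"{key} must be a number in [{lo}, {hi}], got {v!r}")

    check_range("de_alpha", 0.0, 1.0)
    check_range("correlation_alpha", 0.0, 1.0)
    check_range("positive_r", -1.0, 1.0)
    check_range("negative_r", -1.0, 1.0)
    check_range("min_identity", 0.0, 100.0)
    for key in ("min_length_nt", "orf_max_aa", "max_distance", "divergent_window_bp",
                "expression_groups_k"):
        v = merged[key]
        if not isinstance(v, int) or v < 0:
            errors.append(f"{key} must be a non-negative integer, got {v!r}")
    if isinstance(merged["de_min_fold"], (int, float)) and merged["de_min_fold"] < 1:
        errors.append(f"de_min_fold must be >= 1, got {merged['de_min_fold']!r}")
    for key in PipelineConfig.PATH_KEYS:
        v = merged[key]
        if v:
            p = Path(v)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
                merged[key] = str(p)
            if not p.exists():
                errors.append(f"{key}: file not found: {p}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    cfg = PipelineConfig(**merged)
    logger.info("config: %s", json.dumps(asdict(cfg), sort_keys=True))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    out_dir: Path
    summary: dict[str, Any]
    manifest: list[dict[str, Any]] = field(default_factory=list)


def run_all(config: PipelineConfig) -> RunResult:
    """Execute every stage and write the result bundle with a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    stage = "load_annotation"
    try:
        candidates = ann.parse_gtf(config.candidates_gtf)
        reference = ann.parse_gtf(config.reference_gtf)
        coding_genes = ann.genes_from_annotation(
            [t for t in reference if t.biotype == "protein_coding"]
        )
        small_rnas = [
            t.span for t in reference if t.biotype == "small_rna"
        ]

        stage = "classify"
        assessments = (
            cl.read_assessments(config.assessments) if config.assessments else None
        )
        max_fpkm: dict[str, float] | None = None
        counts = None
        if config.counts:
            lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col=0)["length"]
            counts = ex.ExpressionMatrix.from_tsv(
                config.counts, unit="counts", gene_lengths=lengths,
                sample_sheet=config.sample_sheet or None,
            )
            fpkm = ex.compute_fpkm(counts)
            gene_max = fpkm.values.max(axis=1)
            max_fpkm = {
                t.transcript_id: float(gene_max.get(t.gene_id, 0.0)) for t in candidates
            }
        report = cl.classify_transcripts(
            candidates,
            coding_genes,
            small_rnas,
            assessments=assessments,
            max_fpkm=max_fpkm,
            min_length_nt=config.min_length_nt,
            min_expression_fpkm=config.min_expression_fpkm,
            coding_config=cl.CodingFilterConfig(
                orf_max_aa=config.orf_max_aa, score_cutoff=config.coding_score_cutoff
            ),
        )
        emit(report.to_frame(), "classification.tsv")
        summary["transcript_categories"] = report.counts()

        stage = "group_genes"
        kept = [
            t for t in candidates if not report.calls[t.transcript_id].excluded
        ]
        lnc_genes = ann.group_transcripts_into_genes(kept, gene_id_prefix="LNCG")
        gene_cat = {
            g.gene_id: cl.classify_gene(g, report.calls) for g in lnc_genes
        }
        gene_rows = pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "category": gene_cat[g.gene_id],
                    "chrom": g.chrom,
                    "start": g.span.start,
                    "end": g.span.end,
                    "strand": g.strand,
                    "transcripts": ",".join(t.transcript_id for t in g.transcripts),
                    "source_gene_ids": ",".join(sorted({t.gene_id for t in g.transcripts})),
                }
                for g in lnc_genes
            ]
        )
        emit(gene_rows, "lncrna_genes.tsv")
        cat_counts: dict[str, int] = {}
        for c in gene_cat.values():
            cat_counts[c] = cat_counts.get(c, 0) + 1
        summary["gene_categories"] = cat_counts

        stage = "novelty"
        if config.known_lnc_gtf:
            known = ann.genes_from_annotation(ann.parse_gtf(config.known_lnc_gtf))
            novelty = cl.call_novelty(lnc_genes, known)
            emit(
                pd.DataFrame(
                    sorted(novelty.flags.items()), columns=["gene_id", "novel"]
                ),
                "novelty.tsv",
            )
            summary["novelty"] = {"novel": novelty.n_novel, "known": novelty.n_known}

        stage = "expression"
        fpkm_m = None
        if counts is not None:
            fpkm_m = ex.compute_fpkm(counts)
            fpkm_m.values.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene_id")
            written.append(out / "fpkm.tsv")
            tissues = sorted({s.tissue for s in counts.samples})
            if len(tissues) == 2:
                ga = [s.sample_id for s in counts.samples if s.tissue == tissues[0]]
                gb = [s.sample_id for s in counts.samples if s.tissue == tissues[1]]
                de = ex.de_screen(
                    counts, ga, gb, alpha=config.de_alpha, min_fold=config.de_min_fold
                )
                de.reset_index().to_csv(out / "de_results.tsv", sep="\t", index=False)
                written.append(out / "de_results.tsv")
                summary["de"] = {
                    "comparison": f"{tissues[1]} vs {tissues[0]}",
                    "n_significant": int(de["significant"].sum()),
                }
        if config.panel:
            panel = ex.ExpressionMatrix.from_tsv(config.panel, unit="fpkm")
            spec_counts, frac_silent = ex.specificity_count(
                panel, threshold=config.specificity_threshold
            )
            spec_df = spec_counts.rename("n_samples_expressed").rename_axis("gene_id").reset_index()
            emit(spec_df, "specificity.tsv")
            summary["panel"] = {
                "n_samples": panel.values.shape[1],
                "fraction_silent": round(frac_silent, 4),
            }

        stage = "orthology"
        if config.human_lnc_gtf and config.anchors:
            human_lncs = ann.genes_from_annotation(ann.parse_gtf(config.human_lnc_gtf))
            anchors = ortho.read_anchor_table(config.anchors)
            candidates_o: list[ortho.OrthologPair] = []
            if config.hits:
                hits = ortho.parse_blast_hits(config.hits)
                candidates_o.extend(
                    ortho.sequence_matches(
                        hits, min_identity=config.min_identity,
                        max_evalue=config.max_evalue,
                    )
                )
            # synteny uses source gene ids (the annotation's own ids)
            source_genes = ann.genes_from_annotation(kept)
            candidates_o.extend(
                ortho.synteny_matches_all(source_genes, human_lncs, anchors)
            )
            resolved = ortho.resolve_orthologs(candidates_o)
            emit(ortho.pairs_to_frame(resolved), "orthologs.tsv")
            evid_counts: dict[str, int] = {}
            for p in ortho.merge_candidates(candidates_o):
                key = "+".join(sorted(p.evidence))
                evid_counts[key] = evid_counts.get(key, 0) + 1
            summary["orthology"] = {
                "candidates_by_evidence": evid_counts,
                "n_resolved": len(resolved),
            }

        stage = "prioritize"
        if config.disease_genes:
            disease_df = pd.read_csv(config.disease_genes, sep="\t")
            disease_ids = set(disease_df["gene_id"])
            disease_models = [
                g
                for g in ann.genes_from_annotation(reference)
                if g.gene_id in disease_ids
            ]
            source_genes = ann.genes_from_annotation(kept)
            records = pri.candidates_near_genes(
                source_genes, disease_models,
                max_distance=config.max_distance,
                divergent_window_bp=config.divergent_window_bp,
            )
            if fpkm_m is not None:
                records = pri.correlation_screen(
                    records, fpkm_m,
                    positive_r=config.positive_r,
                    negative_r=config.negative_r,
                    alpha=config.correlation_alpha,
                )
            emit(pri.records_to_frame(records), "candidates.tsv")
            calls: dict[str, int] = {}
            for r in records:
                calls[r.correlation_call] = calls.get(r.correlation_call, 0) + 1
            summary["candidates"] = {"n_records": len(records), "correlation_calls": calls}

        stage = "map_loci"
        if config.loci_bed and config.anchors:
            anchors = ortho.read_anchor_table(config.anchors)
            source_genes = ann.genes_from_annotation(kept)
            loci_rows = []
            mapped_rows = []
            with Path(config.loci_bed).open() as fh:
                for line in fh:
                    fields = line.rstrip("\n").split("\t")
                    if len(fields) < 4:
                        continue
                    locus = pri.DiseaseLocus(
                        locus_id=fields[3],
                        human_interval=ann.GenomicInterval(
                            fields[0], int(fields[1]), int(fields[2])
                        ),
                    )
                    mapped, overlapping = pri.map_locus_and_intersect(
                        locus, anchors, source_genes
                    )
                    mi = mapped.mouse_interval
                    mapped_rows.append(
                        f"{mi.chrom}\t{mi.start}\t{mi.end}\t{mapped.locus_id}\t0\t.\n"
                    )
                    loci_rows.append(
                        {
                            "locus_id": mapped.locus_id,
                            "mouse_chrom": mi.chrom,
                            "mouse_start": mi.start,
                            "mouse_end": mi.end,
                            "split": mapped.split,
                            "n_lncrna_genes": len(overlapping),
                            "lncrna_genes": ",".join(g.gene_id for g in overlapping),
                        }
                    )
            (out / "mapped_loci.bed").write_text("".join(mapped_rows))
            written.append(out / "mapped_loci.bed")
            emit(pd.DataFrame(loci_rows), "locus_intersections.tsv")
            summary["loci"] = {
                "n_loci": len(loci_rows),
                "n_genes_in_loci": int(
                    sum(r["n_lncrna_genes"] for r in loci_rows)
                ),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = [
        {"file": p.name, "rows": sum(1 for _ in p.open()), "sha256": _sha256(p)}
        for p in written
    ]
    result = RunResult(out_dir=out, summary=summary, manifest=manifest)
    with (out / "summary.json").open("w") as fh:
        json.dump({"summary": summary, "manifest": manifest}, fh, indent=1, sort_keys=True)
    return result
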