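"""Prioritize lncRNAs near deafness genes and map human loci to mouse.

Generates the synthetic study, searches for lncRNA genes within 4 Mb of
the planted disease genes, labels each pair's positional relationship,
screens the pairs for expression correlation across the 12 inner-ear
samples (positive call: R > 0.3 and P < 0.05), and finally maps a human
deafness locus into mouse coordinates via the anchor blocks and lists the
lncRNA genes it contains.
"""

from earlinc.annotation import GenomicInterval, genes_from_annotation
from earlinc.expression import compute_fpkm
from earlinc.prioritize import (
    DiseaseLocus,
    candidates_near_genes,
    correlation_screen,
    map_locus_and_intersect,
)
from earlinc.simulate import (
    GeneratorConfig,
    generate_annotation,
    generate_counts,
    generate_disease_annotation,
)

cfg = GeneratorConfig(seed=0)
annot = generate_annotation(cfg)
counts = generate_counts(annot, cfg)
fpkm = compute_fpkm(counts)
disease_df, loci = generate_disease_annotation(annot, cfg)

lnc_genes = [g for g in annot.candidate_genes if g.gene_id in annot.truth.gene_classes]
disease_ids = set(disease_df["gene_id"])
disease_genes = [g for g in annot.coding_genes if g.gene_id in disease_ids]

records = candidates_near_genes(lnc_genes, disease_genes, max_distance=4_000_000)
records = correlation_screen(records, fpkm)

calls = {}
for r in records:
    calls[r.correlation_call] = calls.get(r.correlation_call, 0) + 1
print(f"{len(records)} lncRNA x disease-gene pairs within 4 Mb")
print("correlation calls:", dict(sorted(calls.items())))

planted = set(annot.truth.cis_pairs)
pos_pairs = {
    (r.lncrna_gene, r.disease_gene) for r in records if r.correlation_call == "positive"
}
print(f"planted cis-regulatory pairs called positive: "
      f"{len(pos_pairs & planted)}/{len(planted)}")

print("\nclosest five candidates:")
for r in records[:5]:
    R = f"{r.correlation_R:+.2f}" if r.correlation_R is not None else "  NA"
    print(f"  {r.lncrna_gene} ~ {r.disease_gene}: {r.relationship:10s} "
          f"{r.distance_bp:>9,} bp  R={R} ({r.correlation_call})")

locus_id, human_iv = loci[0]
locus = DiseaseLocus(locus_id, human_iv)
mapped, overlapping = map_locus_and_intersect(locus, annot.anchors, lnc_genes)
mi = mapped.mouse_interval
print(f"\nhuman locus {locus_id} {human_iv.chrom}:{human_iv.start}-{human_iv.end}"
      f" maps to {mi.chrom}:{mi.start}-{mi.end}")
print(f"lncRNA genes inside the mapped interval: "
      f"{', '.join(g.gene_id for g in overlapping)}")
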