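"""Cross-species orthology: sequence hits + synteny, 1:1 resolution,
expression grouping.

Generates a mouse/human pair of genomes where a subset of mouse lincRNAs
has planted human counterparts (some recognizable by sequence similarity,
some only by conserved gene neighborhood), resolves the candidates to a 1:1
set, and clusters the resolved pairs into three expression groups.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from earlinc.expression import ExpressionMatrix
from earlinc.orthology import (
    cluster_ortholog_expression,
    parse_blast_hits,
    resolve_orthologs,
    sequence_matches,
    synteny_matches_all,
)
from earlinc.simulate import (
    GeneratorConfig,
    generate_annotation,
    generate_similarity_hits,
    shuffle_anchor_order,
)

cfg = GeneratorConfig(seed=0)
annot = generate_annotation(cfg)

with tempfile.TemporaryDirectory() as td:
    hits_path = Path(td) / "hits.tsv"
    generate_similarity_hits(annot, cfg).to_csv(
        hits_path, sep="\t", index=False, header=False
    )
    seq_pairs = sequence_matches(parse_blast_hits(hits_path))

# only transcripts that survive the filtering cascade enter orthology
lnc_genes = [g for g in annot.candidate_genes if g.gene_id in annot.truth.gene_classes]
syn_pairs = synteny_matches_all(lnc_genes, annot.human_lnc_genes, annot.anchors)
resolved = resolve_orthologs(list(seq_pairs) + syn_pairs)

by_ev = {}
for p in resolved:
    key = "+".join(sorted(p.evidence))
    by_ev[key] = by_ev.get(key, 0) + 1
print(f"resolved 1:1 ortholog pairs: {len(resolved)}")
for ev, n in sorted(by_ev.items()):
    print(f"  evidence {ev:18s} {n}")

planted = {(m, h) for m, h, _ in annot.truth.ortholog_pairs}
got = {(p.mouse_gene, p.human_gene) for p in resolved}
print(f"planted pairs recovered: {len(got & planted)}/{len(planted)}")

# breaking conserved gene order removes every synteny call
shuffled = shuffle_anchor_order(annot.anchors, seed=1)
broken = synteny_matches_all(lnc_genes, annot.human_lnc_genes, shuffled)
print(f"synteny candidates after shuffling human anchor order: {len(broken)}")

# cluster resolved pairs into 3 groups by joint expression level
rng = np.random.default_rng(2)
levels = {1: 40.0, 2: 40.0, 3: 0.5}       # mouse side
hlevels = {1: 40.0, 2: 0.5, 3: 0.5}       # human side
mouse_rows, human_rows = {}, {}
for i, p in enumerate(resolved):
    arch = i % 3 + 1
    mouse_rows[p.mouse_gene] = levels[arch] * rng.uniform(0.8, 1.2, 12)
    human_rows[p.human_gene] = hlevels[arch] * rng.uniform(0.8, 1.2, 6)
mouse_expr = ExpressionMatrix(
    values=pd.DataFrame(mouse_rows).T.set_axis([f"m{s}" for s in range(12)], axis=1),
    unit="fpkm",
)
human_expr = ExpressionMatrix(
    values=pd.DataFrame(human_rows).T.set_axis([f"h{s}" for s in range(6)], axis=1),
    unit="fpkm",
)
grouped, _ = cluster_ortholog_expression(resolved, mouse_expr, human_expr, k=3)
sizes = {}
for p in grouped:
    sizes[p.expression_group] = sizes.get(p.expression_group, 0) + 1
print("expression groups (1 = high in human):",
      ", ".join(f"group {g}: {n}" for g, n in sorted(sizes.items())))
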