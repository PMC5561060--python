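"""Classify a tiny assembled transcriptome into the lncRNA taxonomy.

Builds a synthetic study (one mouse chromosome with planted lincRNAs,
antisense transcripts, small-RNA hosts and exclusion classes), runs the
filtering cascade, and prints the category counts — the same taxonomy a
real discovery run reports (intergenic lincRNAs, antisense lncRNAs,
small-RNA hosts, and the excluded classes).
"""

from earlinc.classify import CodingAssessment, classify_transcripts
from earlinc.simulate import (
    GeneratorConfig,
    generate_annotation,
    generate_coding_assessments,
)

cfg = GeneratorConfig(seed=0)
annot = generate_annotation(cfg)

# coding-potential evidence (ORF length, homology, external score) enters as
# a precomputed per-transcript table, exactly as a real run would consume it
assessments = {
    r.transcript_id: CodingAssessment(
        r.transcript_id, int(r.longest_orf_aa),
        float(r.external_coding_score), bool(r.homology_hit),
    )
    for r in generate_coding_assessments(annot, cfg).itertuples(index=False)
}

report = classify_transcripts(
    annot.candidates, annot.coding_genes, annot.small_rnas, assessments=assessments
)

print(f"{len(annot.candidates)} candidate transcripts classified:")
for category, count in sorted(report.counts().items()):
    print(f"  {category:32s} {count}")

errors = sum(
    report.calls[tid].category != cat
    for tid, cat in annot.truth.transcript_classes.items()
)
print(f"\nmismatches against the planted ground truth: {errors}")
# Each count is the number of transcripts assigned to that category; with the
# generator's unambiguous geometry every planted label is recovered exactly.
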