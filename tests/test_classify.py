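"""Filtering cascade and positional taxonomy, checked against brute force."""

from __future__ import annotations

import re

import numpy as np
import pytest

from earlinc.annotation import GeneModel, GenomicInterval, TranscriptModel
from earlinc.classify import (
    CodingAssessment,
    CodingFilterConfig,
    LncRNAClassification,
    call_novelty,
    classify_gene,
    classify_lncrna,
    classify_transcripts,
    coding_filter,
    find_orfs,
)
from earlinc.simulate import (
    random_noncoding_sequence,
    sequence_with_orf,
)

from conftest import exon_base_set, random_transcript


def orf_oracle(seq: str) -> int:
    """Regex scan over the three sense frames; the independent ORF oracle."""
    best = 0
    seq = seq.upper()
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        s = " ".join(codons)
        for m in re.finditer(r"ATG(?: \S{3})*? (?:TAA|TAG|TGA)", s):
            best = max(best, m.group(0).count(" "))  # codons incl. stop, minus 1
    return best


class TestFindOrfs:
    def test_single_codon_orf(self):
        assert find_orfs("ATGTAA") == 1

    def test_no_start_codon(self):
        assert find_orfs("CCCCCCTAACCC") == 0

    def test_start_without_stop_is_not_an_orf(self):
        assert find_orfs("ATGAAAAAAAAA") == 0

    def test_illegal_character(self):
        with pytest.raises(ValueError, match="illegal"):
            find_orfs("ATGXTAA")

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for i in range(200):
            n = int(rng.integers(30, 1000))
            seq = "".join(rng.choice(list("ACGT"), n))
            assert find_orfs(seq) == orf_oracle(seq), seq

    def test_planted_orf_lengths_recovered(self):
        rng = np.random.default_rng(18)
        for codons in (5, 30, 99, 100, 150):
            seq = sequence_with_orf(rng, codons)
            assert find_orfs(seq) >= codons
            assert orf_oracle(seq) == find_orfs(seq)

    def test_noncoding_generator_sequences_stay_short(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            assert find_orfs(random_noncoding_sequence(rng, 900)) < 100


class TestCodingFilter:
    TX = TranscriptModel("t1", "g1", (GenomicInterval("chr1", 0, 500, "+"),))

    def test_long_orf_drops(self):
        decision, reason = coding_filter(
            self.TX, CodingAssessment("t1", longest_orf_aa=150)
        )
        assert decision == "drop" and "ORF" in reason

    def test_clean_assessment_keeps(self):
        decision, _ = coding_filter(
            self.TX, CodingAssessment("t1", longest_orf_aa=40, external_coding_score=10.0)
        )
        assert decision == "keep"

    def test_missing_assessment_never_silently_kept(self):
        decision, _ = coding_filter(self.TX, None)
        assert decision == "needs_assessment"
        decision, _ = coding_filter(self.TX, CodingAssessment("t1", longest_orf_aa=None))
        assert decision == "needs_assessment"

    def test_matches_truth_table(self):
        rng = np.random.default_rng(23)
        cfg = CodingFilterConfig(orf_max_aa=100, score_cutoff=50.0)
        for _ in range(300):
            orf = int(rng.integers(0, 200))
            score = float(rng.uniform(0, 100))
            hom = bool(rng.random() < 0.3)
            decision, _ = coding_filter(
                self.TX, CodingAssessment("t1", orf, score, hom), cfg
            )
            expected = "drop" if (orf >= 100 or hom or score >= 50.0) else "keep"
            assert decision == expected


def brute_force_classify(t, coding_genes, small_rnas, min_length_nt=200):
    """Per-base reimplementation of the positional decision order."""
    if t.mature_length <= min_length_nt:
        return "excluded_short"
    tb = exon_base_set(t)
    for g in coding_genes:
        for ct in g.transcripts:
            if (
                ct.chrom == t.chrom
                and t.strand in "+-"
                and ct.strand in "+-"
                and ct.strand != t.strand
                and tb & exon_base_set(ct)
            ):
                return "antisense"
    for g in coding_genes:
        if g.chrom != t.chrom or t.strand == "." or g.strand != t.strand:
            continue
        span_bases = set(range(g.span.start, g.span.end))
        g_exon_bases = {b for ct in g.transcripts for b in exon_base_set(ct)}
        if tb <= span_bases and not (tb & g_exon_bases):
            return "excluded_intronic_same_strand"
    for s in small_rnas:
        if (
            s.chrom == t.chrom
            and t.span.start <= s.start
            and s.end <= t.span.end
        ):
            return "small_rna_host"
    return "lincRNA"


class TestClassifyLncrna:
    def _coding_gene(self, gid, start, strand="+", chrom="chr1"):
        exons = (
            GenomicInterval(chrom, start, start + 300, strand),
            GenomicInterval(chrom, start + 1000, start + 1300, strand),
        )
        return GeneModel(gid, (TranscriptModel(f"{gid}_t", gid, exons, "protein_coding"),))

    def test_short_transcript_excluded(self):
        t = TranscriptModel("t", "g", (GenomicInterval("chr1", 0, 150, "+"),))
        assert classify_lncrna(t, []).category == "excluded_short"
        # exactly 200 nt does not pass the > 200 nt floor
        t200 = TranscriptModel("t", "g", (GenomicInterval("chr1", 0, 200, "+"),))
        assert classify_lncrna(t200, []).category == "excluded_short"

    def test_low_expression_excluded(self):
        t = TranscriptModel("t", "g", (GenomicInterval("chr1", 0, 500, "+"),))
        call = classify_lncrna(t, [], max_fpkm=0.05, min_expression_fpkm=0.1)
        assert call.category == "excluded_low_expression"

    def test_antisense_by_opposite_strand_exonic_overlap(self):
        g = self._coding_gene("cg", 1000, "+")
        t = TranscriptModel("t", "g", (GenomicInterval("chr1", 1100, 1500, "-"),))
        assert classify_lncrna(t, [g]).category == "antisense"

    def test_intron_contained_same_strand_excluded(self):
        g = self._coding_gene("cg", 1000, "+")
        t = TranscriptModel("t", "g", (GenomicInterval("chr1", 1400, 1900, "+"),))
        assert classify_lncrna(t, [g]).category == "excluded_intronic_same_strand"

    def test_small_rna_host(self):
        t = TranscriptModel(
            "t", "g",
            (GenomicInterval("chr1", 0, 300, "+"), GenomicInterval("chr1", 1000, 1300, "+")),
        )
        srna = GenomicInterval("chr1", 500, 580, "+")
        assert classify_lncrna(t, [], [srna]).category == "small_rna_host"

    def test_short_beats_any_overlap(self):
        # decision-order property: length floor wins regardless of context
        g = self._coding_gene("cg", 1000, "+")
        t = TranscriptModel("t", "g", (GenomicInterval("chr1", 1100, 1250, "-"),))
        assert classify_lncrna(t, [g]).category == "excluded_short"

    def test_matches_per_base_oracle_adversarial(self):
        rng = np.random.default_rng(29)
        coding_genes = []
        for i in range(12):
            start = int(rng.integers(0, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            coding_genes.append(self._coding_gene(f"cg{i}", start, strand))
        small_rnas = [
            GenomicInterval("chr1", int(s), int(s) + 60)
            for s in rng.integers(0, 9000, 15)
        ]
        for i in range(500):
            t = random_transcript(rng, f"t{i}", max_start=9000, exon_len=(40, 500),
                                  intron_len=(10, 600))
            got = classify_lncrna(t, coding_genes, small_rnas).category
            want = brute_force_classify(t, coding_genes, small_rnas)
            assert got == want, (t, got, want)

    def test_translation_invariance(self):
        rng = np.random.default_rng(31)
        g = self._coding_gene("cg", 2000, "+")
        ts = [random_transcript(rng, f"t{i}", max_start=4000) for i in range(50)]
        shift = 12_345
        g2 = GeneModel(
            "cg",
            (TranscriptModel("cg_t", "cg",
                             tuple(e.shifted(shift) for e in g.transcripts[0].exons),
                             "protein_coding"),),
        )
        for t in ts:
            t2 = TranscriptModel(t.transcript_id, t.gene_id,
                                 tuple(e.shifted(shift) for e in t.exons))
            assert classify_lncrna(t, [g]).category == classify_lncrna(t2, [g2]).category


class TestClassifyGene:
    def _gene_with_calls(self, cats):
        ts = tuple(
            TranscriptModel(f"t{i}", "g", (GenomicInterval("chr1", i * 1000, i * 1000 + 500, "+"),))
            for i in range(len(cats))
        )
        g = GeneModel("g", ts)
        calls = {
            f"t{i}": LncRNAClassification(f"t{i}", c) for i, c in enumerate(cats)
        }
        return g, calls

    @pytest.mark.parametrize(
        "cats,expected",
        [
            (["lincRNA", "antisense"], "antisense"),
            (["lincRNA", "small_rna_host", "antisense"], "small_rna_host"),
            (["excluded_short", "excluded_coding"], "excluded"),
            (["lincRNA"], "lincRNA"),
            (["excluded_short", "lincRNA"], "lincRNA"),
        ],
    )
    def test_precedence(self, cats, expected):
        g, calls = self._gene_with_calls(cats)
        assert classify_gene(g, calls) == expected

    def test_random_mixtures_match_precedence_oracle(self):
        rng = np.random.default_rng(37)
        from earlinc.classify import CATEGORIES
        for _ in range(200):
            k = int(rng.integers(1, 6))
            cats = [CATEGORIES[int(c)] for c in rng.integers(0, len(CATEGORIES), k)]
            g, calls = self._gene_with_calls(cats)
            order = ["small_rna_host", "antisense", "lincRNA"]
            expected = next((c for c in order if c in cats), "excluded")
            assert classify_gene(g, calls) == expected


class TestNovelty:
    def _gene(self, gid, start, end, chrom="chr1", strand="+"):
        return GeneModel(gid, (TranscriptModel(f"{gid}_t", gid,
                                               (GenomicInterval(chrom, start, end, strand),)),))

    def test_exon_overlap_means_known(self):
        q = self._gene("q", 100, 600)
        r = self._gene("r", 400, 900)
        res = call_novelty([q], [r])
        assert res.flags == {"q": False}

    def test_unmatched_chromosome_is_novel_with_warning(self):
        q = self._gene("q", 100, 600, chrom="chrUn")
        r = self._gene("r", 100, 600)
        res = call_novelty([q], [r])
        assert res.flags == {"q": True}
        assert res.unmatched_chroms == ("chrUn",)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(41)
        qs = [GeneModel(f"q{i}", (random_transcript(rng, f"q{i}", max_start=6000),))
              for i in range(100)]
        rs = [GeneModel(f"r{i}", (random_transcript(rng, f"r{i}", max_start=6000),))
              for i in range(40)]
        res = call_novelty(qs, rs)
        for q in qs:
            qb = exon_base_set(q.transcripts[0])
            overlap = any(qb & exon_base_set(r.transcripts[0]) for r in rs)
            assert res.flags[q.gene_id] == (not overlap)
        assert res.n_novel + res.n_known == len(qs)


class TestCascadeConservation:
    def test_every_transcript_gets_one_category(self):
        rng = np.random.default_rng(43)
        ts = [random_transcript(rng, f"t{i}", max_start=20_000) for i in range(150)]
        assessments = {
            t.transcript_id: CodingAssessment(t.transcript_id, int(rng.integers(0, 150)))
            for t in ts
            if rng.random() > 0.1  # some missing on purpose
        }
        report = classify_transcripts(ts, [], assessments=assessments)
        assert len(report.calls) == len(ts)
        assert sum(report.counts().values()) == len(ts)
        for tid in report.needs_assessment:
            assert report.calls[tid].category == "excluded_coding"
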