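"""Sequence/synteny evidence, 1:1 resolution vs an exhaustive matching
oracle, and expression-group clustering."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from earlinc.annotation import GeneModel, GenomicInterval, TranscriptModel
from earlinc.expression import ExpressionMatrix
from earlinc.orthology import (
    AnchorBlock,
    OrthologPair,
    SimilarityHit,
    _rank_key,
    cluster_ortholog_expression,
    merge_candidates,
    parse_blast_hits,
    resolve_orthologs,
    sequence_matches,
    synteny_matches,
)
from earlinc.simulate import GeneratorConfig, generate_annotation, shuffle_anchor_order


def hit(q, s, ident=90.0, evalue=1e-20, bits=100.0):
    return SimilarityHit(q, s, ident, 200, evalue, bits)


def gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, (TranscriptModel(f"{gid}_t", gid,
                                           (GenomicInterval(chrom, start, end, strand),)),))


class TestSequenceMatches:
    def test_empty_table(self):
        assert sequence_matches([]) == []

    def test_best_bit_score_kept_per_pair(self):
        pairs = sequence_matches([hit("m1", "h1", bits=50), hit("m1", "h1", bits=80)])
        assert len(pairs) == 1 and pairs[0].similarity_score == 80

    def test_threshold_filter_matches_oracle(self):
        rng = np.random.default_rng(1)
        hits = []
        expected = set()
        for i in range(200):
            ident = float(rng.uniform(30, 100))
            ev = float(10.0 ** rng.uniform(-30, 1))
            h = hit(f"m{i % 20}", f"h{i % 15}", ident=ident, evalue=ev)
            hits.append(h)
            if ident >= 60.0 and ev <= 1e-5:
                expected.add((h.query_id, h.subject_id))
        got = {(p.mouse_gene, p.human_gene) for p in sequence_matches(hits)}
        assert got == expected

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("m1\th1\t90\t200\t1\t200\t1\t200\t1\t200\t1e-20\n")  # 11 cols
        with pytest.raises(ValueError, match=":1"):
            parse_blast_hits(path)


def anchor(mg, hg, m_start, h_start, length=1000, orientation="same",
           m_chrom="chr1", h_chrom="hchr1"):
    return AnchorBlock(
        GenomicInterval(m_chrom, m_start, m_start + length),
        GenomicInterval(h_chrom, h_start, h_start + length),
        mg, hg, orientation,
    )


class TestSyntenyMatches:
    def test_planted_pair_score_one(self):
        anchors = [anchor("A", "hA", 0, 0), anchor("B", "hB", 10_000, 10_000)]
        lnc = gene("L", "chr1", 4000, 5000)
        hlnc = gene("hL", "hchr1", 4200, 5200)
        pairs = synteny_matches(lnc, [hlnc], anchors)
        assert [(p.mouse_gene, p.human_gene, p.synteny_score) for p in pairs] == [
            ("L", "hL", 1.0)
        ]

    def test_two_human_lncs_share_lower_score(self):
        anchors = [anchor("A", "hA", 0, 0), anchor("B", "hB", 10_000, 10_000)]
        lnc = gene("L", "chr1", 4000, 5000)
        hs = [gene("hL1", "hchr1", 2000, 2500), gene("hL2", "hchr1", 6000, 6500)]
        pairs = synteny_matches(lnc, hs, anchors)
        assert {p.synteny_score for p in pairs} == {0.5}

    def test_inverted_block_pair_still_found(self):
        # human order reversed, both anchors inverted: reflection is consistent
        anchors = [
            anchor("A", "hA", 0, 20_000, orientation="inverted"),
            anchor("B", "hB", 10_000, 0, orientation="inverted"),
        ]
        lnc = gene("L", "chr1", 4000, 5000)
        hlnc = gene("hL", "hchr1", 5000, 6000)
        pairs = synteny_matches(lnc, [hlnc], anchors)
        assert [(p.mouse_gene, p.human_gene) for p in pairs] == [("L", "hL")]

    def test_inconsistent_order_rejected(self):
        # same orientation but human order flipped: synteny broken
        anchors = [anchor("A", "hA", 0, 20_000), anchor("B", "hB", 10_000, 0)]
        lnc = gene("L", "chr1", 4000, 5000)
        hlnc = gene("hL", "hchr1", 5000, 6000)
        assert synteny_matches(lnc, [hlnc], anchors) == []

    def test_intervening_anchor_breaks_synteny(self):
        anchors = [
            anchor("A", "hA", 0, 0),
            anchor("B", "hB", 10_000, 30_000),
            anchor("C", "hC", 50_000, 15_000),  # human position between hA and hB
        ]
        lnc = gene("L", "chr1", 4000, 5000)
        hlnc = gene("hL", "hchr1", 5000, 6000)
        assert synteny_matches(lnc, [hlnc], anchors) == []

    def test_missing_flank_returns_empty(self):
        anchors = [anchor("A", "hA", 0, 0)]
        lnc = gene("L", "chr1", 4000, 5000)
        assert synteny_matches(lnc, [gene("hL", "hchr1", 5000, 6000)], anchors) == []

    def test_planted_universe_recovered_and_shuffle_destroys(self, synthetic_study):
        cfg, annot = synthetic_study
        truth_syn = {
            (m, h) for m, h, ev in annot.truth.ortholog_pairs if "synteny" in ev
        }
        found = set()
        by_gid = {g.gene_id: g for g in annot.candidate_genes}
        for m, h, ev in annot.truth.ortholog_pairs:
            for p in synteny_matches(by_gid[m], annot.human_lnc_genes, annot.anchors):
                found.add((p.mouse_gene, p.human_gene))
        assert found == truth_syn
        shuffled = shuffle_anchor_order(annot.anchors, seed=3)
        for m, h, ev in annot.truth.ortholog_pairs:
            assert synteny_matches(by_gid[m], annot.human_lnc_genes, shuffled) == []


class TestResolve:
    def test_greedy_prefers_higher_score(self):
        cands = [
            OrthologPair("m1", "h1", frozenset({"sequence"}), similarity_score=80),
            OrthologPair("m1", "h2", frozenset({"sequence"}), similarity_score=50),
        ]
        out = resolve_orthologs(cands)
        assert [(p.mouse_gene, p.human_gene) for p in out] == [("m1", "h1")]

    def test_tied_block_resolved_by_id(self):
        cands = [
            OrthologPair(m, h, frozenset({"sequence"}), similarity_score=60)
            for m in ("m1", "m2")
            for h in ("h1", "h2")
        ]
        out = resolve_orthologs(cands)
        assert [(p.mouse_gene, p.human_gene) for p in out] == [("m1", "h1"), ("m2", "h2")]

    def test_evidence_union_and_count_conservation(self):
        cands = [
            OrthologPair("m1", "h1", frozenset({"sequence"}), similarity_score=80),
            OrthologPair("m1", "h1", frozenset({"synteny"}), synteny_score=1.0),
            OrthologPair("m2", "h2", frozenset({"synteny"}), synteny_score=0.5),
        ]
        merged = merge_candidates(cands)
        assert len(merged) == 2
        both = next(p for p in merged if p.mouse_gene == "m1")
        assert both.evidence == {"sequence", "synteny"}
        assert both.similarity_score == 80 and both.synteny_score == 1.0

    def test_output_is_matching(self):
        rng = np.random.default_rng(4)
        cands = [
            OrthologPair(f"m{int(rng.integers(0, 10))}", f"h{int(rng.integers(0, 10))}",
                         frozenset({"sequence"}), similarity_score=float(rng.uniform(0, 100)))
            for _ in range(60)
        ]
        out = resolve_orthologs(cands)
        assert len({p.mouse_gene for p in out}) == len(out)
        assert len({p.human_gene for p in out}) == len(out)

    @staticmethod
    def _oracle(merged):
        """Rank-lexicographically minimal maximal matching, by enumeration."""
        ranked = sorted(merged, key=_rank_key)

        def matchings(avail, used_m, used_h):
            found_any = False
            for i, p in enumerate(avail):
                if p.mouse_gene in used_m or p.human_gene in used_h:
                    continue
                found_any = True
                for rest in matchings(
                    avail[i + 1 :], used_m | {p.mouse_gene}, used_h | {p.human_gene}
                ):
                    yield [p] + rest
            if not found_any:
                yield []

        best = None
        for m in matchings(ranked, set(), set()):
            key = tuple(ranked.index(p) for p in m)
            if best is None or key < best[0]:
                best = (key, m)
        return best[1]

    def test_matches_exhaustive_oracle_small_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(25):
            n_m, n_h = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            cands = []
            for _ in range(int(rng.integers(3, 12))):
                ev = [frozenset({"sequence"}), frozenset({"synteny"}),
                      frozenset({"sequence", "synteny"})][int(rng.integers(0, 3))]
                cands.append(
                    OrthologPair(
                        f"m{int(rng.integers(0, n_m))}",
                        f"h{int(rng.integers(0, n_h))}",
                        ev,
                        similarity_score=(
                            float(rng.integers(0, 5)) if "sequence" in ev else None
                        ),
                        synteny_score=(
                            float(rng.integers(1, 4)) / 4 if "synteny" in ev else None
                        ),
                    )
                )
            merged = merge_candidates(cands)
            got = resolve_orthologs(cands)
            want = self._oracle(merged)
            assert [(p.mouse_gene, p.human_gene) for p in got] == [
                (p.mouse_gene, p.human_gene) for p in want
            ]


class TestExpressionClustering:
    def _matrices(self, pairs, profiles_m, profiles_h):
        midx = [p.mouse_gene for p in pairs]
        hidx = [p.human_gene for p in pairs]
        m = ExpressionMatrix(
            values=pd.DataFrame(profiles_m, index=midx,
                                columns=[f"ms{j}" for j in range(profiles_m.shape[1])]),
            unit="fpkm",
        )
        h = ExpressionMatrix(
            values=pd.DataFrame(profiles_h, index=hidx,
                                columns=[f"hs{j}" for j in range(profiles_h.shape[1])]),
            unit="fpkm",
        )
        return m, h

    def _planted(self, rng, n_per=10):
        # archetypes: high-high, high-mouse-only, low-low
        pairs, pm, ph, labels = [], [], [], []
        arch_m = [50.0, 50.0, 0.5]
        arch_h = [50.0, 0.5, 0.5]
        shapes = rng.uniform(0.5, 2.0, size=12)
        for a in range(3):
            for i in range(n_per):
                pairs.append(
                    OrthologPair(f"m_{a}_{i}", f"h_{a}_{i}", frozenset({"synteny"}))
                )
                pm.append(arch_m[a] * shapes * rng.uniform(0.9, 1.1, 12))
                ph.append(arch_h[a] * shapes[:6] * rng.uniform(0.9, 1.1, 6))
                labels.append(a + 1)
        return pairs, np.array(pm), np.array(ph), labels

    def test_planted_archetypes_recovered_and_ordered(self):
        rng = np.random.default_rng(6)
        pairs, pm, ph, labels = self._planted(rng)
        m, h = self._matrices(pairs, pm, ph)
        grouped, excluded = cluster_ortholog_expression(pairs, m, h, k=3)
        assert excluded == []
        got = {p.mouse_gene: p.expression_group for p in grouped}
        # group 1 must be the high-in-human archetype
        for p, lab in zip(pairs, labels):
            if lab == 1:
                assert got[p.mouse_gene] == 1
        # archetypes map 1:1 onto groups
        mapping = {}
        for p, lab in zip(pairs, labels):
            mapping.setdefault(lab, set()).add(got[p.mouse_gene])
        assert all(len(v) == 1 for v in mapping.values())
        assert set.union(*mapping.values()) == {1, 2, 3}

    def test_k_one_single_group(self):
        rng = np.random.default_rng(7)
        pairs, pm, ph, _ = self._planted(rng, n_per=4)
        m, h = self._matrices(pairs, pm, ph)
        grouped, _ = cluster_ortholog_expression(pairs, m, h, k=1)
        assert {p.expression_group for p in grouped} == {1}

    def test_duplicated_vectors_same_label_and_order_invariance(self):
        rng = np.random.default_rng(8)
        pairs, pm, ph, _ = self._planted(rng, n_per=5)
        m, h = self._matrices(pairs, pm, ph)
        g1, _ = cluster_ortholog_expression(pairs, m, h, k=3)
        perm = list(rng.permutation(len(pairs)))
        g2, _ = cluster_ortholog_expression([pairs[i] for i in perm], m, h, k=3)
        l1 = {p.mouse_gene: p.expression_group for p in g1}
        l2 = {p.mouse_gene: p.expression_group for p in g2}
        assert l1 == l2

    def test_missing_expression_reported(self):
        pairs = [
            OrthologPair("m1", "h1", frozenset({"synteny"})),
            OrthologPair("m2", "h_absent", frozenset({"synteny"})),
        ]
        rng = np.random.default_rng(9)
        m, h = self._matrices(
            [pairs[0]], rng.uniform(1, 10, (1, 12)), rng.uniform(1, 10, (1, 6))
        )
        grouped, excluded = cluster_ortholog_expression(pairs, m, h, k=1)
        assert [p.mouse_gene for p in excluded] == ["m2"]
        assert [p.mouse_gene for p in grouped] == ["m1"]
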