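from __future__ import annotations

import numpy as np
import pytest

from earlinc.annotation import GenomicInterval, TranscriptModel
from earlinc.simulate import GeneratorConfig, generate_annotation


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    chrom: str = "chr1",
    max_start: int = 50_000,
    strand: str | None = None,
    n_exons: tuple[int, int] = (1, 4),
    exon_len: tuple[int, int] = (50, 400),
    intron_len: tuple[int, int] = (30, 800),
) -> TranscriptModel:
    """Random valid transcript for oracle-equivalence tests."""
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, max_start))
    k = int(rng.integers(n_exons[0], n_exons[1] + 1))
    exons = []
    for i in range(k):
        length = int(rng.integers(exon_len[0], exon_len[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(intron_len[0], intron_len[1] + 1))
    return TranscriptModel(tid, f"g_{tid}", tuple(exons))


def exon_base_set(t: TranscriptModel) -> set[int]:
    return {b for e in t.exons for b in range(e.start, e.end)}


@pytest.fixture(scope="session")
def synthetic_study():
    """One default synthetic study shared across tests (seed fixed)."""
    cfg = GeneratorConfig(seed=7)
    return cfg, generate_annotation(cfg)
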