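"""Shared fixtures: tiny hand-built transcript models and simulated datasets."""

import numpy as np
import pytest

from riboflow.ranges import (
    Annotation,
    GenomicInterval,
    ReadTable,
    SplicedRange,
    TranscriptModel,
)
from riboflow.simulate import make_genome, simulate_riboseq


@pytest.fixture
def two_exon_plus():
    """'+' transcript: exons [100,110)+[150,160), CDS at tx [4,16)."""
    exons = SplicedRange(
        (
            GenomicInterval("chr1", 100, 110, "+"),
            GenomicInterval("chr1", 150, 160, "+"),
        )
    )
    return TranscriptModel("txp", "gp", exons, cds=(4, 16))


@pytest.fixture
def two_exon_minus():
    """'-' transcript: exons [150,160)+[100,110) in tx order, CDS at tx [4,16)."""
    exons = SplicedRange(
        (
            GenomicInterval("chr1", 150, 160, "-"),
            GenomicInterval("chr1", 100, 110, "-"),
        )
    )
    return TranscriptModel("txm", "gm", exons, cds=(4, 16))


@pytest.fixture
def tiny_annotation(two_exon_plus, two_exon_minus):
    return Annotation(
        {"txp": two_exon_plus, "txm": two_exon_minus},
        {"chr1": 1000},
    )


def read_table(rows):
    """rows: (chrom, strand, pos5, length, weight)."""
    import pandas as pd

    from riboflow.ranges import READ_COLUMNS

    return ReadTable(pd.DataFrame(rows, columns=READ_COLUMNS))


@pytest.fixture(scope="session")
def calib_sim():
    """Unspliced 20-gene genome + footprints with known offsets {28:12, 29:13}."""
    sim = make_genome(n_genes=20, exon_count_range=(1, 1), seed=42)
    reads, truth = simulate_riboseq(
        sim.annotation, offsets={28: 12, 29: 13}, frame0_frac=0.9, depth=12002, seed=43
    )
    return sim, reads, truth


@pytest.fixture(scope="session")
def spliced_sim():
    """Multi-exon genome on both strands for coordinate and feature tests."""
    return make_genome(n_genes=15, exon_count_range=(2, 4), seed=7)


def random_transcript(rng, chrom="chrR", max_exons=5):
    """A random multi-exon transcript on a random strand (for property tests)."""
    k = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    cursor = int(rng.integers(0, 1000))
    blocks = []
    for _ in range(k):
        w = int(rng.integers(1, 60))
        blocks.append((cursor, cursor + w))
        cursor += w + int(rng.integers(10, 100))
    if strand == "-":
        blocks = blocks[::-1]
    exons = SplicedRange(tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks))
    return TranscriptModel(f"rt{rng.integers(1e9)}", "g", exons)
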