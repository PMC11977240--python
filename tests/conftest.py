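"""Shared fixtures: hand-built transcripts and random instance builders."""

from __future__ import annotations

import numpy as np
import pytest

from rg4coloc import GenomicInterval, TranscriptModel


@pytest.fixture
def two_exon_plus():
    """+ strand, exons [100,150) and [180,230); length 100, CDS tx[20,80)."""
    return TranscriptModel(
        "TXP",
        "GENEP",
        "chr1",
        "+",
        (
            GenomicInterval("chr1", 100, 150, "+"),
            GenomicInterval("chr1", 180, 230, "+"),
        ),
        20,
        80,
    )


@pytest.fixture
def one_exon_minus():
    """- strand, one exon [100,200); length 100, CDS tx[10,70)."""
    return TranscriptModel(
        "TXM",
        "GENEM",
        "chr1",
        "-",
        (GenomicInterval("chr1", 100, 200, "-"),),
        10,
        70,
    )


def random_transcript(rng: np.random.Generator, tx_id: str = "TX") -> TranscriptModel:
    """Random multi-exon coding transcript for property tests."""
    n_exons = int(rng.integers(1, 6))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 300))
        exons.append(GenomicInterval("chrR", pos, pos + length, strand))
        pos += length + int(rng.integers(10, 200))
    total = sum(len(e) for e in exons)
    cds_start = int(rng.integers(0, total - 1))
    cds_end = int(rng.integers(cds_start + 1, total + 1))
    return TranscriptModel(tx_id, f"g_{tx_id}", "chrR", strand, tuple(exons), cds_start, cds_end)


def simple_tx(tx_id: str, l5: int, lc: int, l3: int) -> TranscriptModel:
    """Single-exon coding transcript on its own contig, + strand."""
    L = l5 + lc + l3
    return TranscriptModel(
        tx_id, f"g_{tx_id}", tx_id, "+", (GenomicInterval(tx_id, 0, L, "+"),), l5, l5 + lc
    )
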