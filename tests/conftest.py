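"""Shared fixtures: toy gene models and small simulated data sets."""

from __future__ import annotations

import numpy as np
import pytest

from splicebench import (
    ASEvent,
    EventType,
    GeneModel,
    GenomicInterval,
    Transcript,
    load_preset,
    simulate_annotation,
)


def make_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    main_exons,
    alt_exons_by_id: dict[str, list] | None = None,
    gene_name: str | None = None,
) -> GeneModel:
    transcripts = [
        Transcript.from_intervals(
            f"{gene_id}.t1", gene_id, chrom, strand, main_exons, is_main=True
        )
    ]
    for tid, exons in (alt_exons_by_id or {}).items():
        transcripts.append(
            Transcript.from_intervals(tid, gene_id, chrom, strand, exons)
        )
    return GeneModel(gene_id, gene_name or gene_id, tuple(transcripts))


@pytest.fixture
def toy_gene() -> GeneModel:
    """Three-exon gene on +: exons [101,200], [301,400], [501,600]."""
    return make_gene("G1", "chr1", "+", [(101, 200), (301, 400), (501, 600)])


@pytest.fixture
def toy_gene4() -> GeneModel:
    """Four-exon gene on + for multi-exon skipping cases."""
    return make_gene(
        "G4", "chr1", "+", [(10101, 10200), (10301, 10400), (10501, 10600), (10701, 10800)]
    )


@pytest.fixture(scope="session")
def sim_s0():
    """Small S0 simulation shared across read-only tests."""
    cfg = load_preset("S0", n_genes=60, n_reads=400, seed=7)
    models, truth = simulate_annotation(cfg)
    return cfg, models, truth


def random_events(n: int, seed: int, chroms=("chr1", "chr2")) -> list[ASEvent]:
    """Structurally valid random unified events for round-trip testing."""
    rng = np.random.default_rng(seed)
    types = list(EventType)
    out = []
    for i in range(n):
        etype = types[int(rng.integers(len(types)))]
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.integers(2) else "-"
        n_blocks = int(rng.integers(1, 4)) if etype in (EventType.MES, EventType.MEE) else 1
        pos = int(rng.integers(1, 10_000_000))
        blocks = []
        for _ in range(n_blocks):
            length = int(rng.integers(1, 500))
            blocks.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(2, 1000))
        out.append(
            ASEvent(
                event_id=f"ev{i:05d}",
                gene_name=f"gene{int(rng.integers(100))}",
                chrom=chrom,
                strand=strand,
                event_type=etype,
                blocks=tuple(blocks),
                source_tool=f"tool{int(rng.integers(5))}",
            )
        )
    return out
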