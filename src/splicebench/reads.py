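"""Read simulation with exact per-read truth, plus controlled corruption.

Single-end reads are sampled uniformly over genes, isoforms equiprobable
within a gene, positions uniform along the mature transcript; transcript
coordinates are projected through the exon structure to genomic blocks.
Each read is emitted three ways that agree exactly:

* a truth table of true chromosome, aligned blocks and splice junctions,
* a SAM file with the read perfectly aligned (CIGAR uses only M and N;
  every N span is a junction gap),
* a FASTQ whose bases come from a seeded synthetic reference sequence with
  substitutions at the configured error rate (qualities are constant "I" —
  no downstream metric consumes them).

Sequences are reported in the forward genomic frame regardless of gene
strand, so at error rate 0 the FASTQ base string equals the reference
projection exactly.

:func:`corrupt_alignments` turns exact fractions of reads (largest-remainder
rounding) into unmapped or position-shifted records so that downstream
mapping metrics have analytically known expected values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pysam
from Bio import SeqIO

from .genemodel import GeneModel, GenomicInterval
from .simulate import CHROM, INTERGENIC_GAP, SimulationConfig

__all__ = [
    "TruthRead",
    "TruthReadTable",
    "simulate_reads",
    "corrupt_alignments",
    "downsample_reads",
    "largest_remainder_counts",
    "reference_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MISPLACE_SHIFT = 1000


@dataclass(frozen=True)
class TruthRead:
    read_id: str
    transcript_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    junctions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b[0] <= a[1]:
                raise ValueError(f"read {self.read_id}: blocks not sorted/disjoint")
        expected = tuple((a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:]))
        if self.junctions != expected:
            raise ValueError(
                f"read {self.read_id}: junctions {self.junctions} are not the "
                f"gaps between blocks (expected {expected})"
            )


class TruthReadTable:
    def __init__(self, reads: list[TruthRead]):
        self.reads = list(reads)
        self.by_id = {r.read_id: r for r in self.reads}
        if len(self.by_id) != len(self.reads):
            raise ValueError("duplicate read_id in truth read table")

    def __len__(self) -> int:
        return len(self.reads)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("read_id\ttranscript_id\tchrom\tblocks\tjunctions\n")
            for r in self.reads:
                blocks = ";".join(f"{s}-{e}" for s, e in r.blocks)
                juncs = ";".join(f"{d}:{a}" for d, a in r.junctions)
                fh.write(
                    f"{r.read_id}\t{r.transcript_id}\t{r.chrom}\t{blocks}\t{juncs}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "TruthReadTable":
        reads = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                rid, tid, chrom, blocks, juncs = line.split("\t")
                bl = tuple(
                    tuple(int(x) for x in p.split("-")) for p in blocks.split(";")
                )
                jn = (
                    tuple(tuple(int(x) for x in p.split(":")) for p in juncs.split(";"))
                    if juncs
                    else ()
                )
                reads.append(TruthRead(rid, tid, chrom, bl, jn))
        return cls(reads)


def reference_sequence(length: int, seed: int) -> np.ndarray:
    """Deterministic synthetic chromosome sequence as a uint8 base array."""
    rng = np.random.default_rng((int(seed), 23))
    return _BASES[rng.integers(0, 4, int(length))]


def _project(
    exons_tx_order: list[tuple[int, int]], strand: str, p0: int, p1: int
) -> list[tuple[int, int]]:
    """Map the transcript-coordinate interval [p0, p1] to genomic blocks."""
    blocks = []
    c = 0
    for s, e in exons_tx_order:
        ln = e - s + 1
        lo, hi = max(p0, c), min(p1, c + ln - 1)
        if lo <= hi:
            if strand == "+":
                blocks.append((s + (lo - c), s + (hi - c)))
            else:
                blocks.append((e - (hi - c), e - (lo - c)))
        c += ln
    blocks.sort()
    return blocks


def _cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for i, (s, e) in enumerate(blocks):
        if i:
            out.append((3, s - blocks[i - 1][1] - 1))  # N
        out.append((0, e - s + 1))  # M
    return out


def _sam_header(chrom_len: int) -> dict:
    return {"HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": CHROM, "LN": int(chrom_len)}]}


def simulate_reads(
    models: list[GeneModel],
    cfg: SimulationConfig,
    sam_path: str | os.PathLike,
    fastq_path: str | os.PathLike,
) -> TruthReadTable:
    """Simulate reads and write truth-consistent SAM and FASTQ files.

    Transcripts shorter than the read length are excluded from sampling
    (reads shorter than ``cfg.read_length`` are never produced); if no
    transcript is long enough a :class:`ValueError` is raised.
    """
    L = cfg.read_length
    eligible: list[list] = []  # per gene: list of (tid, strand, exons in tx order, len)
    for g in models:
        txs = []
        for t in g.transcripts:
            if t.length >= L:
                ex = list(t.exon_coords)
                if t.strand == "-":
                    ex = ex[::-1]
                txs.append((t.transcript_id, t.strand, ex, t.length))
        if txs:
            eligible.append(txs)
    if not eligible and cfg.n_reads > 0:
        raise ValueError(
            f"no transcript is at least read_length={L} bases long"
        )

    chrom_len = max(g.span.end for g in models) + INTERGENIC_GAP
    ref = reference_sequence(chrom_len, cfg.seed)
    rng = np.random.default_rng((int(cfg.seed), 31))

    reads: list[TruthRead] = []
    header = _sam_header(chrom_len)
    qual = pysam.qualitystring_to_array("I" * L)
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam, open(
        fastq_path, "w", newline=""
    ) as fq:
        for i in range(cfg.n_reads):
            gene = eligible[int(rng.integers(len(eligible)))]
            tid, strand, ex, txlen = gene[int(rng.integers(len(gene)))]
            p0 = int(rng.integers(0, txlen - L + 1))
            blocks = _project(ex, strand, p0, p0 + L - 1)
            juncs = tuple((a[1], b[0]) for a, b in zip(blocks, blocks[1:]))
            rid = f"r{i:07d}"
            reads.append(TruthRead(rid, tid, CHROM, tuple(blocks), juncs))

            seq = np.concatenate([ref[s - 1 : e] for s, e in blocks])
            if cfg.error_rate > 0:
                hits = np.flatnonzero(rng.random(L) < cfg.error_rate)
                for h in hits:
                    cur = int(np.searchsorted(_BASES, seq[h]))
                    seq[h] = _BASES[(cur + int(rng.integers(1, 4))) % 4]
            seq_s = seq.tobytes().decode()

            a = pysam.AlignedSegment(header=sam.header)
            a.query_name = rid
            a.flag = 0
            a.reference_id = 0
            a.reference_start = blocks[0][0] - 1
            a.mapping_quality = 60
            a.cigartuples = _cigar(blocks)
            a.query_sequence = seq_s
            a.query_qualities = qual
            sam.write(a)
            fq.write(f"@{rid}\n{seq_s}\n+\n{'I' * L}\n")

    return TruthReadTable(reads)


def largest_remainder_counts(n: int, fractions: list[float]) -> list[int]:
    """Integer apportionment of ``n`` by the largest-remainder method.

    Ties in the fractional parts are broken by list position, so the split
    is fully deterministic and sums to ``n`` exactly.
    """
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def corrupt_alignments(
    sam_in: str | os.PathLike,
    sam_out: str | os.PathLike,
    u: float,
    m: float,
    seed: int,
) -> tuple[int, int, int]:
    """Unmap a ``u``-fraction and misplace a disjoint ``m``-fraction of reads.

    Misplaced reads keep their CIGAR but are shifted +1000 bp; fractions are
    realised exactly via largest-remainder rounding over (unmapped,
    misplaced, intact). Returns the three counts.
    """
    if not (0 <= u <= 1 and 0 <= m <= 1 and u + m <= 1):
        raise ValueError("u, m must be in [0,1] with u + m <= 1")
    with pysam.AlignmentFile(str(sam_in), "r", check_sq=False) as fh:
        header = fh.header.to_dict()
        records = list(fh)
    n = len(records)
    n_u, n_m, n_ok = largest_remainder_counts(n, [u, m, 1.0 - u - m])
    perm = np.random.default_rng(int(seed)).permutation(n)
    unmap = set(int(x) for x in perm[:n_u])
    shift = set(int(x) for x in perm[n_u : n_u + n_m])
    with pysam.AlignmentFile(str(sam_out), "wh", header=header) as out:
        for i, rec in enumerate(records):
            if i in unmap:
                rec.is_unmapped = True
                rec.reference_id = -1
                rec.reference_start = -1
                rec.cigartuples = None
                rec.mapping_quality = 0
            elif i in shift:
                rec.reference_start += _MISPLACE_SHIFT
            out.write(rec)
    return n_u, n_m, n_ok


def downsample_reads(
    path_in: str | os.PathLike,
    path_out: str | os.PathLike,
    n: int,
    seed: int,
) -> int:
    """Uniform sample of ``n`` records without replacement, order preserved.

    Input format (SAM or FASTQ) is detected from the file extension.
    """
    suffix = str(path_in).lower()
    is_sam = suffix.endswith(".sam")
    if is_sam:
        with pysam.AlignmentFile(str(path_in), "r", check_sq=False) as fh:
            header = fh.header.to_dict()
            records = list(fh)
    else:
        records = list(SeqIO.parse(str(path_in), "fastq"))
    if n > len(records):
        raise ValueError(
            f"cannot downsample to {n}: only {len(records)} records present"
        )
    rng = np.random.default_rng(int(seed))
    keep = np.sort(rng.choice(len(records), size=n, replace=False))
    if is_sam:
        with pysam.AlignmentFile(str(path_out), "wh", header=header) as out:
            for i in keep:
                out.write(records[int(i)])
    else:
        with open(path_out, "w", newline="") as out:
            SeqIO.write([records[int(i)] for i in keep], out, "fastq")
    return n
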