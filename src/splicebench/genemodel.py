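"""Genomic intervals and the gene → transcript → exon data model.

All coordinates are 1-based and inclusive on both ends (the native GTF/SAM
convention); half-open BED-style coordinates never appear in this package
except at explicitly labelled export points.

Every gene carries exactly one *main* transcript — the reference isoform
against which alternative-splicing events are defined — plus any number of
alternative isoforms that realise events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ValidationError",
    "GenomicInterval",
    "Exon",
    "Transcript",
    "GeneModel",
    "transcript_introns",
    "select_main_transcript",
]


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval on one strand.

    ``start`` and ``end`` are 1-based and inclusive; ``start <= end`` always
    holds, so the empty interval cannot be represented (by design: every
    event-defining block covers at least one base).
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Exon:
    """An exon with its ordinal position in transcription order.

    ``exon_index`` is 1 for the first *transcribed* exon, which is the
    genomically leftmost exon on '+' and the rightmost on '-'.
    """

    interval: GenomicInterval
    exon_index: int

    def __post_init__(self) -> None:
        if self.exon_index < 1:
            raise ValidationError(f"exon_index must be >= 1, got {self.exon_index}")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    exons: tuple[Exon, ...]
    is_main: bool = False

    def __post_init__(self) -> None:
        if len(self.exons) < 1:
            raise ValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        object.__setattr__(self, "exons", tuple(self.exons))
        chroms = {e.interval.chrom for e in self.exons}
        strands = {e.interval.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} mixes strands {sorted(strands)}"
            )
        ivs = [e.interval for e in self.exons]
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons not sorted/disjoint "
                    f"({a.coords()} then {b.coords()})"
                )
        # transcription order: 1..n left-to-right on '+', right-to-left on '-'
        n = len(self.exons)
        for pos, exon in enumerate(self.exons):
            expected = pos + 1 if self.strand == "+" else n - pos
            if exon.exon_index != expected:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon at {exon.interval.coords()} "
                    f"has exon_index {exon.exon_index}, expected {expected}"
                )

    @classmethod
    def from_intervals(
        cls,
        transcript_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        coords: Iterable[tuple[int, int]],
        is_main: bool = False,
    ) -> "Transcript":
        """Build a transcript from (start, end) pairs in any order."""
        pairs = sorted(coords)
        n = len(pairs)
        exons = tuple(
            Exon(
                GenomicInterval(chrom, s, e, strand),
                pos + 1 if strand == "+" else n - pos,
            )
            for pos, (s, e) in enumerate(pairs)
        )
        return cls(transcript_id, gene_id, exons, is_main)

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].interval.start, self.exons[-1].interval.end, self.strand
        )

    @property
    def exon_coords(self) -> tuple[tuple[int, int], ...]:
        return tuple(e.interval.coords() for e in self.exons)

    @property
    def length(self) -> int:
        """Spliced (mature transcript) length in bases."""
        return sum(e.interval.length for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        mains = [t for t in self.transcripts if t.is_main]
        if len(mains) != 1:
            raise ValidationError(
                f"gene {self.gene_id} must have exactly one main transcript, "
                f"found {len(mains)}"
            )
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"gene {self.gene_id}: transcripts disagree on chrom/strand"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def main_transcript(self) -> Transcript:
        return next(t for t in self.transcripts if t.is_main)

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


def transcript_introns(t: Transcript) -> list[GenomicInterval]:
    """Introns of a transcript in genomic order.

    For consecutive exons [s1, e1], [s2, e2] the intron is [e1 + 1, s2 - 1];
    a single-exon transcript yields the empty list.
    """
    out: list[GenomicInterval] = []
    for a, b in zip(t.exons, t.exons[1:]):
        out.append(
            GenomicInterval(t.chrom, a.interval.end + 1, b.interval.start - 1, t.strand)
        )
    return out


def select_main_transcript(transcripts: Sequence[Transcript]) -> str:
    """Pick the main isoform when no explicit tag is present.

    Rule: most exons, ties broken by longest genomic span, then by
    lexicographically smallest transcript_id (fully deterministic).
    """
    best = min(
        transcripts,
        key=lambda t: (-len(t.exons), -t.span.length, t.transcript_id),
    )
    return best.transcript_id
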