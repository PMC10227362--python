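"""The unified alternative-splicing event format.

One record per detected event, carrying the event-defining coordinates:
skipped exon(s) for ES/MES/MEE, the retained intron for IR, the alternative
part of an exon for A5/A3, and the alternative first/last exon for AFE/ALE —
plus gene name, chromosome, strand and a unique ID.

Serialisation is a fixed-column TSV whose byte layout is documented in
``docs/format.md``; equal event collections always serialise to identical
bytes so outputs are diff-able.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .genemodel import GenomicInterval, ValidationError

__all__ = [
    "EventType",
    "ASEvent",
    "EventParseError",
    "write_unified",
    "read_unified",
    "event_key",
    "format_blocks",
    "parse_blocks",
    "UNIFIED_HEADER",
]

UNIFIED_HEADER = (
    "event_id\tgene_name\tchrom\tstrand\tevent_type\tblocks\tsource_tool"
)


class EventType(str, Enum):
    """The eight core alternative-splicing event classes."""

    ES = "ES"    # exon skipping
    MES = "MES"  # multiple exon skipping
    MEE = "MEE"  # mutually exclusive exons
    IR = "IR"    # intron retention
    A5 = "A5"    # alternative 5'-splice site (donor), strand-relative
    A3 = "A3"    # alternative 3'-splice site (acceptor), strand-relative
    AFE = "AFE"  # alternative first exon
    ALE = "ALE"  # alternative last exon


# Number of coordinate blocks each type carries. MES/MEE are normally >= 2,
# but degenerate single-block skipping records occur in tool output and are
# accepted (they collapse to ES under the skipping-collapse rule anyway).
_MIN_BLOCKS = {
    EventType.ES: (1, 1),
    EventType.IR: (1, 1),
    EventType.A5: (1, 1),
    EventType.A3: (1, 1),
    EventType.AFE: (1, 1),
    EventType.ALE: (1, 1),
    EventType.MES: (1, None),
    EventType.MEE: (1, None),
}


class EventParseError(ValueError):
    """A unified-format TSV row could not be parsed; message names the row."""


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    gene_name: str
    chrom: str
    strand: str
    event_type: EventType
    blocks: tuple[GenomicInterval, ...]
    source_tool: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "event_type", EventType(self.event_type))
        if self.strand not in ("+", "-"):
            raise ValidationError(f"event {self.event_id}: bad strand {self.strand!r}")
        lo, hi = _MIN_BLOCKS[self.event_type]
        n = len(self.blocks)
        if n < lo or (hi is not None and n > hi):
            raise ValidationError(
                f"event {self.event_id}: {self.event_type.value} requires "
                f"{'exactly ' + str(lo) if hi == lo else '>= ' + str(lo)} block(s), got {n}"
            )
        for b in self.blocks:
            if b.chrom != self.chrom or b.strand != self.strand:
                raise ValidationError(
                    f"event {self.event_id}: block {b.coords()} not on "
                    f"{self.chrom}{self.strand}"
                )
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"event {self.event_id}: blocks not sorted/disjoint"
                )

    @property
    def start(self) -> int:
        return self.blocks[0].start

    def block_coords(self) -> tuple[tuple[int, int], ...]:
        return tuple(b.coords() for b in self.blocks)


def format_blocks(blocks: Sequence[GenomicInterval]) -> str:
    """``start-end`` joined by ``;`` — e.g. ``301-400;501-600``."""
    return ";".join(f"{b.start}-{b.end}" for b in blocks)


def parse_blocks(text: str, chrom: str, strand: str) -> tuple[GenomicInterval, ...]:
    out = []
    for part in text.split(";"):
        s, _, e = part.partition("-")
        if not s or not e or not s.isdigit() or not e.isdigit():
            raise ValueError(f"bad block syntax {part!r}")
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return tuple(out)


def _check_unique_ids(events: Sequence[ASEvent]) -> None:
    seen: dict[str, int] = {}
    for e in events:
        seen[e.event_id] = seen.get(e.event_id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate event_id values: {', '.join(dups)}")


def write_unified(events: Iterable[ASEvent], path: str | os.PathLike) -> None:
    """Write events as unified TSV, sorted and byte-deterministic.

    Rows are ordered by (chrom, first block start, event_type, event_id).
    Duplicate event ids raise :class:`ValidationError` listing the offenders.
    """
    events = list(events)
    _check_unique_ids(events)
    events.sort(key=lambda e: (e.chrom, e.start, e.event_type.value, e.event_id))
    with open(path, "w", newline="") as fh:
        fh.write(UNIFIED_HEADER + "\n")
        for e in events:
            fh.write(
                "\t".join(
                    [
                        e.event_id,
                        e.gene_name,
                        e.chrom,
                        e.strand,
                        e.event_type.value,
                        format_blocks(e.blocks),
                        e.source_tool,
                    ]
                )
                + "\n"
            )


def read_unified(path: str | os.PathLike) -> list[ASEvent]:
    """Read a unified TSV; inverse of :func:`write_unified` field-wise."""
    events: list[ASEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != UNIFIED_HEADER:
            raise EventParseError(
                f"{path}: unexpected header {header!r}"
            )
        for rowno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise EventParseError(
                    f"{path}: row {rowno}: expected 7 columns, got {len(fields)}"
                )
            event_id, gene_name, chrom, strand, etype, blocks, source = fields
            if strand not in ("+", "-"):
                raise EventParseError(f"{path}: row {rowno}: bad strand {strand!r}")
            try:
                et = EventType(etype)
            except ValueError as exc:
                raise EventParseError(
                    f"{path}: row {rowno}: unknown event_type {etype!r}"
                ) from exc
            try:
                parsed = parse_blocks(blocks, chrom, strand)
            except ValueError as exc:
                raise EventParseError(f"{path}: row {rowno}: {exc}") from exc
            try:
                events.append(
                    ASEvent(event_id, gene_name, chrom, strand, et, parsed, source)
                )
            except ValidationError as exc:
                raise EventParseError(f"{path}: row {rowno}: {exc}") from exc
    _check_unique_ids(events)
    return events


def event_key(e: ASEvent, collapse_skipping: bool = True):
    """Canonical comparison key for matching and tool intersections.

    The key is (chrom, strand, effective type, block coordinates); gene name,
    event id and source tool are deliberately excluded because tools disagree
    on identifiers while coordinates are the comparable signal. With
    ``collapse_skipping`` the MES and MEE labels map onto ES, mirroring how
    the benchmark treats multi-exon skipping.
    """
    etype = e.event_type
    if collapse_skipping and etype in (EventType.MES, EventType.MEE):
        etype = EventType.ES
    return (e.chrom, e.strand, etype.value, e.block_coords())
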