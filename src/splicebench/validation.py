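"""Independent structural validation of simulated truth events.

This module re-derives the event set of a simulated annotation purely by
diffing each alternative isoform against the main isoform — it shares no
code or state with the event-placement machinery, so agreement between the
two is a genuine cross-check of the simulator:

* an alternative missing a run of internal main exons → ES (run of 1) or
  MES (run of 2+), blocks = the missing exons;
* an alternative exon spanning two adjacent main exons and their intron
  exactly → IR, block = the intron;
* an alternative exon sharing one boundary with a main exon and shifted on
  the other → A5/A3 (strand decides which), block = the exonic difference;
* a first/last transcribed exon disjoint from every main exon, with the
  main terminal exon absent → AFE/ALE, block = the novel exon.

Mutually exclusive exons need *two* coordinated isoforms (each missing one
of the two exons), which a per-isoform diff reads as two exon skips; MEE
pairing is therefore opt-in and only safe when no genuine adjacent
complementary skips can occur (as in MEE-bearing configurations, where
events_per_transcript is 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .events import EventType
from .genemodel import GeneModel, Transcript
from .simulate import TruthEventTable

__all__ = ["DerivedEvent", "derive_gene_events", "validate_truth", "ValidationReport"]


@dataclass(frozen=True)
class DerivedEvent:
    transcript_id: str
    event_type: EventType
    blocks: tuple[tuple[int, int], ...]


class StructuralMismatch(ValueError):
    """An alternative isoform differs from the main in an unclassifiable way."""


def _diff_transcript(
    main: list[tuple[int, int]], alt: list[tuple[int, int]], strand: str, tid: str
) -> list[tuple[EventType, tuple[tuple[int, int], ...]]]:
    events: list[tuple[EventType, tuple[tuple[int, int], ...]]] = []
    main_set = set(main)
    consumed = [False] * len(main)

    def overlap_idx(a):
        return [
            k for k, m in enumerate(main) if a[0] <= m[1] and m[0] <= a[1]
        ]

    alt_remaining = []
    # terminal novelty: first/last transcribed exon with no main overlap
    first_tx = alt[0] if strand == "+" else alt[-1]
    last_tx = alt[-1] if strand == "+" else alt[0]
    main_first = 0 if strand == "+" else len(main) - 1
    main_last = len(main) - 1 if strand == "+" else 0
    novel = set()
    if not overlap_idx(first_tx):
        events.append((EventType.AFE, (first_tx,)))
        consumed[main_first] = True
        novel.add(first_tx)
    if last_tx != first_tx and not overlap_idx(last_tx):
        events.append((EventType.ALE, (last_tx,)))
        consumed[main_last] = True
        novel.add(last_tx)

    for a in alt:
        if a in novel:
            continue
        if a in main_set:
            consumed[main.index(a)] = True
            continue
        hits = overlap_idx(a)
        if len(hits) == 2 and hits[1] == hits[0] + 1:
            k = hits[0]
            if a == (main[k][0], main[k + 1][1]):
                intron = (main[k][1] + 1, main[k + 1][0] - 1)
                events.append((EventType.IR, (intron,)))
                consumed[k] = consumed[k + 1] = True
                continue
            raise StructuralMismatch(
                f"{tid}: exon {a} straddles two main exons without exact merge"
            )
        if len(hits) == 1:
            (k,) = hits
            m = main[k]
            if a[0] == m[0] and a[1] != m[1]:
                lo, hi = sorted((a[1], m[1]))
                block = (lo + 1, hi)
                etype = EventType.A5 if strand == "+" else EventType.A3
            elif a[1] == m[1] and a[0] != m[0]:
                lo, hi = sorted((a[0], m[0]))
                block = (lo, hi - 1)
                etype = EventType.A3 if strand == "+" else EventType.A5
            else:
                raise StructuralMismatch(
                    f"{tid}: exon {a} overlaps main exon {m} on neither boundary"
                )
            events.append((etype, (block,)))
            consumed[k] = True
            continue
        raise StructuralMismatch(f"{tid}: exon {a} overlaps {len(hits)} main exons")

    # remaining unconsumed internal main exons: runs of skipped exons
    missing = [k for k in range(len(main)) if not consumed[k]]
    run: list[int] = []
    for k in missing + [None]:
        if run and (k is None or k != run[-1] + 1):
            blocks = tuple(main[i] for i in run)
            etype = EventType.ES if len(run) == 1 else EventType.MES
            events.append((etype, blocks))
            run = []
        if k is not None:
            run.append(k)
    return events


def derive_gene_events(gene: GeneModel, detect_mee: bool = False) -> list[DerivedEvent]:
    """Re-derive all events of a gene from transcript structure alone."""
    main = list(gene.main_transcript.exon_coords)
    out: list[DerivedEvent] = []
    per_tx: dict[str, list] = {}
    for t in gene.transcripts:
        if t.is_main:
            continue
        per_tx[t.transcript_id] = _diff_transcript(
            main, list(t.exon_coords), gene.strand, t.transcript_id
        )

    if detect_mee:
        # pair complementary single-skips of adjacent exons into one MEE
        singles: dict[tuple[int, int], str] = {}
        for tid, evs in per_tx.items():
            if len(evs) == 1 and evs[0][0] == EventType.ES:
                singles[evs[0][1][0]] = tid
        used: set[str] = set()
        ordered = sorted(main)
        for k in range(len(ordered) - 1):
            a, b = ordered[k], ordered[k + 1]
            if a in singles and b in singles and singles[a] != singles[b]:
                ta, tb = singles[a], singles[b]
                if ta in used or tb in used:
                    continue
                # the isoform missing exon b (keeping a) is the MEE lead
                out.append(DerivedEvent(singles[b], EventType.MEE, (a, b)))
                used.update((ta, tb))
        for tid, evs in per_tx.items():
            if tid in used:
                continue
            out.extend(DerivedEvent(tid, et, bl) for et, bl in evs)
    else:
        for tid, evs in per_tx.items():
            out.extend(DerivedEvent(tid, et, bl) for et, bl in evs)
    return out


@dataclass
class ValidationReport:
    n_truth: int
    n_derived: int
    n_agree: int
    mismatches: list[str] = field(default_factory=list)

    @property
    def fully_recovered(self) -> bool:
        return self.n_truth == self.n_derived == self.n_agree

    @property
    def recovery_rate(self) -> float:
        return self.n_agree / self.n_truth if self.n_truth else 1.0


def validate_truth(
    models: list[GeneModel], truth: TruthEventTable, detect_mee: bool = False
) -> ValidationReport:
    """Compare per-transcript derived events with the truth table.

    Events are compared as (transcript, type, blocks) multisets, so the
    check is sharper than key-set equality: a swap of events between
    isoforms of one gene would be flagged.
    """
    derived = Counter()
    for g in models:
        for d in derive_gene_events(g, detect_mee=detect_mee):
            derived[(d.transcript_id, d.event_type, d.blocks)] += 1
    wanted = Counter()
    for r in truth.records:
        wanted[(r.transcript_id, r.event.event_type, r.event.block_coords())] += 1

    agree = sum((derived & wanted).values())
    mismatches = []
    for key in sorted(
        set(wanted) - set(derived), key=lambda k: (k[0], k[1].value, k[2])
    ):
        mismatches.append(f"missing from derivation: {key}")
    for key in sorted(
        set(derived) - set(wanted), key=lambda k: (k[0], k[1].value, k[2])
    ):
        mismatches.append(f"derived but not in truth: {key}")
    return ValidationReport(
        n_truth=sum(wanted.values()),
        n_derived=sum(derived.values()),
        n_agree=agree,
        mismatches=mismatches,
    )
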