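"""Synthetic ground-truth annotation simulator.

Generates gene models on a single synthetic chromosome and injects
alternative-splicing events of controlled type proportions into alternative
isoforms, recording every realised event with its unified coordinates in a
:class:`TruthEventTable`. The six stock designs S0–S5 vary the event-type
set, the number of events per transcript, whether one exon may be involved
in more than one event, and the sequencing error rate.

Gene geometry (chosen for speed while allowing all event types): exon count
uniform in [4, 12], exon length uniform in [50, 300] bp, intron length
uniform in [100, 1000] bp, 5000 bp intergenic gaps, alternating strands,
chromosome name ``simchr1``. All randomness flows from the config seed, so
equal configs produce byte-identical outputs.

Event realisation rules against the main (all-exon) isoform:

* ES removes one internal exon; MES removes 2–3 consecutive internal exons.
* MEE picks two adjacent internal exons and emits a *pair* of alternative
  isoforms, each retaining exactly one of the two.
* IR merges two adjacent exons across their intron.
* A5 / A3 move a donor / acceptor 10–60 bp into the intron (strand-aware);
  the truth block is the exonic difference between the two variants.
* AFE / ALE replace the first / last transcribed exon with a novel exon in
  the flanking intergenic region.

Within one alternative isoform, co-occurring events always claim disjoint
exons and introns (otherwise one event would erase the evidence for the
other); the "events per exon" knob controls whether events in *different*
isoforms of the same gene may involve the same exon.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .events import ASEvent, EventType, format_blocks, parse_blocks, read_unified
from .genemodel import GeneModel, GenomicInterval, Transcript, ValidationError

__all__ = [
    "CHROM",
    "INTERGENIC_GAP",
    "SimulationConfig",
    "ConfigurationError",
    "TruthRecord",
    "TruthEventTable",
    "load_preset",
    "PRESET_NAMES",
    "simulate_annotation",
    "truncate_annotation",
]

CHROM = "simchr1"
INTERGENIC_GAP = 5000

_EXON_COUNT = (4, 12)
_EXON_LEN = (50, 300)
_INTRON_LEN = (100, 1000)
_SHIFT = (10, 60)        # A5/A3 splice-site displacement, bp
_MIN_RESIDUAL_INTRON = 20  # intron bases that must survive an A5/A3 shift

PRESET_NAMES = ("S0", "S1", "S2", "S3", "S4", "S5")

_CORE4 = (EventType.ES, EventType.IR, EventType.A5, EventType.A3)
_SEVEN = _CORE4 + (EventType.MES, EventType.ALE, EventType.AFE)


class ConfigurationError(ValueError):
    """The simulation configuration is internally impossible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation design parameters.

    ``event_types`` maps each admissible type to its sampling proportion
    (must sum to 1). ``events_per_exon`` = 1 forces all events of a gene to
    involve disjoint exons; >= 2 allows events in different isoforms to share
    an exon. ``error_rate`` is the per-base substitution probability applied
    to read sequences.
    """

    event_types: dict[EventType, float]
    n_genes: int = 200
    transcripts_per_gene: int = 1
    events_per_transcript: int = 1
    events_per_exon: int = 1
    error_rate: float = 0.0
    read_length: int = 76
    n_reads: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        props = dict(self.event_types)
        object.__setattr__(self, "event_types", props)
        if not props:
            raise ConfigurationError("event_types must not be empty")
        if any(p < 0 for p in props.values()):
            raise ConfigurationError("event-type proportions must be >= 0")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"event-type proportions must sum to 1 (got {total})"
            )
        if self.events_per_transcript not in (1, 2):
            raise ConfigurationError("events_per_transcript must be 1 or 2")
        if self.events_per_exon < 1:
            raise ConfigurationError("events_per_exon must be >= 1")
        if self.transcripts_per_gene < 1:
            raise ConfigurationError("transcripts_per_gene must be >= 1")
        if self.read_length < 20:
            raise ConfigurationError("read_length must be >= 20")
        if self.n_reads < 0:
            raise ConfigurationError("n_reads must be >= 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigurationError("error_rate must be in [0, 1]")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if (
            EventType.MEE in props
            and props[EventType.MEE] > 0
            and self.events_per_transcript != 1
        ):
            raise ConfigurationError(
                "MEE requires events_per_transcript == 1 (it occupies a "
                "dedicated pair of alternative isoforms)"
            )


def _equal(types) -> dict[EventType, float]:
    return {t: 1.0 / len(types) for t in types}


def load_preset(
    name: str,
    proportions: dict[EventType, float] | None = None,
    **overrides,
) -> SimulationConfig:
    """Return one of the stock simulation designs S0–S5.

    S5 takes caller-supplied event proportions over {ES, IR, A5, A3} (they
    emulate proportions estimated from a real cohort and are a free input);
    without them it falls back to equal proportions. Any
    :class:`SimulationConfig` field may be overridden by keyword.
    """
    designs = {
        "S0": dict(event_types=_equal(_CORE4), transcripts_per_gene=1,
                   events_per_transcript=1, events_per_exon=1, error_rate=0.0),
        "S1": dict(event_types=_equal(_SEVEN), transcripts_per_gene=1,
                   events_per_transcript=1, events_per_exon=1, error_rate=0.0),
        "S2": dict(event_types=_equal(_SEVEN), transcripts_per_gene=1,
                   events_per_transcript=1, events_per_exon=1, error_rate=0.001),
        "S3": dict(event_types=_equal(_SEVEN), transcripts_per_gene=2,
                   events_per_transcript=2, events_per_exon=1, error_rate=0.001),
        "S4": dict(event_types=_equal(_SEVEN), transcripts_per_gene=2,
                   events_per_transcript=2, events_per_exon=2, error_rate=0.001),
        "S5": dict(event_types=_equal(_CORE4), transcripts_per_gene=2,
                   events_per_transcript=2, events_per_exon=2, error_rate=0.001),
    }
    if name not in designs:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    params = dict(designs[name])
    if proportions is not None:
        if name != "S5":
            raise ConfigurationError("custom proportions are an S5 parameter")
        bad = set(proportions) - set(_CORE4)
        if bad:
            raise ConfigurationError(
                f"S5 admits only ES/IR/A5/A3, got {sorted(t.value for t in bad)}"
            )
        params["event_types"] = dict(proportions)
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass(frozen=True)
class TruthRecord:
    """One simulated truth event plus its provenance."""

    event: ASEvent
    gene_id: str
    transcript_id: str


class TruthEventTable:
    """The simulated ground-truth event set with per-event provenance."""

    def __init__(self, records: list[TruthRecord]):
        self.records = list(records)

    @property
    def events(self) -> list[ASEvent]:
        return [r.event for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def by_transcript(self) -> dict[str, list[TruthRecord]]:
        out: dict[str, list[TruthRecord]] = {}
        for r in self.records:
            out.setdefault(r.transcript_id, []).append(r)
        return out

    def type_counts(self) -> dict[EventType, int]:
        out: dict[EventType, int] = {}
        for r in self.records:
            out[r.event.event_type] = out.get(r.event.event_type, 0) + 1
        return out

    def write_tsv(self, path: str | os.PathLike) -> None:
        """Unified columns plus gene_id and transcript_id provenance."""
        recs = sorted(
            self.records,
            key=lambda r: (r.event.chrom, r.event.start, r.event.event_type.value,
                           r.event.event_id),
        )
        with open(path, "w", newline="") as fh:
            fh.write(
                "event_id\tgene_name\tchrom\tstrand\tevent_type\tblocks\t"
                "source_tool\tgene_id\ttranscript_id\n"
            )
            for r in recs:
                e = r.event
                fh.write(
                    "\t".join(
                        [e.event_id, e.gene_name, e.chrom, e.strand,
                         e.event_type.value, format_blocks(e.blocks),
                         e.source_tool, r.gene_id, r.transcript_id]
                    )
                    + "\n"
                )

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "TruthEventTable":
        records = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                (eid, gname, chrom, strand, etype, blocks, source,
                 gene_id, tid) = line.split("\t")
                ev = ASEvent(eid, gname, chrom, strand, EventType(etype),
                             parse_blocks(blocks, chrom, strand), source)
                records.append(TruthRecord(ev, gene_id, tid))
        return cls(records)


# ---------------------------------------------------------------------------
# event realisation machinery


class _GeneDraft:
    """Mutable state while events are being placed on one gene."""

    def __init__(self, exons: list[tuple[int, int]], strand: str,
                 left_gap: int, right_gap: int):
        self.exons = exons          # main-transcript exons, genomic order
        self.strand = strand
        self.left_gap = left_gap    # intergenic space available left of gene
        self.right_gap = right_gap
        self.involved: set[int] = set()   # exon idx involved in >= 1 event (gene-wide)

    @property
    def n(self) -> int:
        return len(self.exons)


class _TranscriptDraft:
    """Per-isoform edit plan: disjoint claims guarantee a clean diff."""

    def __init__(self, draft: _GeneDraft):
        self.gene = draft
        self.claimed_exons: set[int] = set()
        self.claimed_introns: set[int] = set()
        self.deleted: set[int] = set()
        self.new_start: dict[int, int] = {}
        self.new_end: dict[int, int] = {}
        self.merged_introns: set[int] = set()
        self.novel_left: tuple[int, int] | None = None
        self.novel_right: tuple[int, int] | None = None

    def free(self, exon_idx=(), intron_idx=()) -> bool:
        if any(i in self.claimed_exons for i in exon_idx):
            return False
        if any(i in self.claimed_introns for i in intron_idx):
            return False
        return True

    def claim(self, exon_idx=(), intron_idx=()) -> None:
        self.claimed_exons.update(exon_idx)
        self.claimed_introns.update(intron_idx)

    def build_exons(self) -> list[tuple[int, int]]:
        ex = self.gene.exons
        out: list[tuple[int, int]] = []
        i = 0
        while i < len(ex):
            if i in self.deleted:
                i += 1
                continue
            s = self.new_start.get(i, ex[i][0])
            e = self.new_end.get(i, ex[i][1])
            while i in self.merged_introns:
                i += 1
                e = self.new_end.get(i, ex[i][1])
            out.append((s, e))
            i += 1
        if self.novel_left:
            out.insert(0, self.novel_left)
        if self.novel_right:
            out.append(self.novel_right)
        return out


def _exon_ok(draft: _GeneDraft, idx_set, events_per_exon: int) -> bool:
    if events_per_exon >= 2:
        return True
    return not (set(idx_set) & draft.involved)


def _place_event(
    etype: EventType,
    draft: _GeneDraft,
    tdraft: _TranscriptDraft,
    rng: np.random.Generator,
    events_per_exon: int,
):
    """Try to realise one event; returns (blocks, involved_exons, extra) or None.

    ``extra`` is only used by MEE and carries the paired-isoform edit.
    """
    ex = draft.exons
    n = draft.n
    strand = draft.strand
    internal = [k for k in range(1, n - 1)]

    def pick(cands):
        if not cands:
            return None
        return cands[int(rng.integers(len(cands)))]

    if etype in (EventType.ES, EventType.MES, EventType.MEE):
        if etype == EventType.ES:
            runlens = [1]
        elif etype == EventType.MES:
            runlens = [int(rng.integers(2, 4))]  # 2 or 3 consecutive exons
        else:
            runlens = [2]
        runlen = runlens[0]
        cands = []
        for k in internal:
            idxs = list(range(k, k + runlen))
            if idxs[-1] > n - 2:
                continue
            introns = list(range(k - 1, k + runlen))
            if not tdraft.free(idxs, introns):
                continue
            if not _exon_ok(draft, idxs, events_per_exon):
                continue
            cands.append(k)
        k = pick(cands)
        if k is None:
            return None
        idxs = list(range(k, k + runlen))
        introns = list(range(k - 1, k + runlen))
        if etype == EventType.MEE:
            # this isoform keeps exon k and drops k+1; the pair does the converse
            tdraft.claim(idxs, introns)
            tdraft.deleted.add(k + 1)
            blocks = [ex[k], ex[k + 1]]
            return blocks, set(idxs), {"mee_partner_deletes": k}
        tdraft.claim(idxs, introns)
        tdraft.deleted.update(idxs)
        return [ex[i] for i in idxs], set(idxs), None

    if etype == EventType.IR:
        cands = []
        for k in range(n - 1):
            if not tdraft.free((k, k + 1), (k,)):
                continue
            if not _exon_ok(draft, (k, k + 1), events_per_exon):
                continue
            cands.append(k)
        k = pick(cands)
        if k is None:
            return None
        tdraft.claim((k, k + 1), (k,))
        tdraft.merged_introns.add(k)
        block = (ex[k][1] + 1, ex[k + 1][0] - 1)
        return [block], {k, k + 1}, None

    if etype in (EventType.A5, EventType.A3):
        # genomic side of the intron that moves: on '+', A5 moves the left
        # (donor) boundary, A3 the right (acceptor); '-' swaps the roles.
        left_side = (etype == EventType.A5) == (strand == "+")
        cands = []
        for k in range(n - 1):
            mod_exon = k if left_side else k + 1
            if not tdraft.free((mod_exon,), (k,)):
                continue
            if not _exon_ok(draft, (mod_exon,), events_per_exon):
                continue
            cands.append(k)
        k = pick(cands)
        if k is None:
            return None
        mod_exon = k if left_side else k + 1
        intron_len = ex[k + 1][0] - ex[k][1] - 1
        max_shift = min(_SHIFT[1], intron_len - _MIN_RESIDUAL_INTRON)
        delta = int(rng.integers(_SHIFT[0], max_shift + 1))
        tdraft.claim((mod_exon,), (k,))
        if left_side:
            e = ex[k][1]
            tdraft.new_end[k] = e + delta
            block = (e + 1, e + delta)
        else:
            s = ex[k + 1][0]
            tdraft.new_start[k + 1] = s - delta
            block = (s - delta, s - 1)
        return [block], {mod_exon}, None

    if etype in (EventType.AFE, EventType.ALE):
        # first transcribed exon is genomic-left on '+', genomic-right on '-'
        replace_left = (etype == EventType.AFE) == (strand == "+")
        term = 0 if replace_left else n - 1
        adj_intron = 0 if replace_left else n - 2
        if not tdraft.free((term,), (adj_intron,)):
            return None
        if not _exon_ok(draft, (term,), events_per_exon):
            return None
        gap = int(rng.integers(_INTRON_LEN[0], _INTRON_LEN[1] + 1))
        length = int(rng.integers(_EXON_LEN[0], _EXON_LEN[1] + 1))
        if gap + length > (draft.left_gap if replace_left else draft.right_gap):
            return None
        tdraft.claim((term,), (adj_intron,))
        tdraft.deleted.add(term)
        if replace_left:
            end = ex[0][0] - gap - 1
            novel = (end - length + 1, end)
            tdraft.novel_left = novel
        else:
            start = ex[-1][1] + gap + 1
            novel = (start, start + length - 1)
            tdraft.novel_right = novel
        return [novel], {term}, None

    raise AssertionError(f"unhandled event type {etype}")


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], TruthEventTable]:
    """Simulate gene models plus their ground-truth event table.

    Every gene gets a main isoform containing all exons and
    ``transcripts_per_gene`` alternative isoforms, each realising
    ``events_per_transcript`` events whose types are drawn independently
    from the configured proportions. A drawn type that cannot be placed on
    the gene (e.g. no free internal exon left) is resampled, so the total
    event count is always ``n_genes * transcripts_per_gene *
    events_per_transcript`` (MEE adds its paired isoform on top).
    """
    rng = np.random.default_rng((int(cfg.seed), 17))
    types = sorted(cfg.event_types, key=lambda t: t.value)
    props = np.array([cfg.event_types[t] for t in types], dtype=float)
    props = props / props.sum()

    models: list[GeneModel] = []
    records: list[TruthRecord] = []
    cursor = INTERGENIC_GAP + 1

    def _draw_exons(start: int, min_exons: int) -> list[tuple[int, int]]:
        n_exons = int(rng.integers(min_exons, _EXON_COUNT[1] + 1))
        exon_lens = rng.integers(_EXON_LEN[0], _EXON_LEN[1] + 1, n_exons)
        intron_lens = rng.integers(_INTRON_LEN[0], _INTRON_LEN[1] + 1, n_exons - 1)
        exons: list[tuple[int, int]] = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j]) - 1))
            pos = exons[-1][1] + 1
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        return exons

    def _place_gene(draft: _GeneDraft):
        """One placement attempt over all isoforms; None when it dead-ends."""
        alt_plans = []
        for _ in range(cfg.transcripts_per_gene):
            tdraft = _TranscriptDraft(draft)
            placed: list[tuple[EventType, list[tuple[int, int]], dict | None]] = []
            for _slot in range(cfg.events_per_transcript):
                result = None
                tried: set[EventType] = set()
                while len(tried) < len(types):
                    etype = types[int(rng.choice(len(types), p=props))]
                    if etype in tried:
                        continue
                    result = _place_event(
                        etype, draft, tdraft, rng, cfg.events_per_exon
                    )
                    if result is not None:
                        break
                    tried.add(etype)
                if result is None:
                    return None
                blocks, involved, extra = result
                draft.involved |= involved
                placed.append((etype, blocks, extra))
            alt_plans.append((tdraft, placed))
        return alt_plans

    for gi in range(cfg.n_genes):
        gene_id = f"SIMG{gi + 1:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        exons = _draw_exons(cursor, _EXON_COUNT[0])
        alt_plans = None
        # greedy placement can dead-end on small genes even when a global
        # assignment exists; retry, then redraw a larger gene, before giving up
        for trial in range(60):
            if trial == 30:
                exons = _draw_exons(cursor, 8)
            draft = _GeneDraft(
                exons, strand,
                left_gap=INTERGENIC_GAP // 2 - 1,
                right_gap=INTERGENIC_GAP // 2 - 1,
            )
            alt_plans = _place_gene(draft)
            if alt_plans is not None:
                break
        if alt_plans is None:
            raise ConfigurationError(
                f"gene {gene_id}: cannot place "
                f"{cfg.transcripts_per_gene}x{cfg.events_per_transcript} events; "
                "the configuration is infeasible for the gene geometry"
            )

        transcripts = [
            Transcript.from_intervals(
                f"{gene_id}.t1", gene_id, CHROM, strand, exons, is_main=True
            )
        ]
        ev_counter = 0
        alt_counter = 1
        for tdraft, placed in alt_plans:
            alt_counter += 1
            tid = f"{gene_id}.t{alt_counter}"
            transcripts.append(
                Transcript.from_intervals(
                    tid, gene_id, CHROM, strand, tdraft.build_exons()
                )
            )
            for etype, blocks, extra in placed:
                ev_counter += 1
                event = ASEvent(
                    event_id=f"{gene_id}.e{ev_counter}",
                    gene_name=gene_id,
                    chrom=CHROM,
                    strand=strand,
                    event_type=etype,
                    blocks=tuple(
                        GenomicInterval(CHROM, s, e, strand) for s, e in blocks
                    ),
                    source_tool="truth",
                )
                records.append(TruthRecord(event, gene_id, tid))
                if extra and "mee_partner_deletes" in extra:
                    # the mutually-exclusive partner isoform
                    alt_counter += 1
                    partner = _TranscriptDraft(draft)
                    partner.deleted.add(extra["mee_partner_deletes"])
                    transcripts.append(
                        Transcript.from_intervals(
                            f"{gene_id}.t{alt_counter}", gene_id, CHROM, strand,
                            partner.build_exons(),
                        )
                    )

        models.append(GeneModel(gene_id, gene_id, tuple(transcripts)))
        span_end = max(t.span.end for t in transcripts)
        cursor = span_end + INTERGENIC_GAP + 1

    return models, TruthEventTable(records)


def truncate_annotation(models: list[GeneModel]) -> list[GeneModel]:
    """Keep only the main isoform of each gene (the "-tr" annotation).

    Gene and exon coordinates are untouched; the operation is idempotent.
    """
    return [
        GeneModel(g.gene_id, g.gene_name, (g.main_transcript,)) for g in models
    ]
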