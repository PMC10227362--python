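"""Normalisation of heterogeneous event-reporting conventions.

Detection tools describe the same splicing event in three different ways:

* ``skipped_exon`` — the event-defining coordinates themselves (the skipped
  exon(s), retained intron, alternative exon part, ...), optionally with a
  claimed event type;
* ``flanking_exons`` — the two annotated exons *around* a skipped exon;
* ``junction`` — an anchoring exon plus the splice junction(s) observed.

Each convention is mapped onto the unified format using the gene model:
the gene is resolved by coordinate containment, and junction records are
classified against the *main* transcript of that gene (matching the
truncated-annotation evaluation, where only the main isoform is known).

A junction record's anchor exon must itself match an annotated exon of the
resolved gene (any isoform). An anchor the annotation does not know,
combined with a shifted or missing junction, is indistinguishable from a
novel junction and is rejected as such — this is what makes intron
retention and alternative splice sites degrade, as real tools do, when only
main isoforms are annotated.

Rejections carry a machine-readable reason; lenient batch mode collects
them in a report while strict mode raises on the first one.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .events import ASEvent, EventType
from .genemodel import GeneModel, GenomicInterval, ValidationError, transcript_introns

__all__ = [
    "DIALECTS",
    "RawEventRecord",
    "NormalizationError",
    "UnresolvedGeneError",
    "NotNormalizableError",
    "NovelJunctionError",
    "GeneIndex",
    "normalize_skipped_exon",
    "normalize_flanking_exons",
    "normalize_junctions",
    "normalize_batch",
    "NormalizationReport",
    "render_to_dialect",
    "read_dialect_tsv",
    "write_dialect_tsv",
]

DIALECTS = ("skipped_exon", "flanking_exons", "junction")

# rejection reasons
UNRESOLVED_GENE = "unresolved-gene"
NOT_NORMALIZABLE = "not-normalizable"
NOVEL_JUNCTION = "novel-junction"
INVALID_RECORD = "invalid-record"


class NormalizationError(ValueError):
    reason = INVALID_RECORD


class UnresolvedGeneError(NormalizationError):
    reason = UNRESOLVED_GENE


class NotNormalizableError(NormalizationError):
    reason = NOT_NORMALIZABLE


class NovelJunctionError(NormalizationError):
    reason = NOVEL_JUNCTION


@dataclass(frozen=True)
class RawEventRecord:
    """One tool-output record in one of the three reporting conventions."""

    dialect: str
    chrom: str
    strand: str
    gene_hint: str | None = None
    claimed_type: EventType | None = None
    # skipped_exon payload
    exons: tuple[tuple[int, int], ...] = ()
    # flanking_exons payload
    upstream: tuple[int, int] | None = None
    downstream: tuple[int, int] | None = None
    # junction payload
    anchor: tuple[int, int] | None = None
    junctions: tuple[tuple[int, int], ...] = ()
    retained: bool = False

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        for d, a in self.junctions:
            if d >= a:
                raise ValueError(
                    f"junction ({d}, {a}): donor_end must be < acceptor_start"
                )


class GeneIndex:
    """Span-indexed gene lookup plus cached main-transcript geometry."""

    def __init__(self, models: list[GeneModel]):
        self.models = {g.gene_id: g for g in models}
        self._trees: dict[str, IntervalTree] = {}
        self._main_exons: dict[str, set[tuple[int, int]]] = {}
        self._all_exons: dict[str, set[tuple[int, int]]] = {}
        self._introns: dict[str, list[tuple[int, int]]] = {}
        self._spans: dict[str, tuple[int, int]] = {}
        for g in models:
            span = g.span
            self._spans[g.gene_id] = (span.start, span.end)
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree[span.start : span.end + 1] = g.gene_id
            self._main_exons[g.gene_id] = set(g.main_transcript.exon_coords)
            self._all_exons[g.gene_id] = {
                c for t in g.transcripts for c in t.exon_coords
            }
            self._introns[g.gene_id] = [
                i.coords() for i in transcript_introns(g.main_transcript)
            ]

    def resolve(self, chrom: str, strand: str, start: int, end: int) -> GeneModel | None:
        """Gene whose span contains [start, end]; smallest span wins ties."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = []
        for iv in tree.overlap(start, end + 1):
            gid = iv.data
            s, e = self._spans[gid]
            g = self.models[gid]
            if s <= start and end <= e and g.strand == strand:
                hits.append((e - s, gid))
        if not hits:
            return None
        hits.sort()
        return self.models[hits[0][1]]

    def main_exons(self, gene_id: str) -> set[tuple[int, int]]:
        return self._main_exons[gene_id]

    def annotated_exons(self, gene_id: str) -> set[tuple[int, int]]:
        return self._all_exons[gene_id]

    def main_introns(self, gene_id: str) -> list[tuple[int, int]]:
        return self._introns[gene_id]


def _mk_event(
    event_id: str,
    gene_name: str,
    rec: RawEventRecord,
    etype: EventType,
    blocks,
    source_tool: str,
) -> ASEvent:
    return ASEvent(
        event_id=event_id,
        gene_name=gene_name,
        chrom=rec.chrom,
        strand=rec.strand,
        event_type=etype,
        blocks=tuple(
            GenomicInterval(rec.chrom, s, e, rec.strand) for s, e in sorted(blocks)
        ),
        source_tool=source_tool,
    )


def normalize_skipped_exon(
    rec: RawEventRecord,
    index: GeneIndex,
    event_id: str = "event",
    source_tool: str = "tool",
    strict: bool = True,
) -> ASEvent:
    """Direct conversion: the payload intervals *are* the unified blocks.

    Without a claimed type the record is ES (one exon) or MES (several).
    The gene name is resolved by containment; in lenient mode an intergenic
    payload yields gene_name "NA" instead of an error.
    """
    if rec.dialect != "skipped_exon":
        raise NormalizationError(f"expected skipped_exon record, got {rec.dialect}")
    if not rec.exons:
        raise NormalizationError("skipped_exon record carries no exons")
    blocks = sorted(rec.exons)
    etype = rec.claimed_type or (
        EventType.ES if len(blocks) == 1 else EventType.MES
    )
    gene = index.resolve(rec.chrom, rec.strand, blocks[0][0], blocks[-1][1])
    if gene is None:
        if strict:
            raise UnresolvedGeneError(
                f"payload {blocks} on {rec.chrom}{rec.strand} lies in no gene span"
            )
        gene_name = rec.gene_hint or "NA"
    else:
        gene_name = gene.gene_name
    return _mk_event(event_id, gene_name, rec, etype, blocks, source_tool)


def normalize_flanking_exons(
    rec: RawEventRecord,
    index: GeneIndex,
    event_id: str = "event",
    source_tool: str = "tool",
) -> ASEvent:
    """Recover skipped exon(s) from the two annotated flanks around them."""
    if rec.dialect != "flanking_exons":
        raise NormalizationError(f"expected flanking_exons record, got {rec.dialect}")
    if rec.upstream is None or rec.downstream is None:
        raise NormalizationError("flanking record needs upstream and downstream exons")
    up, down = sorted([rec.upstream, rec.downstream])
    if up[1] >= down[0]:
        raise NormalizationError("flanking exons must be disjoint")
    gene = index.resolve(rec.chrom, rec.strand, up[0], down[1])
    if gene is None or not (
        up in index.main_exons(gene.gene_id)
        and down in index.main_exons(gene.gene_id)
    ):
        raise UnresolvedGeneError(
            f"flanks {up}, {down} are not main-transcript exons of any gene"
        )
    between = sorted(
        c for c in index.main_exons(gene.gene_id) if up[1] < c[0] and c[1] < down[0]
    )
    if not between:
        raise NotNormalizableError(
            f"no annotated exon between flanks {up} and {down} "
            "(candidate intron retention or novel junction)"
        )
    etype = EventType.ES if len(between) == 1 else EventType.MES
    return _mk_event(event_id, gene.gene_name, rec, etype, between, source_tool)


def _classify_junction(
    j: tuple[int, int],
    introns: list[tuple[int, int]],
    main_exons: set[tuple[int, int]],
    strand: str,
    span: tuple[int, int],
):
    """Classify one junction against main-transcript splice sites.

    Returns (event_type, blocks) for an event-bearing junction, None for a
    junction that matches an annotated intron exactly (no event), and raises
    for novel or inconsistent junctions.
    """
    left, right = j
    donors = {s - 1 for s, _ in introns}        # genomic-left intron flanks
    acceptors = {e + 1 for _, e in introns}     # genomic-right intron flanks
    if (left + 1, right - 1) in set(introns):
        return None
    l_ok = left in donors
    r_ok = right in acceptors
    if l_ok and r_ok:
        inside = sorted(c for c in main_exons if left < c[0] and c[1] < right)
        if inside:
            etype = EventType.ES if len(inside) == 1 else EventType.MES
            return etype, inside
        raise NotNormalizableError(
            f"junction ({left}, {right}) joins annotated splice sites with no "
            "annotated exon in between"
        )
    if r_ok and not l_ok:
        # genomic-left boundary shifted: donor on '+', acceptor on '-'
        (i_s, i_e) = next(iv for iv in introns if iv[1] + 1 == right)
        ann = i_s - 1
        block = (min(left, ann) + 1, max(left, ann))
        etype = EventType.A5 if strand == "+" else EventType.A3
    elif l_ok and not r_ok:
        (i_s, i_e) = next(iv for iv in introns if iv[0] - 1 == left)
        ann = i_e + 1
        block = (min(right, ann), max(right, ann) - 1)
        etype = EventType.A3 if strand == "+" else EventType.A5
    else:
        raise NovelJunctionError(
            f"junction ({left}, {right}) matches no annotated splice site on "
            "either end"
        )
    if block[0] < span[0] or block[1] > span[1]:
        raise NovelJunctionError(
            f"junction ({left}, {right}): inferred alternative part {block} "
            "falls outside the gene span"
        )
    return etype, [block]


def normalize_junctions(
    rec: RawEventRecord,
    index: GeneIndex,
    event_id: str = "event",
    source_tool: str = "tool",
) -> ASEvent:
    """Classify a junction-convention record against the main transcript.

    A skip junction over annotated exon(s) becomes ES/MES; a junction
    sharing exactly one splice site with an annotated intron becomes A5/A3
    (strand-aware) with the exonic difference as block; a retained-flag
    record whose anchor covers exactly one annotated intron becomes IR.
    """
    if rec.dialect != "junction":
        raise NormalizationError(f"expected junction record, got {rec.dialect}")
    if rec.anchor is None:
        raise NormalizationError("junction record needs an anchor exon")
    if not rec.retained and not rec.junctions:
        raise NormalizationError("junction record needs >= 1 junction pair")
    gene = index.resolve(rec.chrom, rec.strand, rec.anchor[0], rec.anchor[1])
    if gene is None:
        raise UnresolvedGeneError(
            f"anchor exon {rec.anchor} on {rec.chrom}{rec.strand} lies in no gene span"
        )
    if rec.anchor not in index.annotated_exons(gene.gene_id):
        raise NovelJunctionError(
            f"anchor exon {rec.anchor} is not an annotated exon of "
            f"{gene.gene_id}; junction evidence alone cannot be separated "
            "from a novel junction"
        )
    introns = index.main_introns(gene.gene_id)
    span = (gene.span.start, gene.span.end)

    if rec.retained:
        covered = [
            iv
            for iv in introns
            if rec.anchor[0] < iv[0] and iv[1] < rec.anchor[1]
        ]
        if len(covered) != 1:
            raise NotNormalizableError(
                f"retained-flag anchor {rec.anchor} covers {len(covered)} "
                "annotated introns (need exactly 1)"
            )
        return _mk_event(
            event_id, gene.gene_name, rec, EventType.IR, covered, source_tool
        )

    results = []
    for j in rec.junctions:
        out = _classify_junction(
            j, introns, index.main_exons(gene.gene_id), rec.strand, span
        )
        if out is not None:
            results.append(out)
    if not results:
        raise NotNormalizableError(
            "all junctions match annotated introns; record describes no event"
        )
    if len(results) > 1:
        raise NotNormalizableError(
            f"record describes {len(results)} distinct events; one expected"
        )
    etype, blocks = results[0]
    return _mk_event(event_id, gene.gene_name, rec, etype, blocks, source_tool)


@dataclass
class NormalizationReport:
    """Per-reason rejection tally plus the rejected records themselves."""

    rejections: list[tuple[int, str, str, str]] = field(default_factory=list)

    def add(self, row: int, dialect: str, reason: str, detail: str) -> None:
        self.rejections.append((row, dialect, reason, detail))

    @property
    def counts(self) -> Counter:
        return Counter(reason for (_, _, reason, _) in self.rejections)

    def __len__(self) -> int:
        return len(self.rejections)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("row\tdialect\treason\tdetail\n")
            for row, dialect, reason, detail in self.rejections:
                fh.write(f"{row}\t{dialect}\t{reason}\t{detail}\n")


_NORMALIZERS = {
    "skipped_exon": normalize_skipped_exon,
    "flanking_exons": normalize_flanking_exons,
    "junction": normalize_junctions,
}


def normalize_batch(
    records: list[RawEventRecord],
    models: list[GeneModel] | GeneIndex,
    mode: str = "lenient",
    source_tool: str = "tool",
) -> tuple[list[ASEvent], NormalizationReport]:
    """Normalise a record batch, dispatching on dialect.

    Strict mode raises on the first rejection; lenient mode skips the record
    and logs it in the report (skipped-exon records that merely fail gene
    resolution are still emitted with gene_name "NA" in lenient mode).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    index = models if isinstance(models, GeneIndex) else GeneIndex(models)
    events: list[ASEvent] = []
    report = NormalizationReport()
    for row, rec in enumerate(records, start=1):
        event_id = f"{source_tool}.{row:06d}"
        fn = _NORMALIZERS[rec.dialect]
        try:
            if rec.dialect == "skipped_exon":
                ev = fn(rec, index, event_id, source_tool, strict=True)
            else:
                ev = fn(rec, index, event_id, source_tool)
        except (NormalizationError, ValidationError) as exc:
            if mode == "strict":
                raise
            if rec.dialect == "skipped_exon" and isinstance(exc, UnresolvedGeneError):
                ev = normalize_skipped_exon(
                    rec, index, event_id, source_tool, strict=False
                )
                events.append(ev)
            report.add(
                row, rec.dialect, getattr(exc, "reason", INVALID_RECORD), str(exc)
            )
            continue
        events.append(ev)
    return events, report


# ---------------------------------------------------------------------------
# inverse rendering: express a unified event in a tool dialect


def render_to_dialect(
    event: ASEvent, gene: GeneModel, dialect: str
) -> RawEventRecord | None:
    """Render a unified event the way a tool of the given dialect reports it.

    Returns None when the dialect cannot express the event type
    (flanking_exons carries only exon skipping; the junction convention has
    no representation for AFE/ALE/MEE). Used to build cross-dialect
    equivalence fixtures and end-to-end benchmarks.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    etype = event.event_type
    blocks = event.block_coords()
    main = list(gene.main_transcript.exon_coords)

    if dialect == "skipped_exon":
        return RawEventRecord(
            dialect="skipped_exon",
            chrom=event.chrom,
            strand=event.strand,
            gene_hint=gene.gene_name,
            claimed_type=etype,
            exons=blocks,
        )

    if dialect == "flanking_exons":
        if etype not in (EventType.ES, EventType.MES):
            return None
        try:
            i = main.index(blocks[0])
            j = main.index(blocks[-1])
        except ValueError:
            return None
        if i == 0 or j == len(main) - 1:
            return None
        return RawEventRecord(
            dialect="flanking_exons",
            chrom=event.chrom,
            strand=event.strand,
            gene_hint=gene.gene_name,
            upstream=main[i - 1],
            downstream=main[j + 1],
        )

    # junction dialect
    introns = [i.coords() for i in transcript_introns(gene.main_transcript)]
    if etype in (EventType.ES, EventType.MES):
        try:
            i = main.index(blocks[0])
            j = main.index(blocks[-1])
        except ValueError:
            return None
        if i == 0 or j == len(main) - 1:
            return None
        return RawEventRecord(
            dialect="junction",
            chrom=event.chrom,
            strand=event.strand,
            gene_hint=gene.gene_name,
            anchor=main[i - 1],
            junctions=((main[i - 1][1], main[j + 1][0]),),
        )
    if etype == EventType.IR:
        (i_s, i_e) = blocks[0]
        k = next((k for k, iv in enumerate(introns) if iv == (i_s, i_e)), None)
        if k is None:
            return None
        merged = (main[k][0], main[k + 1][1])
        return RawEventRecord(
            dialect="junction",
            chrom=event.chrom,
            strand=event.strand,
            gene_hint=gene.gene_name,
            anchor=merged,
            retained=True,
        )
    if etype in (EventType.A5, EventType.A3):
        (b_s, b_e) = blocks[0]
        for k, (i_s, i_e) in enumerate(introns):
            if i_s <= b_s and b_e <= i_e:
                if b_s == i_s:
                    # genomic-left boundary moved right into the intron
                    anchor = (main[k][0], b_e)
                    junction = (b_e, i_e + 1)
                elif b_e == i_e:
                    anchor = (b_s, main[k + 1][1])
                    junction = (i_s - 1, b_s)
                else:
                    return None
                return RawEventRecord(
                    dialect="junction",
                    chrom=event.chrom,
                    strand=event.strand,
                    gene_hint=gene.gene_name,
                    anchor=anchor,
                    junctions=(junction,),
                )
        return None
    return None  # AFE / ALE / MEE have no junction-dialect rendering


# ---------------------------------------------------------------------------
# dialect TSV files (schemas documented in docs/format.md)

_DIALECT_HEADERS = {
    "skipped_exon": "chrom\tstrand\tblocks\tclaimed_type\tgene",
    "flanking_exons": "chrom\tstrand\tup_start\tup_end\tdown_start\tdown_end",
    "junction": "chrom\tstrand\tanchor_start\tanchor_end\tjunctions\tretained",
}


def write_dialect_tsv(
    records: list[RawEventRecord], dialect: str, path: str | os.PathLike
) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        fh.write(_DIALECT_HEADERS[dialect] + "\n")
        for rec in records:
            if rec.dialect != dialect:
                raise ValueError(
                    f"record dialect {rec.dialect} does not match file dialect {dialect}"
                )
            if dialect == "skipped_exon":
                blocks = ";".join(f"{s}-{e}" for s, e in rec.exons)
                fh.write(
                    f"{rec.chrom}\t{rec.strand}\t{blocks}\t"
                    f"{rec.claimed_type.value if rec.claimed_type else ''}\t"
                    f"{rec.gene_hint or ''}\n"
                )
            elif dialect == "flanking_exons":
                fh.write(
                    f"{rec.chrom}\t{rec.strand}\t{rec.upstream[0]}\t{rec.upstream[1]}"
                    f"\t{rec.downstream[0]}\t{rec.downstream[1]}\n"
                )
            else:
                juncs = ";".join(f"{d}:{a}" for d, a in rec.junctions)
                fh.write(
                    f"{rec.chrom}\t{rec.strand}\t{rec.anchor[0]}\t{rec.anchor[1]}"
                    f"\t{juncs}\t{1 if rec.retained else 0}\n"
                )


def read_dialect_tsv(path: str | os.PathLike, dialect: str) -> list[RawEventRecord]:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[RawEventRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _DIALECT_HEADERS[dialect]:
            raise ValueError(f"{path}: unexpected header for dialect {dialect}")
        for rowno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if dialect == "skipped_exon":
                    chrom, strand, blocks, claimed, gene = fields
                    exons = tuple(
                        tuple(int(x) for x in p.split("-")) for p in blocks.split(";")
                    )
                    records.append(
                        RawEventRecord(
                            dialect=dialect,
                            chrom=chrom,
                            strand=strand,
                            exons=exons,
                            claimed_type=EventType(claimed) if claimed else None,
                            gene_hint=gene or None,
                        )
                    )
                elif dialect == "flanking_exons":
                    chrom, strand, us, ue, ds, de = fields
                    records.append(
                        RawEventRecord(
                            dialect=dialect,
                            chrom=chrom,
                            strand=strand,
                            upstream=(int(us), int(ue)),
                            downstream=(int(ds), int(de)),
                        )
                    )
                else:
                    chrom, strand, a_s, a_e, juncs, retained = fields
                    records.append(
                        RawEventRecord(
                            dialect=dialect,
                            chrom=chrom,
                            strand=strand,
                            anchor=(int(a_s), int(a_e)),
                            junctions=tuple(
                                tuple(int(x) for x in p.split(":"))
                                for p in juncs.split(";")
                                if p
                            ),
                            retained=retained == "1",
                        )
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: row {rowno}: {exc}") from exc
    return records
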