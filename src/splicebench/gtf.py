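"""GTF reading and writing for :class:`~splicebench.genemodel.GeneModel`.

The dialect is Ensembl-style GTF: nine tab-separated columns with attributes
serialised as ``key "value";`` pairs. Only gene / transcript / exon features
are modelled (no CDS/UTR). The writer marks the main isoform with a
``main_transcript "true"`` attribute so that annotations round-trip
losslessly; annotations lacking the tag fall back to a deterministic
selection rule (see :func:`~splicebench.genemodel.select_main_transcript`).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

from .genemodel import (
    GeneModel,
    GenomicInterval,
    Transcript,
    ValidationError,
    select_main_transcript,
)

__all__ = ["GTFParseError", "read_gtf", "write_gtf"]

_HEADER = "#!annotation-source splicebench"


class GTFParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


def _attr(feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    if not vals:
        return None
    return vals[0]


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GTF file into gene models.

    Exon features are grouped by (gene_id, transcript_id); coordinates are
    taken verbatim (GTF is already 1-based inclusive). Genes are returned
    sorted by (chrom, span start, gene_id).
    """
    # (gene_id, transcript_id) -> list of (chrom, start, end, strand)
    exons: dict[tuple[str, str], list[tuple[str, int, int, str]]] = {}
    gene_names: dict[str, str] = {}
    declared_transcripts: dict[str, list[str]] = {}
    main_tagged: dict[str, set[str]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise GTFParseError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            gene_id = _attr(f, "gene_id")
            if gene_id is None:
                raise GTFParseError(f"{path}: line {lineno}: missing gene_id attribute")
            if gene_id not in gene_names:
                order.append(gene_id)
                gene_names[gene_id] = gene_id
            name = _attr(f, "gene_name")
            if name:
                gene_names[gene_id] = name

            if f.featuretype == "gene":
                continue
            tid = _attr(f, "transcript_id")
            if tid is None:
                raise GTFParseError(
                    f"{path}: line {lineno}: missing transcript_id attribute"
                )
            if f.featuretype == "transcript":
                declared_transcripts.setdefault(gene_id, []).append(tid)
                if (_attr(f, "main_transcript") or "").lower() == "true":
                    main_tagged.setdefault(gene_id, set()).add(tid)
            elif f.featuretype == "exon":
                if (_attr(f, "main_transcript") or "").lower() == "true":
                    main_tagged.setdefault(gene_id, set()).add(tid)
                exons.setdefault((gene_id, tid), []).append(
                    (f.seqid, f.start, f.end, f.strand)
                )

    models: list[GeneModel] = []
    for gene_id in order:
        tids = [t for (g, t) in exons if g == gene_id]
        # keep first-seen order but deterministic: sort by transcript_id
        tids = sorted(set(tids))
        for declared in declared_transcripts.get(gene_id, []):
            if declared not in tids:
                raise ValidationError(
                    f"gene {gene_id}: transcript {declared} declared but has no exons"
                )
        if not tids:
            continue  # gene feature without exons: nothing to model
        transcripts = []
        for tid in tids:
            recs = exons[(gene_id, tid)]
            chroms = {r[0] for r in recs}
            strands = {r[3] for r in recs}
            if len(chroms) > 1:
                raise ValidationError(
                    f"transcript {tid}: exons on multiple chromosomes {sorted(chroms)}"
                )
            if len(strands) > 1:
                raise ValidationError(
                    f"transcript {tid}: exons on mixed strands"
                )
            transcripts.append(
                Transcript.from_intervals(
                    tid,
                    gene_id,
                    recs[0][0],
                    recs[0][3],
                    [(s, e) for (_, s, e, _) in recs],
                )
            )
        tagged = main_tagged.get(gene_id, set()) & {t.transcript_id for t in transcripts}
        if len(tagged) == 1:
            main_id = next(iter(tagged))
        else:
            main_id = select_main_transcript(transcripts)
        transcripts = [
            Transcript(t.transcript_id, t.gene_id, t.exons, t.transcript_id == main_id)
            for t in transcripts
        ]
        models.append(GeneModel(gene_id, gene_names[gene_id], transcripts))

    models.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return models


def _fmt_attrs(pairs: Sequence[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def _line(chrom, feature, start, end, strand, attrs) -> str:
    return "\t".join(
        [chrom, "splicebench", feature, str(start), str(end), ".", strand, ".", _fmt_attrs(attrs)]
    )


def write_gtf(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as Ensembl-dialect GTF.

    Attribute order is fixed, genes are sorted by (chrom, start, gene_id) and
    transcripts by id, so equal inputs produce byte-identical files and
    ``read_gtf(write_gtf(models))`` returns field-wise equal models.
    """
    models = sorted(models, key=lambda g: (g.chrom, g.span.start, g.gene_id))
    lines = [_HEADER]
    for gene in models:
        span = gene.span
        lines.append(
            _line(
                gene.chrom,
                "gene",
                span.start,
                span.end,
                gene.strand,
                [("gene_id", gene.gene_id), ("gene_name", gene.gene_name)],
            )
        )
        for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
            base = [
                ("gene_id", gene.gene_id),
                ("transcript_id", t.transcript_id),
                ("gene_name", gene.gene_name),
            ]
            tattrs = list(base)
            if t.is_main:
                tattrs.append(("main_transcript", "true"))
            ts = t.span
            lines.append(_line(gene.chrom, "transcript", ts.start, ts.end, gene.strand, tattrs))
            for exon in t.exons:
                eattrs = list(base) + [("exon_number", str(exon.exon_index))]
                if t.is_main:
                    eattrs.append(("main_transcript", "true"))
                lines.append(
                    _line(
                        gene.chrom,
                        "exon",
                        exon.interval.start,
                        exon.interval.end,
                        gene.strand,
                        eattrs,
                    )
                )
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
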