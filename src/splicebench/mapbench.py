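"""Benchmark metrics for splice-aware read mapping.

Two headline quantities, both defined against the simulated per-read truth:

* fraction of unmapped reads — unmapped reads over *all simulated* reads
  (reads missing from the alignment file count as unmapped, since some
  mappers drop reads instead of emitting flag-4 records);
* precision — correctly mapped reads over all mapped reads, where a read is
  correct iff its chromosome, every aligned block and every splice junction
  agree with the truth within a coordinate tolerance (default 0).

Because "reads and junctions" can be pooled in more than one way, the
junction-strict per-read precision (``precision_read``) is reported as the
headline number and a separate junction-level precision
(``precision_junction``) is kept alongside it.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .reads import TruthReadTable

__all__ = [
    "CigarError",
    "MappingMetrics",
    "extract_alignment_blocks",
    "evaluate_mapping",
    "mapping_report",
    "write_mapping_report",
]


class CigarError(ValueError):
    """A CIGAR string cannot be decomposed into blocks; names the read."""


# reference-consuming ops that extend the current block
_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X
_SKIP_OP = 3               # N
_QUERY_OPS = {1, 4, 5, 6}  # I, S, H, P consume no reference


def extract_alignment_blocks(
    rec: pysam.AlignedSegment,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Decode a mapped record's CIGAR into reference blocks and junctions.

    M/=/X/D extend the current block; each N closes it and contributes a
    junction (last reference base, next reference start); I/S/H/P consume no
    reference. Coordinates are 1-based inclusive.
    """
    if rec.is_unmapped or rec.cigartuples is None:
        raise CigarError(f"read {rec.query_name}: record is unmapped or lacks CIGAR")
    pos = rec.reference_start + 1
    blocks: list[tuple[int, int]] = []
    junctions: list[tuple[int, int]] = []
    cur_start: int | None = None
    cur = pos
    for op, ln in rec.cigartuples:
        if op in _BLOCK_OPS:
            if cur_start is None:
                cur_start = cur
            cur += ln
        elif op == _SKIP_OP:
            if cur_start is None:
                raise CigarError(
                    f"read {rec.query_name}: N operation without preceding "
                    "reference-consuming operation"
                )
            blocks.append((cur_start, cur - 1))
            junctions.append((cur - 1, cur + ln))
            cur += ln
            cur_start = None
        elif op in _QUERY_OPS:
            continue
        else:
            raise CigarError(f"read {rec.query_name}: unsupported CIGAR op {op}")
    if cur_start is None:
        raise CigarError(f"read {rec.query_name}: CIGAR consumes no reference")
    blocks.append((cur_start, cur - 1))
    return blocks, junctions


@dataclass(frozen=True)
class MappingMetrics:
    n_simulated: int
    n_mapped: int
    n_reads_correct: int
    n_junctions_observed: int
    n_junctions_correct: int

    def __post_init__(self) -> None:
        if self.n_mapped > self.n_simulated:
            raise ValueError("n_mapped exceeds n_simulated")

    @property
    def n_unmapped(self) -> int:
        return self.n_simulated - self.n_mapped

    @property
    def fraction_unmapped(self) -> float:
        return self.n_unmapped / self.n_simulated if self.n_simulated else 0.0

    @property
    def precision_read(self) -> float:
        return self.n_reads_correct / self.n_mapped if self.n_mapped else 0.0

    @property
    def precision_junction(self) -> float:
        if self.n_junctions_observed == 0:
            return 0.0
        return self.n_junctions_correct / self.n_junctions_observed


def _within(a: tuple[int, int], b: tuple[int, int], tol: int) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def evaluate_mapping(
    sam_path: str | os.PathLike,
    truth: TruthReadTable,
    tolerance: int = 0,
) -> MappingMetrics:
    """Score an alignment file against the truth read table.

    Only primary alignments contribute (one vote per read); a read is
    correct iff chromosome and block count match and every block boundary
    and junction agrees with the truth within ``tolerance`` bases. A read id
    absent from the truth table is an error; truth reads absent from the SAM
    count as unmapped.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if len(truth) == 0:
        raise ValueError("truth read table is empty")

    n_mapped = 0
    n_correct = 0
    n_j_obs = 0
    n_j_corr = 0
    seen: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        chrom_names = list(fh.references)
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            rid = rec.query_name
            if rid not in truth.by_id:
                raise ValueError(f"read {rid} in SAM is absent from the truth table")
            if rid in seen:
                continue  # one vote per read: first primary record wins
            seen.add(rid)
            if rec.is_unmapped:
                continue
            n_mapped += 1
            t = truth.by_id[rid]
            blocks, junctions = extract_alignment_blocks(rec)
            chrom = rec.reference_name

            # junction-level tally: each truth junction consumed at most once
            remaining = list(t.junctions)
            n_j_obs += len(junctions)
            if chrom == t.chrom:
                for j in junctions:
                    for k, tj in enumerate(remaining):
                        if _within(j, tj, tolerance):
                            n_j_corr += 1
                            del remaining[k]
                            break

            ok = (
                chrom == t.chrom
                and len(blocks) == len(t.blocks)
                and all(_within(b, tb, tolerance) for b, tb in zip(blocks, t.blocks))
                and len(junctions) == len(t.junctions)
                and all(
                    _within(j, tj, tolerance) for j, tj in zip(junctions, t.junctions)
                )
            )
            if ok:
                n_correct += 1

    return MappingMetrics(
        n_simulated=len(truth),
        n_mapped=n_mapped,
        n_reads_correct=n_correct,
        n_junctions_observed=n_j_obs,
        n_junctions_correct=n_j_corr,
    )


def mapping_report(
    metrics_by_label: Mapping[str, MappingMetrics] | Iterable[tuple[str, MappingMetrics]],
) -> pd.DataFrame:
    """Tabulate per-tool mapping metrics, sorted by label.

    Precision columns are NA when a tool mapped nothing. The
    (precision_read, fraction_unmapped) pairs are the plot-ready data for
    the precision-versus-unmapped scatter.
    """
    items = list(
        metrics_by_label.items()
        if isinstance(metrics_by_label, Mapping)
        else metrics_by_label
    )
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {', '.join(dups)}")
    if not items:
        raise ValueError("at least one labelled metrics record is required")
    rows = []
    for label, m in sorted(items):
        rows.append(
            {
                "label": label,
                "n_simulated": m.n_simulated,
                "n_mapped": m.n_mapped,
                "fraction_unmapped": m.fraction_unmapped,
                "precision_read": m.precision_read if m.n_mapped else math.nan,
                "precision_junction": m.precision_junction if m.n_mapped else math.nan,
            }
        )
    return pd.DataFrame(rows)


def write_mapping_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
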