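"""Event-level benchmarking: matching, precision/recall, intersections.

Reported events are assigned to simulated truth events one-to-one; from the
assignment follow recall (correct / truth events) and precision (correct /
reported events), overall and per event type. Multi-exon skipping may be
credited partially: a reported single-exon skip can consume a truth MES,
which then counts as found once — mirroring benchmarks that treat MES/MEE
as plain exon skipping because most tools cannot label them.

The assignment is a deterministic maximum bipartite matching: a greedy pass
over candidates ordered by (exactness, chrom, start, truth id) is completed
by augmenting paths, so the number of matched events is always maximal and
never depends on input file order.

Cross-tool comparison groups events by their canonical key; the
intersection table generalises a Venn/UpSet decomposition and the consensus
caller keeps one representative per key supported by at least ``k`` tools.
"""

from __future__ import annotations

import math
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .events import ASEvent, EventType, event_key

__all__ = [
    "MatchRules",
    "MatchResult",
    "match_events",
    "precision_recall",
    "intersect_toolsets",
    "consensus_events",
    "ConsensusEvent",
    "plot_intersections",
]


@dataclass(frozen=True)
class MatchRules:
    """Knobs of the matching predicate.

    tolerance: allowed coordinate slack in bases (0 = exact).
    collapse_skipping: treat MES and MEE as ES for type comparison.
    type_strict: require equal (effective) event types.
    partial_mes_credit: let a reported single-block skip consume one block
        of a truth MES/MEE; the truth event counts as found once.
    """

    tolerance: int = 0
    collapse_skipping: bool = True
    type_strict: bool = True
    partial_mes_credit: bool = True

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    def effective_type(self, e: ASEvent) -> EventType:
        if self.collapse_skipping and e.event_type in (EventType.MES, EventType.MEE):
            return EventType.ES
        return e.event_type


@dataclass
class MatchResult:
    pairs: dict[str, str]              # reported event_id -> truth event_id
    n_truth: int
    n_reported: int
    unmatched_truth: list[str]
    unmatched_reported: list[str]
    per_type: dict[EventType, dict[str, int]]  # type -> n_truth/n_reported/n_correct

    @property
    def n_correct(self) -> int:
        return len(self.pairs)


def _check_ids(events: Sequence[ASEvent], what: str) -> None:
    ids = [e.event_id for e in events]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate event_id in {what} set: {', '.join(dup)}")


def _within(a: tuple[int, int], b: tuple[int, int], tol: int) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def _candidates(
    reported: Sequence[ASEvent], truth: Sequence[ASEvent], rules: MatchRules
) -> list[tuple[int, int, int, int]]:
    """All admissible (reported, truth) pairs as (exact, deviation, ri, ti)."""
    out = []
    by_loc: dict[tuple[str, str], list[int]] = {}
    for ti, t in enumerate(truth):
        by_loc.setdefault((t.chrom, t.strand), []).append(ti)
    for ri, r in enumerate(reported):
        r_eff = rules.effective_type(r)
        for ti in by_loc.get((r.chrom, r.strand), []):
            t = truth[ti]
            if rules.type_strict and r_eff != rules.effective_type(t):
                continue
            rb, tb = r.block_coords(), t.block_coords()
            if len(rb) == len(tb) and all(
                _within(a, b, rules.tolerance) for a, b in zip(rb, tb)
            ):
                dev = sum(
                    abs(a[0] - b[0]) + abs(a[1] - b[1]) for a, b in zip(rb, tb)
                )
                out.append((0, dev, ri, ti))
                continue
            if (
                rules.partial_mes_credit
                and len(rb) == 1
                and len(tb) > 1
                and t.event_type in (EventType.MES, EventType.MEE)
                and r_eff == EventType.ES
            ):
                devs = [
                    abs(rb[0][0] - b[0]) + abs(rb[0][1] - b[1])
                    for b in tb
                    if _within(rb[0], b, rules.tolerance)
                ]
                if devs:
                    out.append((1, min(devs), ri, ti))
    return out


def match_events(
    reported: Sequence[ASEvent], truth: Sequence[ASEvent], rules: MatchRules | None = None
) -> MatchResult:
    """Assign reported events to truth events one-to-one (injective both ways).

    Candidate pairs require equal chromosome and strand, effective-type
    equality when ``type_strict``, and block-wise agreement within the
    tolerance (or partial MES credit). Duplicate reports of an
    already-consumed truth event remain unmatched and count as false
    positives. Truth MES events count once regardless of block count.
    """
    rules = rules or MatchRules()
    reported = list(reported)
    truth = list(truth)
    _check_ids(reported, "reported")
    _check_ids(truth, "truth")

    cands = _candidates(reported, truth, rules)
    # deterministic order: exact matches first, then by coordinate deviation,
    # location, truth id, reported id — independent of input file order
    cands.sort(
        key=lambda c: (
            c[0],
            c[1],
            truth[c[3]].chrom,
            truth[c[3]].start,
            truth[c[3]].event_id,
            reported[c[2]].event_id,
        )
    )
    r_match: dict[int, int] = {}
    t_match: dict[int, int] = {}
    adj: dict[int, list[int]] = {}
    for _, _, ri, ti in cands:
        adj.setdefault(ri, []).append(ti)
    for _, _, ri, ti in cands:
        if ri not in r_match and ti not in t_match:
            r_match[ri] = ti
            t_match[ti] = ri

    # augmenting-path completion: the greedy seed is not always a maximum
    # matching once partial credit creates overlapping candidates
    def augment(ri: int, banned: set[int]) -> bool:
        for ti in adj.get(ri, []):
            if ti in banned:
                continue
            banned.add(ti)
            if ti not in t_match or augment(t_match[ti], banned):
                r_match[ri] = ti
                t_match[ti] = ri
                return True
        return False

    for ri in sorted(adj):
        if ri not in r_match:
            augment(ri, set())

    pairs = {
        reported[ri].event_id: truth[ti].event_id for ri, ti in sorted(r_match.items())
    }
    unmatched_truth = sorted(
        truth[ti].event_id for ti in range(len(truth)) if ti not in t_match
    )
    unmatched_reported = sorted(
        reported[ri].event_id for ri in range(len(reported)) if ri not in r_match
    )

    per_type: dict[EventType, dict[str, int]] = {}
    for t in truth:
        d = per_type.setdefault(rules.effective_type(t), Counter())
        d["n_truth"] += 1
    for r in reported:
        d = per_type.setdefault(rules.effective_type(r), Counter())
        d["n_reported"] += 1
    for ri, ti in r_match.items():
        per_type[rules.effective_type(truth[ti])]["n_correct"] += 1
    per_type = {
        k: {
            "n_truth": v.get("n_truth", 0),
            "n_reported": v.get("n_reported", 0),
            "n_correct": v.get("n_correct", 0),
        }
        for k, v in per_type.items()
    }

    return MatchResult(
        pairs=pairs,
        n_truth=len(truth),
        n_reported=len(reported),
        unmatched_truth=unmatched_truth,
        unmatched_reported=unmatched_reported,
        per_type=per_type,
    )


def precision_recall(m: MatchResult) -> pd.DataFrame:
    """Precision/recall table: one ALL row plus one row per event type.

    recall = n_correct / n_truth, precision = n_correct / n_reported; a
    metric is NA when its denominator is zero.
    """

    def row(label, nt, nr, nc):
        return {
            "event_type": label,
            "n_truth": nt,
            "n_reported": nr,
            "n_correct": nc,
            "precision": nc / nr if nr else math.nan,
            "recall": nc / nt if nt else math.nan,
        }

    rows = [row("ALL", m.n_truth, m.n_reported, m.n_correct)]
    for etype in sorted(m.per_type, key=lambda t: t.value):
        d = m.per_type[etype]
        rows.append(row(etype.value, d["n_truth"], d["n_reported"], d["n_correct"]))
    return pd.DataFrame(rows)


def intersect_toolsets(
    events_by_tool: Mapping[str, Sequence[ASEvent]], rules: MatchRules | None = None
) -> pd.DataFrame:
    """UpSet-style exclusive intersection counts over canonical event keys.

    For every non-empty subset of tools, the count of keys found by exactly
    that subset; the counts over all subsets sum to the size of the key
    union (each distinct key is counted in exactly one region).
    """
    rules = rules or MatchRules()
    if len(events_by_tool) < 2:
        raise ValueError("intersection analysis needs >= 2 tool labels")
    membership: dict[tuple, set[str]] = {}
    for label, events in events_by_tool.items():
        for e in events:
            membership.setdefault(
                event_key(e, rules.collapse_skipping), set()
            ).add(label)
    counts = Counter(
        "&".join(sorted(tools)) for tools in membership.values()
    )
    rows = [
        {"subset": subset, "n_tools": subset.count("&") + 1, "count": n}
        for subset, n in counts.items()
    ]
    rows.sort(key=lambda r: (r["n_tools"], r["subset"]))
    return pd.DataFrame(rows, columns=["subset", "n_tools", "count"])


@dataclass(frozen=True)
class ConsensusEvent:
    event: ASEvent
    support: int
    tools: tuple[str, ...]


def consensus_events(
    events_by_tool: Mapping[str, Sequence[ASEvent]],
    k: int,
    rules: MatchRules | None = None,
) -> list[ConsensusEvent]:
    """Events (by canonical key) reported by at least ``k`` of the tools.

    ``k = 1`` is the union, ``k = n_tools`` the full intersection. The
    representative record comes from the lexicographically smallest
    supporting tool label (smallest event_id within that tool).
    """
    rules = rules or MatchRules()
    n = len(events_by_tool)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    reps: dict[tuple, dict[str, ASEvent]] = {}
    for label, events in events_by_tool.items():
        for e in events:
            key = event_key(e, rules.collapse_skipping)
            per_tool = reps.setdefault(key, {})
            if label not in per_tool or e.event_id < per_tool[label].event_id:
                per_tool[label] = e
    out = []
    for key in sorted(reps):
        per_tool = reps[key]
        if len(per_tool) >= k:
            label = min(per_tool)
            out.append(
                ConsensusEvent(
                    event=per_tool[label],
                    support=len(per_tool),
                    tools=tuple(sorted(per_tool)),
                )
            )
    return out


def plot_intersections(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Bar panel of exclusive intersection sizes (optional side output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = table.sort_values("count", ascending=False)
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(t)), 3.5))
    ax.bar(range(len(t)), t["count"], color="#4878b0")
    ax.set_xticks(range(len(t)))
    ax.set_xticklabels(t["subset"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("events found by exactly this tool set")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
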