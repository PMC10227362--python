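import math

import numpy as np
import pytest

from splicebench import (
    ASEvent,
    EventType,
    GenomicInterval,
    MatchRules,
    consensus_events,
    event_key,
    intersect_toolsets,
    match_events,
    precision_recall,
)
from splicebench.eventbench import _candidates

from conftest import random_events


def ev(eid, etype, blocks, strand="+", chrom="chr1", tool="tool"):
    return ASEvent(
        eid, "G", chrom, strand, etype,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks), tool,
    )


def relabel(e, eid, tool="other"):
    return ASEvent(eid, e.gene_name, e.chrom, e.strand, e.event_type, e.blocks, tool)


@pytest.fixture()
def truth4():
    return [
        ev("T1", EventType.ES, [(301, 400)]),
        ev("T2", EventType.IR, [(1201, 1300)]),
        ev("T3", EventType.A5, [(2201, 2250)]),
        ev("T4", EventType.ES, [(3301, 3400)], strand="-"),
    ]


def test_basic_matching(truth4):
    reported = [
        relabel(truth4[0], "R1"),
        relabel(truth4[1], "R2"),
        ev("F1", EventType.ES, [(900_000, 900_100)]),
    ]
    m = match_events(reported, truth4)
    assert m.n_correct == 2
    assert m.unmatched_truth == ["T3", "T4"]
    assert m.unmatched_reported == ["F1"]
    # conservation identities
    assert m.n_correct + len(m.unmatched_reported) == m.n_reported
    assert m.n_correct + len(m.unmatched_truth) == m.n_truth


def test_partial_mes_credit():
    truth = [ev("T1", EventType.MES, [(301, 400), (501, 600)])]
    reported = [ev("R1", EventType.ES, [(301, 400)])]
    m = match_events(reported, truth)
    assert m.n_correct == 1 and m.pairs == {"R1": "T1"}
    # switched off: no match
    m2 = match_events(reported, truth, MatchRules(partial_mes_credit=False))
    assert m2.n_correct == 0


def test_mes_consumed_once():
    truth = [ev("T1", EventType.MES, [(301, 400), (501, 600)])]
    reported = [
        ev("R1", EventType.ES, [(301, 400)]),
        ev("R2", EventType.ES, [(501, 600)]),
    ]
    m = match_events(reported, truth)
    assert m.n_correct == 1
    assert len(m.unmatched_reported) == 1


def test_duplicate_reports_are_false_positives(truth4):
    reported = [relabel(truth4[0], "R1"), relabel(truth4[0], "R2")]
    m = match_events(reported, truth4)
    assert m.n_correct == 1
    assert len(m.unmatched_reported) == 1


def test_type_strictness(truth4):
    wrong_type = ev("R1", EventType.IR, [(301, 400)])
    assert match_events([wrong_type], truth4).n_correct == 0
    loose = match_events([wrong_type], truth4, MatchRules(type_strict=False))
    assert loose.n_correct == 1


def test_strand_must_match(truth4):
    flipped = ev("R1", EventType.ES, [(301, 400)], strand="-")
    assert match_events([flipped], truth4).n_correct == 0


def test_tolerance_matching(truth4):
    near = ev("R1", EventType.ES, [(303, 398)])
    assert match_events([near], truth4).n_correct == 0
    assert match_events([near], truth4, MatchRules(tolerance=2)).n_correct == 1


def test_duplicate_ids_rejected(truth4):
    with pytest.raises(ValueError, match="duplicate"):
        match_events([truth4[0], truth4[0]], truth4)


def test_precision_recall_arithmetic(truth4):
    reported = [relabel(truth4[0], "R1"), relabel(truth4[1], "R2"),
                ev("F1", EventType.ES, [(900_000, 900_100)])]
    table = precision_recall(match_events(reported, truth4))
    allrow = table[table.event_type == "ALL"].iloc[0]
    assert allrow.recall == pytest.approx(2 / 4)
    assert allrow.precision == pytest.approx(2 / 3)
    es = table[table.event_type == "ES"].iloc[0]
    assert es.n_truth == 2 and es.n_reported == 2 and es.n_correct == 1


def test_truth_vs_truth_is_perfect(truth4):
    reported = [relabel(t, f"R{i}") for i, t in enumerate(truth4)]
    table = precision_recall(match_events(reported, truth4))
    assert (table.precision == 1.0).all() and (table.recall == 1.0).all()


def test_empty_reported_gives_na_precision(truth4):
    table = precision_recall(match_events([], truth4))
    allrow = table[table.event_type == "ALL"].iloc[0]
    assert math.isnan(allrow.precision) and allrow.recall == 0.0


def test_symmetry_precision_recall_swap():
    """Swapping reported and truth swaps precision and recall (strict types,
    no partial credit)."""
    rules = MatchRules(partial_mes_credit=False)
    a = [ev(f"A{i}", EventType.ES, [(1000 * i + 1, 1000 * i + 100)]) for i in range(1, 6)]
    b = [relabel(x, f"B{i}") for i, x in enumerate(a[:3])] + [
        ev("B9", EventType.IR, [(50_001, 50_100)])
    ]
    pr_ab = precision_recall(match_events(a, b, rules))
    pr_ba = precision_recall(match_events(b, a, rules))
    row_ab = pr_ab[pr_ab.event_type == "ALL"].iloc[0]
    row_ba = pr_ba[pr_ba.event_type == "ALL"].iloc[0]
    assert row_ab.precision == pytest.approx(row_ba.recall)
    assert row_ab.recall == pytest.approx(row_ba.precision)


def _bruteforce_max_matching(edges, n_r, n_t):
    """Exhaustive maximum bipartite matching size by recursion."""
    adj = {}
    for ri, ti in edges:
        adj.setdefault(ri, set()).add(ti)

    order = sorted(adj)
    memo = {}

    def best(i, used):
        if i == len(order):
            return 0
        key = (i, used)
        if key in memo:
            return memo[key]
        ri = order[i]
        top = best(i + 1, used)  # leave ri unmatched
        for ti in adj[ri]:
            if ti not in used:
                top = max(top, 1 + best(i + 1, used | {ti}))
        memo[key] = top
        return top

    return best(0, frozenset())


def _random_fixture(rng):
    """Random reported/truth sets with duplicates and overlapping MES."""
    truth, reported = [], []
    n_sites = int(rng.integers(2, 6))
    sites = [(1000 * (k + 1) + 1, 1000 * (k + 1) + 100) for k in range(n_sites)]
    for i in range(int(rng.integers(1, 11))):
        if rng.random() < 0.3 and n_sites >= 2:
            k = int(rng.integers(n_sites - 1))
            truth.append(ev(f"T{i}", EventType.MES, [sites[k], sites[k + 1]]))
        else:
            k = int(rng.integers(n_sites))
            truth.append(ev(f"T{i}", EventType.ES, [sites[k]]))
    for i in range(int(rng.integers(0, 11))):
        if rng.random() < 0.2 and n_sites >= 2:
            k = int(rng.integers(n_sites - 1))
            reported.append(ev(f"R{i}", EventType.MES, [sites[k], sites[k + 1]]))
        else:
            k = int(rng.integers(n_sites))
            reported.append(ev(f"R{i}", EventType.ES, [sites[k]]))
    return reported, truth


def test_matching_is_maximum_on_random_fixtures():
    """The deterministic assignment always reaches the exhaustive maximum
    matching size, including adversarial duplicate/partial-credit graphs."""
    rng = np.random.default_rng(42)
    rules = MatchRules()
    for _ in range(100):
        reported, truth = _random_fixture(rng)
        m = match_events(reported, truth, rules)
        edges = [(ri, ti) for _, _, ri, ti in _candidates(reported, truth, rules)]
        expected = _bruteforce_max_matching(edges, len(reported), len(truth))
        assert m.n_correct == expected


def test_matching_deterministic_under_input_order():
    rng = np.random.default_rng(7)
    reported, truth = _random_fixture(rng)
    while not reported:
        reported, truth = _random_fixture(rng)
    m1 = match_events(reported, truth)
    m2 = match_events(list(reversed(reported)), list(reversed(truth)))
    assert m1.pairs == m2.pairs


# --- intersections and consensus -------------------------------------------


@pytest.fixture()
def three_tools():
    e1 = ev("E1", EventType.ES, [(301, 400)])
    e2 = ev("E2", EventType.IR, [(1201, 1300)])
    e3 = ev("E3", EventType.A5, [(2201, 2250)])
    return {
        "A": [relabel(e1, "A1", "A"), relabel(e2, "A2", "A")],
        "B": [relabel(e2, "B1", "B"), relabel(e3, "B2", "B")],
    }


def test_intersection_regions(three_tools):
    table = intersect_toolsets(three_tools)
    counts = dict(zip(table.subset, table["count"]))
    assert counts == {"A": 1, "B": 1, "A&B": 1}
    assert table["count"].sum() == 3  # == |union of keys|


def test_intersection_disjoint_tools():
    a = {"A": [ev("A1", EventType.ES, [(301, 400)])],
         "B": [ev("B1", EventType.ES, [(501, 600)])]}
    table = intersect_toolsets(a)
    assert "A&B" not in set(table.subset)


def test_intersection_needs_two_tools():
    with pytest.raises(ValueError, match=">= 2"):
        intersect_toolsets({"A": []})


def test_intersection_conservation_on_random_tools():
    rng = np.random.default_rng(3)
    pool = random_events(60, seed=33)
    tools = {
        label: [pool[i] for i in rng.choice(60, size=25, replace=False)]
        for label in ("A", "B", "C")
    }
    # event ids must be unique per tool but keys may repeat across tools
    table = intersect_toolsets(tools)
    union = {
        event_key(e) for events in tools.values() for e in events
    }
    assert table["count"].sum() == len(union)


def test_consensus_thresholds(three_tools):
    assert {c.event.event_id for c in consensus_events(three_tools, 2)} == {"A2"}
    assert len(consensus_events(three_tools, 1)) == 3
    full = consensus_events(three_tools, 2)
    assert full[0].support == 2 and full[0].tools == ("A", "B")
    with pytest.raises(ValueError, match="k must be"):
        consensus_events(three_tools, 3)
    with pytest.raises(ValueError, match="k must be"):
        consensus_events(three_tools, 0)


def test_consensus_representative_from_smallest_label(three_tools):
    cons = consensus_events(three_tools, 2)
    assert cons[0].event.source_tool == "A"
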