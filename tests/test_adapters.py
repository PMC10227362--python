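import pytest

from splicebench import (
    EventType,
    GeneIndex,
    event_key,
    load_preset,
    normalize_batch,
    normalize_flanking_exons,
    normalize_junctions,
    normalize_skipped_exon,
    render_to_dialect,
    simulate_annotation,
    truncate_annotation,
)
from splicebench.adapters import (
    NotNormalizableError,
    NovelJunctionError,
    RawEventRecord,
    UnresolvedGeneError,
    read_dialect_tsv,
    write_dialect_tsv,
)

from conftest import make_gene


def rec(dialect, **kw):
    kw.setdefault("chrom", "chr1")
    kw.setdefault("strand", "+")
    return RawEventRecord(dialect=dialect, **kw)


@pytest.fixture()
def toy_index(toy_gene, toy_gene4):
    return GeneIndex([toy_gene, toy_gene4])


# --- skipped_exon dialect ---------------------------------------------------


def test_skipped_exon_identity(toy_index):
    e = normalize_skipped_exon(rec("skipped_exon", exons=((301, 400),)), toy_index)
    assert e.event_type == EventType.ES
    assert e.block_coords() == ((301, 400),)
    assert e.gene_name == "G1"


def test_skipped_exon_multiple_becomes_mes(toy_index):
    e = normalize_skipped_exon(
        rec("skipped_exon", exons=((301, 400), (501, 600))), toy_index
    )
    assert e.event_type == EventType.MES
    assert e.block_coords() == ((301, 400), (501, 600))


def test_skipped_exon_claimed_type_honoured(toy_index):
    e = normalize_skipped_exon(
        rec("skipped_exon", exons=((201, 300),), claimed_type=EventType.IR), toy_index
    )
    assert e.event_type == EventType.IR


def test_skipped_exon_intergenic_strict_vs_lenient(toy_index):
    intergenic = rec("skipped_exon", exons=((900_000, 900_100),))
    with pytest.raises(UnresolvedGeneError):
        normalize_skipped_exon(intergenic, toy_index, strict=True)
    e = normalize_skipped_exon(intergenic, toy_index, strict=False)
    assert e.gene_name == "NA"


# --- flanking_exons dialect -------------------------------------------------


def test_flanking_single_exon_between(toy_index):
    e = normalize_flanking_exons(
        rec("flanking_exons", upstream=(101, 200), downstream=(501, 600)), toy_index
    )
    assert e.event_type == EventType.ES
    assert e.block_coords() == ((301, 400),)


def test_flanking_two_exons_between_is_mes(toy_index):
    e = normalize_flanking_exons(
        rec("flanking_exons", upstream=(10101, 10200), downstream=(10701, 10800)),
        toy_index,
    )
    assert e.event_type == EventType.MES
    assert e.block_coords() == ((10301, 10400), (10501, 10600))


def test_flanking_adjacent_exons_not_normalizable(toy_index):
    with pytest.raises(NotNormalizableError, match="intron retention"):
        normalize_flanking_exons(
            rec("flanking_exons", upstream=(101, 200), downstream=(301, 400)), toy_index
        )


def test_flanking_unknown_exons_unresolved(toy_index):
    with pytest.raises(UnresolvedGeneError):
        normalize_flanking_exons(
            rec("flanking_exons", upstream=(105, 200), downstream=(501, 600)), toy_index
        )


# --- junction dialect -------------------------------------------------------


def test_junction_skip_becomes_es(toy_index):
    """Junction (200, 501) skips the middle exon of the toy gene."""
    e = normalize_junctions(
        rec("junction", anchor=(101, 200), junctions=((200, 501),)), toy_index
    )
    assert e.event_type == EventType.ES
    assert e.block_coords() == ((301, 400),)


def test_junction_skip_two_exons_becomes_mes(toy_index):
    e = normalize_junctions(
        rec("junction", anchor=(10101, 10200), junctions=((10200, 10701),)), toy_index
    )
    assert e.event_type == EventType.MES
    assert e.block_coords() == ((10301, 10400), (10501, 10600))


@pytest.fixture()
def a5_gene_pair():
    """Same genomic geometry on both strands: intron [201,300] with the
    genomic-left donor moved to base 250 in the alternative isoform."""
    plus = make_gene(
        "GP", "chrA", "+", [(101, 200), (301, 400)],
        {"GP.t2": [(101, 250), (301, 400)]},
    )
    minus = make_gene(
        "GM", "chrB", "-", [(101, 200), (301, 400)],
        {"GM.t2": [(101, 250), (301, 400)]},
    )
    return GeneIndex([plus, minus])


def test_junction_shifted_left_boundary_is_a5_on_plus(a5_gene_pair):
    e = normalize_junctions(
        rec("junction", chrom="chrA", anchor=(101, 250), junctions=((250, 301),)),
        a5_gene_pair,
    )
    assert e.event_type == EventType.A5
    assert e.block_coords() == ((201, 250),)


def test_junction_shifted_left_boundary_is_a3_on_minus(a5_gene_pair):
    """Mirror of the previous case: identical genomic geometry, '-' strand,
    so the moved splice site is the acceptor."""
    e = normalize_junctions(
        rec("junction", chrom="chrB", strand="-", anchor=(101, 250),
            junctions=((250, 301),)),
        a5_gene_pair,
    )
    assert e.event_type == EventType.A3
    assert e.block_coords() == ((201, 250),)


@pytest.fixture()
def a3_index():
    gene = make_gene(
        "GA", "chr1", "+", [(101, 200), (301, 400)],
        {"GA.t2": [(101, 200), (351, 400)]},
    )
    return GeneIndex([gene])


def test_junction_shifted_right_boundary_is_a3_on_plus(a3_index):
    """Acceptor moved from 301 to 351: alternative part is [301, 350]."""
    e = normalize_junctions(
        rec("junction", anchor=(351, 400), junctions=((200, 351),)), a3_index
    )
    assert e.event_type == EventType.A3
    assert e.block_coords() == ((301, 350),)


def test_junction_retained_flag_is_ir():
    gene = make_gene(
        "GI", "chr1", "+", [(101, 200), (301, 400)], {"GI.t2": [(101, 400)]}
    )
    e = normalize_junctions(
        rec("junction", anchor=(101, 400), retained=True), GeneIndex([gene])
    )
    assert e.event_type == EventType.IR
    assert e.block_coords() == ((201, 300),)


def test_junction_unannotated_anchor_rejected_as_novel(toy_index):
    with pytest.raises(NovelJunctionError, match="anchor"):
        normalize_junctions(
            rec("junction", anchor=(101, 250), junctions=((250, 301),)), toy_index
        )


def test_junction_matching_no_splice_site_is_novel(toy_index):
    with pytest.raises(NovelJunctionError, match="no annotated splice site"):
        normalize_junctions(
            rec("junction", anchor=(101, 200), junctions=((250, 471),)), toy_index
        )


def test_junction_matching_annotated_intron_is_no_event(toy_index):
    with pytest.raises(NotNormalizableError, match="no event"):
        normalize_junctions(
            rec("junction", anchor=(101, 200), junctions=((200, 301),)), toy_index
        )


# --- batch ------------------------------------------------------------------


def test_batch_cross_dialect_same_key(toy_index):
    records = [
        rec("skipped_exon", exons=((301, 400),)),
        rec("flanking_exons", upstream=(101, 200), downstream=(501, 600)),
        rec("junction", anchor=(101, 200), junctions=((200, 501),)),
    ]
    events, report = normalize_batch(records, toy_index, "strict", "t")
    assert len(events) == 3 and len(report) == 0
    keys = {event_key(e) for e in events}
    assert len(keys) == 1


def test_batch_empty_input(toy_index):
    events, report = normalize_batch([], toy_index)
    assert events == [] and len(report) == 0


def test_batch_lenient_collects_rejections(toy_index):
    records = [
        rec("skipped_exon", exons=((301, 400),)),
        rec("flanking_exons", upstream=(900_000, 900_100), downstream=(901_000, 901_100)),
    ]
    events, report = normalize_batch(records, toy_index, "lenient", "t")
    assert len(events) == 1
    assert report.counts == {"unresolved-gene": 1}


def test_batch_lenient_intergenic_skipped_exon_still_emitted(toy_index):
    records = [rec("skipped_exon", exons=((900_000, 900_100),))]
    events, report = normalize_batch(records, toy_index, "lenient", "t")
    assert len(events) == 1 and events[0].gene_name == "NA"
    assert report.counts == {"unresolved-gene": 1}


def test_batch_strict_raises(toy_index):
    records = [rec("flanking_exons", upstream=(101, 200), downstream=(301, 400))]
    with pytest.raises(NotNormalizableError):
        normalize_batch(records, toy_index, "strict")


def test_batch_event_ids_unique_per_tool(toy_index):
    records = [rec("skipped_exon", exons=((301, 400),))] * 3
    events, _ = normalize_batch(records, toy_index, "lenient", "toolX")
    assert len({e.event_id for e in events}) == 3
    assert all(e.source_tool == "toolX" for e in events)


# --- cross-dialect equivalence on simulated truth ---------------------------


@pytest.mark.parametrize("preset", ["S0", "S1"])
def test_cross_dialect_equivalence_on_simulation(preset):
    """Every representable rendering of every truth event normalises back to
    the truth event's canonical key."""
    cfg = load_preset(preset, n_genes=80, seed=17)
    models, truth = simulate_annotation(cfg)
    by_gene = {g.gene_id: g for g in models}
    index = GeneIndex(models)
    checked = 0
    for r in truth.records:
        for dialect in ("skipped_exon", "flanking_exons", "junction"):
            raw = render_to_dialect(r.event, by_gene[r.gene_id], dialect)
            if raw is None:
                continue
            events, report = normalize_batch([raw], index, "strict", dialect)
            assert event_key(events[0]) == event_key(r.event), (dialect, r.event)
            checked += 1
    assert checked > len(truth)  # every event representable in >= 1 dialect


def test_normalized_blocks_stay_inside_gene_span():
    cfg = load_preset("S0", n_genes=60, seed=19)
    models, truth = simulate_annotation(cfg)
    by_gene = {g.gene_id: g for g in models}
    index = GeneIndex(models)
    spans = {g.gene_name: g.span for g in models}
    for r in truth.records:
        raw = render_to_dialect(r.event, by_gene[r.gene_id], "junction")
        if raw is None:
            continue
        events, _ = normalize_batch([raw], index, "strict", "t")
        span = spans[events[0].gene_name]
        for b in events[0].blocks:
            assert span.start <= b.start and b.end <= span.end


def test_truncated_annotation_degrades_annotation_dependent_types():
    """With main-only annotation, junction-dialect IR and A5/A3 records are
    rejected as novel junctions while exon skipping survives."""
    cfg = load_preset("S0", n_genes=80, seed=23)
    models, truth = simulate_annotation(cfg)
    by_gene = {g.gene_id: g for g in models}
    index = GeneIndex(truncate_annotation(models))
    outcomes = {}
    for r in truth.records:
        raw = render_to_dialect(r.event, by_gene[r.gene_id], "junction")
        if raw is None:
            continue
        events, report = normalize_batch([raw], index, "lenient", "t")
        ok = bool(events) and event_key(events[0]) == event_key(r.event)
        outcomes.setdefault(r.event.event_type, []).append(
            (ok, report.counts.get("novel-junction", 0))
        )
    assert all(ok for ok, _ in outcomes[EventType.ES])
    for etype in (EventType.IR, EventType.A5, EventType.A3):
        assert not any(ok for ok, _ in outcomes[etype])
        assert sum(n for _, n in outcomes[etype]) == len(outcomes[etype])


def test_mirror_symmetry_preserves_splice_site_labels():
    """Reflecting gene and records through a coordinate pivot with strand
    flip leaves A5/A3 designations unchanged (they are strand-relative)."""
    pivot = 2_000_000

    def reflect(iv):
        return (pivot - iv[1], pivot - iv[0])

    gene = make_gene(
        "GP", "chrA", "+", [(101, 200), (301, 400)],
        {"GP.t2": [(101, 250), (301, 400)]},
    )
    mirrored = make_gene(
        "GP", "chrA", "-",
        [reflect(x) for x in [(101, 200), (301, 400)]],
        {"GP.t2": [reflect(x) for x in [(101, 250), (301, 400)]]},
    )
    fwd = normalize_junctions(
        rec("junction", chrom="chrA", anchor=(101, 250), junctions=((250, 301),)),
        GeneIndex([gene]),
    )
    d, a = 250, 301  # mirrored junction swaps and reflects the two flanks
    back = normalize_junctions(
        rec("junction", chrom="chrA", strand="-", anchor=reflect((101, 250)),
            junctions=((pivot - a, pivot - d),)),
        GeneIndex([mirrored]),
    )
    assert fwd.event_type == back.event_type == EventType.A5
    assert back.block_coords() == (reflect(fwd.block_coords()[0]),)


# --- dialect TSV round trips ------------------------------------------------


@pytest.mark.parametrize("dialect", ["skipped_exon", "flanking_exons", "junction"])
def test_dialect_tsv_roundtrip(tmp_path, dialect):
    records = {
        "skipped_exon": [
            rec("skipped_exon", exons=((301, 400),)),
            rec("skipped_exon", exons=((301, 400), (501, 600)),
                claimed_type=EventType.MES, gene_hint="G1"),
        ],
        "flanking_exons": [
            rec("flanking_exons", upstream=(101, 200), downstream=(501, 600)),
        ],
        "junction": [
            rec("junction", anchor=(101, 200), junctions=((200, 501),)),
            rec("junction", anchor=(101, 400), retained=True),
        ],
    }[dialect]
    p = tmp_path / f"{dialect}.tsv"
    write_dialect_tsv(records, dialect, p)
    back = read_dialect_tsv(p, dialect)
    assert back == records


def test_junction_record_rejects_inverted_pair():
    with pytest.raises(ValueError, match="donor_end"):
        rec("junction", anchor=(101, 200), junctions=((501, 200),))
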