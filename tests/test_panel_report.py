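"""Panel triage, SV frequency database, and cohort aggregation."""

import pytest

from lorediag.core import InvalidArgumentError
from lorediag.panel_report import (
    FindingsRecord,
    GenePanel,
    affected_span,
    aggregate_cohort,
    annotate_frequency,
    build_sv_db,
    filter_svs_by_panel,
    filter_unique,
    render_report,
    table2_fixture,
)
from lorediag.sv_reconstruction import DerivativeChromosome, Junction

CHROMS = {"chr1": 1_000_000}


def derivative(segments, junctions=1, circular=False):
    return DerivativeChromosome(
        segments=segments,
        circular=circular,
        motif_label="DEL",
        mosaic_fraction=None,
        junctions_used=[
            Junction(("chr1", s, "+"), ("chr1", s + 1, "-"), [f"r{i}"])
            for i, s in enumerate(range(junctions))
        ],
    )


PANEL = GenePanel("NDD", {"GENE1": [("chr1", 100_000, 110_000)]})


def test_table2_fixture_counts():
    records = table2_fixture()
    assert len(records) == 17
    assert len({r.individual_id for r in records}) == 13
    other = [r for r in records if r.variant_type == "OTHER"]
    assert len(other) == 1
    assert "isodisomy" in other[0].variant_id


def test_large_sv_kept_genome_wide():
    # 15 kb deletion far from the panel
    der = derivative([("chr1", 0, 500_000, "+"), ("chr1", 515_000, 1_000_000, "+")])
    kept, dropped = filter_svs_by_panel([der], PANEL, CHROMS)
    assert kept == [der] and dropped == []
    assert der.annotations["triage"] == "genome_wide_tier"


def test_small_sv_kept_only_inside_panel():
    inside = derivative([("chr1", 0, 105_000, "+"), ("chr1", 107_000, 1_000_000, "+")])
    outside = derivative([("chr1", 0, 600_000, "+"), ("chr1", 602_000, 1_000_000, "+")])
    kept, dropped = filter_svs_by_panel([inside, outside], PANEL, CHROMS)
    assert kept == [inside]
    assert dropped == [(outside, "sub_threshold_outside_panel")]


def test_many_breakpoint_event_always_kept():
    der = derivative(
        [("chr1", 0, 600_000, "+"), ("chr1", 604_000, 1_000_000, "+")], junctions=5
    )
    kept, _ = filter_svs_by_panel([der], PANEL, CHROMS)
    assert kept == [der]
    assert der.annotations["triage"] == "breakpoint_count"


def test_empty_panel_drops_small_svs_with_warning():
    der = derivative([("chr1", 0, 600_000, "+"), ("chr1", 602_000, 1_000_000, "+")])
    kept, dropped = filter_svs_by_panel([der], None, CHROMS)
    assert kept == [] and dropped[0][1] == "sub_threshold_no_panel"


def test_filtering_is_idempotent():
    ders = [
        derivative([("chr1", 0, 500_000, "+"), ("chr1", 515_000, 1_000_000, "+")]),
        derivative([("chr1", 0, 600_000, "+"), ("chr1", 602_000, 1_000_000, "+")]),
    ]
    kept1, _ = filter_svs_by_panel(ders, PANEL, CHROMS)
    kept2, _ = filter_svs_by_panel(kept1, PANEL, CHROMS)
    assert kept1 == kept2


def test_affected_span_weights_cn_and_inversions():
    # balanced 20 kb inversion: span = inverted length
    inv = derivative(
        [("chr1", 0, 40_000, "+"), ("chr1", 40_000, 60_000, "-"),
         ("chr1", 60_000, 1_000_000, "+")]
    )
    assert affected_span(inv, CHROMS) == 20_000


def junction_at(pos_a, pos_b, reads=("r1",)):
    return Junction(("chr1", pos_a, "+"), ("chr1", pos_b, "-"), list(reads))


def test_db_frequency_counts_distinct_samples():
    cohort = {f"s{i}": [junction_at(100, 900)] for i in range(50)}
    cohort |= {f"t{i}": [] for i in range(50)}
    db = build_sv_db(cohort)
    assert db.n_samples == 100
    assert db.frequency(junction_at(100, 900)) == pytest.approx(0.50)
    assert db.frequency(junction_at(100_000, 200_000)) == 0.0


def test_db_jittered_duplicates_form_one_signature():
    cohort = {f"s{i}": [junction_at(100 + d, 900 - d)] for i, d in enumerate([-3, 0, 4])}
    db = build_sv_db(cohort, pos_tolerance=50)
    assert len(db.entries) == 1
    assert db.frequency(junction_at(101, 899)) == pytest.approx(1.0)


def test_filter_unique_keeps_rare_and_query_private():
    cohort = {f"s{i}": [junction_at(100, 900)] for i in range(50)}
    cohort |= {"q": [junction_at(5_000, 9_000)]} | {f"t{i}": [] for i in range(49)}
    db = build_sv_db(cohort)
    query = [junction_at(100, 900), junction_at(5_000, 9_000)]
    kept = filter_unique(query, db, query_sample="q", max_frequency=0.05)
    assert kept == [junction_at(5_000, 9_000)]
    annotated = annotate_frequency(query, db)
    assert annotated[0][1] == pytest.approx(0.5)


def test_aggregate_cohort_yields():
    records = [
        FindingsRecord(f"ind{i}", f"v{i}", "SNV/INDEL", "G", "P") for i in range(29)
    ]
    summary = aggregate_cohort(records, 100)
    assert summary.diagnostic_yield_pct == pytest.approx(29.0)
    assert aggregate_cohort([], 100).diagnostic_yield_pct == 0.0


def test_individual_counts_once_under_best_classification():
    records = [
        FindingsRecord("ind1", "v1", "SV", "G", "P"),
        FindingsRecord("ind1", "v2", "STR", "G", "VUS_hot"),
    ]
    summary = aggregate_cohort(records, 10)
    assert summary.individuals_by_best_class == {"P": 1}
    assert summary.hot_vus_yield_pct == 0.0


def test_aggregation_invariant_to_order_and_duplicates():
    records = table2_fixture()
    s1 = aggregate_cohort(records, 100)
    s2 = aggregate_cohort(records[::-1] + records, 100)
    assert s1 == s2


def test_unknown_classification_rejected():
    with pytest.raises(InvalidArgumentError):
        FindingsRecord("i", "v", "SV", "G", "pathogenic-ish")
    with pytest.raises(InvalidArgumentError):
        FindingsRecord("i", "v", "SV", "G", "P", reported=False)  # NR only for LB/B


def test_render_report_sections_and_determinism():
    records = table2_fixture()
    summary = aggregate_cohort(records, 100)
    text = render_report(summary, records)
    assert text == render_report(summary, records)
    clinical = text.split("## Clinical findings (reported)")[1].split("## Audit")[0]
    n_nr = sum(1 for r in records if not r.reported)
    assert n_nr == 5
    clinical_rows = [l for l in clinical.strip().splitlines()[1:] if l]
    assert len(clinical_rows) == len(records) - n_nr
    audit = text.split("## Audit section")[1]
    assert sum(1 for l in audit.splitlines() if l.startswith(("RD_", "NA_"))) == 17


def test_per_type_tallies_match_reference_grouping():
    summary = aggregate_cohort(table2_fixture(), 100)
    assert summary.per_type_individuals == {
        "SNV/INDEL": 2, "SV": 7, "STR": 3, "OTHER": 1,
    }
    assert sum(summary.per_type_variants.values()) == 17
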