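"""Junction algebra, clustering, copy number, walks, and mosaic arithmetic."""

import numpy as np
import pytest

import lorediag as ld
from lorediag.core import AlignmentBlock, ReadAlignment
from lorediag.sv_reconstruction import (
    DerivativeChromosome,
    Junction,
    classify_rearrangement,
    cluster_junctions,
    estimate_mosaic_fraction,
    extract_junctions,
    junctions_to_breakend_vcf,
    render_subway,
    segment_copy_number,
)


def chimeric_read(blocks, read_id="r"):
    total = max(b[4] for b in blocks)
    return ReadAlignment(
        read_id=read_id,
        seq="A" * total,
        blocks=[
            AlignmentBlock(chrom, start, strand, cigar, rs, re)
            for chrom, start, strand, cigar, re, rs in [
                (b[0], b[1], b[2], b[5], b[4], b[3]) for b in blocks
            ]
        ],
    )


def split_read(read_id, left, right):
    """Two-block read; left/right = (chrom, ref_start, strand, cigar)."""
    return ReadAlignment(
        read_id=read_id,
        seq="A" * 200,
        blocks=[
            AlignmentBlock(*left, read_start=0, read_end=100),
            AlignmentBlock(*right, read_start=100, read_end=200),
        ],
    )


def test_deletion_junction_orientation():
    read = split_read(
        "del",
        ("chr1", 900, "+", [("M", 100), ("S", 100)]),
        ("chr1", 2_000, "+", [("S", 100), ("M", 100)]),
    )
    (j,) = extract_junctions([read])
    assert j.end_a == ("chr1", 1_000, "+")
    assert j.end_b == ("chr1", 2_000, "-")


def test_inversion_junction_has_like_orientations():
    read = split_read(
        "inv",
        ("chr1", 900, "+", [("M", 100), ("S", 100)]),
        ("chr1", 3_000, "-", [("S", 100), ("M", 100)]),
    )
    (j,) = extract_junctions([read])
    assert {j.end_a[2], j.end_b[2]} == {"+"}
    assert {j.end_a[1], j.end_b[1]} == {1_000, 3_100}


def test_empty_input_yields_empty_junctions():
    assert extract_junctions([]) == []


def test_cluster_six_identical_junctions():
    raw = [
        Junction(("chr1", 100, "+"), ("chr1", 900, "-"), [f"r{i}"]) for i in range(6)
    ]
    kept, dropped = cluster_junctions(raw, min_support=3)
    assert len(kept) == 1 and dropped == 0
    assert kept[0].n_support == 6


def test_cluster_below_min_support_dropped_but_counted():
    raw = [Junction(("chr1", 100, "+"), ("chr1", 900, "-"), [f"r{i}"]) for i in range(2)]
    kept, dropped = cluster_junctions(raw, min_support=3)
    assert kept == [] and dropped == 1


def test_cluster_jittered_positions_merge_to_median():
    jit = [-3, -1, 0, 1, 2, 3]
    raw = [
        Junction(("chr1", 500 + d, "+"), ("chr1", 900 - d, "-"), [f"r{i}"])
        for i, d in enumerate(jit)
    ]
    kept, _ = cluster_junctions(raw, pos_tolerance=10, min_support=3)
    assert len(kept) == 1
    assert kept[0].end_a[1] == int(np.median([500 + d for d in jit]))


def test_uniform_diploid_copy_number(diploid_sample):
    segs = segment_copy_number(diploid_sample.reads, {"chr1": 100_000})
    assert all(abs(s.copy_number - 2) < 0.4 for s in segs)


def test_heterozygous_deletion_copy_number():
    ref = ld.make_reference(1, 100_000, seed=5)
    plan = ld.DerivativePlan([("chr1", 0, 40_000, "+"), ("chr1", 60_000, 100_000, "+")])
    haps = [ld.HaplotypeSpec(1, weight=0.5), ld.HaplotypeSpec(2, weight=0.5)]
    s = ld.simulate_sample(
        ref, haps, [plan],
        ld.SimulationConfig(coverage=30, seed=2, read_length_median=2000,
                            read_length_n50=3500),
    )
    segs = segment_copy_number(
        s.reads, {"chr1": 100_000}, boundaries={"chr1": [40_000, 60_000]}
    )
    by_start = {s.start: s for s in segs}
    assert abs(by_start[40_000].copy_number - 1) < 0.35
    assert abs(by_start[0].copy_number - 2) < 0.35


def test_zero_depth_genome_is_error():
    with pytest.raises(ld.core.LorediagError):
        segment_copy_number([], {"chr1": 10_000})


def test_bin_size_validation():
    with pytest.raises(ld.core.InvalidArgumentError):
        segment_copy_number([], {"chr1": 10_000}, bin_size=50)


def test_no_junctions_yields_reference_derivative():
    der = ld.build_derivative([], None, ("chr1", 0, 1), {"chr1": 50_000})
    assert der.motif_label == "REFERENCE"
    assert der.segments == [("chr1", 0, 50_000, "+")]


def word(segments, circular=False, junctions=1):
    return DerivativeChromosome(
        segments=segments,
        circular=circular,
        motif_label="COMPLEX",
        mosaic_fraction=None,
        junctions_used=[
            Junction(("chr1", 1, "+"), ("chr1", 2, "-"), ["r"]) for _ in range(junctions)
        ],
    )


@pytest.mark.parametrize(
    "segments,circular,expected",
    [
        ([("chr1", 0, 40, "+"), ("chr1", 60, 100, "+")], False, "DEL"),
        ([("chr1", 0, 60, "+"), ("chr1", 30, 100, "+")], False, "DUP"),
        (
            [("chr1", 0, 40, "+"), ("chr1", 40, 60, "-"), ("chr1", 60, 100, "+")],
            False,
            "INV",
        ),
        ([("chr1", 10, 90, "+")], True, "RING"),
        (
            [("chr1", 20, 100, "-"), ("chr1", 10, 60, "+")],
            False,
            "DEL-INV-DUP",
        ),
    ],
)
def test_classification_from_segment_word(segments, circular, expected):
    der = word(segments, circular=circular)
    assert classify_rearrangement(der, None, {"chr1": 100, "chr2": 100}) == expected


def test_translocation_classification():
    der = word([("chr1", 0, 60, "+"), ("chr2", 30, 100, "+")])
    assert (
        classify_rearrangement(der, None, {"chr1": 100, "chr2": 100})
        == "UNBALANCED_TRANSLOCATION"
    )


def test_inversion_with_breakpoint_deletion_annotated():
    der = word(
        [("chr1", 0, 40, "+"), ("chr1", 40, 60, "-"), ("chr1", 68, 100, "+")],
        junctions=2,
    )
    assert classify_rearrangement(der, None, {"chr1": 100}) == "INV"
    assert der.annotations["breakpoint_deletion_bp"] == 8


def test_mosaic_fraction_values():
    est = estimate_mosaic_fraction(6, 28)
    assert est.percent == 42  # truncated, not rounded (2*6/28 = 42.86%)
    assert est.fraction == pytest.approx(2 * 6 / 28)
    assert estimate_mosaic_fraction(14, 28).percent == 100
    assert estimate_mosaic_fraction(20, 28).fraction == 1.0  # capped
    assert estimate_mosaic_fraction(0, 28).percent == 0
    assert estimate_mosaic_fraction(3, 0) is None  # no-call


def test_mosaic_estimator_unbiased_over_binomial_replicates():
    rng = np.random.default_rng(1)
    estimates = [
        estimate_mosaic_fraction(int(rng.binomial(60, 0.2)), 60).fraction
        for _ in range(200)
    ]
    assert abs(float(np.mean(estimates)) - 0.4) < 0.03


def test_breakend_vcf_export_is_readable(tmp_path):
    import pysam

    junctions = [
        Junction(("chr1", 1_000, "+"), ("chr1", 2_000, "-"), ["r1", "r2", "r3"]),
        Junction(("chr1", 3_000, "-"), ("chr2", 500, "-"), ["r4", "r5", "r6"]),
    ]
    path = str(tmp_path / "bnd.vcf")
    junctions_to_breakend_vcf(junctions, {"chr1": 10_000, "chr2": 10_000}, path)
    with pysam.VariantFile(path) as vf:
        records = list(vf)
    assert len(records) == 4
    assert all(r.info["SVTYPE"] == "BND" for r in records)
    assert {r.info["MATEID"] for r in records} == {r.id for r in records}


def test_subway_rendering_is_deterministic():
    der = word([("chr1", 0, 40, "+"), ("chr1", 60, 100, "+")])
    assert render_subway(der) == render_subway(der)
    assert "chr1:0-40(+)" in render_subway(der)
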