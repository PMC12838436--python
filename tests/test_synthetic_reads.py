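"""Generator properties: determinism, coverage, junction dosage, methylation."""

import math

import pytest

import lorediag as ld
from lorediag.core import mean_depth
from lorediag.methylation import MethylRegion, region_methylation_fraction
from lorediag.samio import load_sam, write_sam
from lorediag.synthetic_reads import build_tract


def test_reference_length_and_determinism(tmp_path):
    ref = ld.make_reference(1, 100_000, 0.41, seed=7)
    assert len(ref["chr1"]) == 100_000
    assert ref == ld.make_reference(1, 100_000, 0.41, seed=7)
    # byte-identical FASTA across runs
    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    ld.write_fasta(ld.make_reference(2, 50_000, seed=7), str(p1))
    ld.write_fasta(ld.make_reference(2, 50_000, seed=7), str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_reference_gc_within_binomial_bounds():
    n, p = 20_000, 0.6
    ref = ld.make_reference(1, n, p, seed=1)
    gc = sum(ref["chr1"].count(b) for b in "GC")
    sd = math.sqrt(n * p * (1 - p))
    assert abs(gc - n * p) < 3 * sd


def test_reference_argument_validation():
    with pytest.raises(ld.core.InvalidArgumentError):
        ld.make_reference(1, 0, 0.5)
    with pytest.raises(ld.core.InvalidArgumentError):
        ld.make_reference(1, 1000, 1.2)


def test_lognormal_parameters_match_median_and_n50():
    cfg = ld.SimulationConfig()
    assert math.isclose(math.exp(cfg.lognormal_mu), 5_000)
    # N50 of a log-normal is the median of its length-biased version
    assert math.isclose(
        math.exp(cfg.lognormal_mu + cfg.lognormal_sigma**2), 16_000, rel_tol=1e-9
    )


def test_coverage_conservation(diploid_sample):
    total = sum(len(r.seq) for r in diploid_sample.reads)
    assert abs(total / 100_000 - 30) / 30 < 0.10
    # depth is uniform along the chromosome (no edge ramps)
    depths = [
        mean_depth(diploid_sample.reads, "chr1", i * 10_000, (i + 1) * 10_000)
        for i in range(10)
    ]
    assert all(abs(d - 30) / 30 < 0.35 for d in depths)


def test_simulation_determinism():
    ref = ld.make_reference(1, 30_000, seed=2)
    haps = [ld.HaplotypeSpec(1, weight=0.5), ld.HaplotypeSpec(2, weight=0.5)]
    cfg = ld.SimulationConfig(coverage=10, seed=9)
    s1 = ld.simulate_sample(ref, haps, config=cfg)
    s2 = ld.simulate_sample(ref, haps, config=cfg)
    assert [r.seq for r in s1.reads] == [r.seq for r in s2.reads]
    assert s1.truth.equals(s2.truth)


def test_identity_plan_has_no_junction_reads(diploid_sample):
    assert not diploid_sample.truth["has_junction"].any()


def test_full_fraction_junction_forced():
    """With cell_fraction 1.0 every derivative read overlapping the breakpoint
    by a sufficient anchor carries a split alignment."""
    ref = ld.make_reference(1, 60_000, seed=4)
    plan = ld.DerivativePlan(
        [("chr1", 0, 20_000, "+"), ("chr1", 40_000, 60_000, "+")], cell_fraction=1.0
    )
    haps = [ld.HaplotypeSpec(1, weight=0.5), ld.HaplotypeSpec(2, weight=0.5)]
    s = ld.simulate_sample(
        ref, haps, [plan], ld.SimulationConfig(coverage=20, seed=5)
    )
    truth = s.truth.set_index("read_id")
    for read in s.reads:
        row = truth.loc[read.read_id]
        if row["donor"] != "der1":
            assert len(read.blocks) == 1
            continue
        # derivative coordinates: junction at molecule offset 20_000
        lo, hi = row["start"], row["start"] + row["length"]
        if lo + 100 <= 20_000 <= hi - 100:
            assert len(read.blocks) == 2


def test_junction_dosage_converges_to_half_cell_fraction():
    """Junction reads among breakpoint-spanning reads ~ Binomial(f/2)."""
    ref = ld.make_reference(1, 100_000, seed=5)
    f = 0.4
    plan = ld.DerivativePlan(
        [("chr1", 0, 40_000, "+"), ("chr1", 60_000, 100_000, "+")], cell_fraction=f
    )
    haps = [ld.HaplotypeSpec(1, weight=0.5), ld.HaplotypeSpec(2, weight=0.5)]
    s = ld.simulate_sample(ref, haps, [plan], ld.SimulationConfig(coverage=60, seed=6))
    junctions, _ = ld.cluster_junctions(ld.extract_junctions(s.reads), min_support=1)
    assert len(junctions) == 1
    n_span = ld.count_spanning_reads(s.reads, junctions[0])
    frac = junctions[0].n_support / n_span
    sd = math.sqrt((f / 2) * (1 - f / 2) / n_span)
    assert abs(frac - f / 2) < 4 * sd


def test_methylation_fidelity_per_haplotype():
    ref = ld.make_reference(1, 20_000, seed=1)
    haps = [
        ld.HaplotypeSpec(1, weight=0.5, methyl_level=0.9),
        ld.HaplotypeSpec(2, weight=0.5, methyl_level=0.1),
    ]
    s = ld.simulate_sample(
        ref, haps, config=ld.SimulationConfig(coverage=30, seed=2, methyl_call_noise=0.03)
    )
    region = MethylRegion("R", "R", "chr1", 2_000, 18_000)
    f1, n1 = region_methylation_fraction(s.reads, region, haplotype_filter=1)
    f2, n2 = region_methylation_fraction(s.reads, region, haplotype_filter=2)
    assert n1 > 200 and n2 > 200
    assert abs(f1 - 0.9) < 0.05
    assert abs(f2 - 0.1) < 0.05


def test_build_tract_interruptions_preserve_unit_length():
    tract = build_tract("CAG", 5, [(2, "CAT")])
    assert tract == "CAGCAGCATCAGCAG"
    with pytest.raises(ld.core.InvalidArgumentError):
        build_tract("CAG", 5, [(2, "CATT")])


def test_plan_bounds_error():
    ref = ld.make_reference(1, 10_000, seed=1)
    plan = ld.DerivativePlan([("chr1", 0, 20_000, "+")], replaces_haplotype=1)
    haps = [ld.HaplotypeSpec(1, weight=1.0)]
    with pytest.raises(ld.core.BoundsError):
        ld.simulate_sample(ref, haps, [plan], ld.SimulationConfig(coverage=5, seed=1))


def test_haplotype_weights_must_sum_to_one():
    ref = ld.make_reference(1, 10_000, seed=1)
    haps = [ld.HaplotypeSpec(1, weight=0.5), ld.HaplotypeSpec(2, weight=0.4)]
    with pytest.raises(ld.core.InvalidArgumentError):
        ld.simulate_sample(ref, haps, config=ld.SimulationConfig(coverage=5, seed=1))


def test_sam_round_trip_preserves_alignments_and_methylation(tmp_path):
    ref = ld.make_reference(1, 50_000, seed=4)
    plan = ld.DerivativePlan(
        [("chr1", 0, 20_000, "+"), ("chr1", 30_000, 50_000, "+")], cell_fraction=1.0
    )
    haps = [
        ld.HaplotypeSpec(1, weight=0.5, methyl_level=0.8),
        ld.HaplotypeSpec(2, weight=0.5, methyl_level=0.2),
    ]
    s = ld.simulate_sample(ref, haps, [plan], ld.SimulationConfig(coverage=15, seed=3))
    path = str(tmp_path / "sample.sam")
    write_sam(s.reads, {"chr1": 50_000}, path)
    loaded = {r.read_id: r for r in load_sam(path)}
    assert len(loaded) == len(s.reads)
    for read in s.reads:
        back = loaded[read.read_id]
        assert back.seq == read.seq
        assert [(b.chrom, b.ref_start, b.strand, b.cigar) for b in back.blocks] == [
            (b.chrom, b.ref_start, b.strand, b.cigar) for b in read.blocks
        ]
        a = sorted((c.read_pos, c.prob) for c in read.meth_calls)
        b = sorted((c.read_pos, c.prob) for c in back.meth_calls)
        assert [x[0] for x in a] == [x[0] for x in b]
        assert all(abs(x[1] - y[1]) <= 1 / 128 for x, y in zip(a, b))
    # junctions recomputed from the SAM match the in-memory ones
    j_mem, _ = ld.cluster_junctions(ld.extract_junctions(s.reads))
    j_sam, _ = ld.cluster_junctions(ld.extract_junctions(list(loaded.values())))
    assert [(j.end_a, j.end_b) for j in j_mem] == [(j.end_a, j.end_b) for j in j_sam]
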