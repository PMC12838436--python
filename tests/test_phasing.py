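"""Haplotype assignment, cis/trans phasing and paralog copy number."""

import lorediag as ld
from lorediag.core import AlignmentBlock, ReadAlignment, SmallVariant
from lorediag.phasing import ParalogFamily, assign_haplotypes, paralog_copy_number, phase_pair
from tests.conftest import alt_of


def read_over(seq, ref_start, read_id):
    return ReadAlignment(
        read_id=read_id,
        seq=seq,
        blocks=[AlignmentBlock("chr1", ref_start, "+", [("M", len(seq))], 0, len(seq))],
    )


def hand_reads(alleles_by_read, positions, ref_base="A", alt_base="T"):
    """Reads of length 100 covering `positions`; alleles 1=alt, 0=ref, None=skip."""
    reads = []
    for rid, alleles in alleles_by_read.items():
        seq = list("C" * 100)
        for pos, allele in zip(positions, alleles):
            if allele is None:
                continue
            seq[pos] = alt_base if allele else ref_base
        reads.append(read_over("".join(seq), 0, rid))
    return reads


VARIANTS = [SmallVariant("chr1", p + 1, "A", "T") for p in (10, 30, 50, 70, 90)]


def test_two_clean_haplotypes_fully_assigned():
    reads = hand_reads(
        {f"h1_{i}": [1, 1, 1, 1, 1] for i in range(3)}
        | {f"h2_{i}": [0, 0, 0, 0, 0] for i in range(3)},
        [10, 30, 50, 70, 90],
    )
    tags = assign_haplotypes(reads, VARIANTS)
    groups = {tags[f"h1_{i}"] for i in range(3)}, {tags[f"h2_{i}"] for i in range(3)}
    assert groups[0] in ({1}, {2}) and groups[1] in ({1}, {2})
    assert groups[0] != groups[1]


def test_single_read_single_site_assigned():
    reads = hand_reads({"only": [1, None, None, None, None]}, [10, 30, 50, 70, 90])
    tags = assign_haplotypes(reads, VARIANTS)
    assert tags["only"] in (1, 2)


def test_exact_tie_stays_unassigned():
    reads = hand_reads(
        {
            "a": [1, 1, None, None, None],
            "b": [0, 0, None, None, None],
            "tie": [1, 0, None, None, None],
        },
        [10, 30, 50, 70, 90],
    )
    tags = assign_haplotypes(reads, VARIANTS)
    assert tags["tie"] is None


def test_no_coverage_leaves_all_unassigned():
    reads = hand_reads({"r": [None] * 5}, [10, 30, 50, 70, 90])
    far = [SmallVariant("chr1", 5_000, "A", "T")]
    tags = assign_haplotypes(reads, far)
    assert tags["r"] is None


def test_direct_phase_cis_and_trans():
    va = SmallVariant("chr1", 11, "A", "T")
    vb = SmallVariant("chr1", 51, "A", "T")
    cis_reads = hand_reads(
        {f"c{i}": [1, None, 1, None, None] for i in range(3)}
        | {f"r{i}": [0, None, 0, None, None] for i in range(3)},
        [10, 30, 50, 70, 90],
    )
    assert phase_pair(cis_reads, va, vb).phase == "cis"
    trans_reads = hand_reads(
        {f"t{i}": [1, None, 0, None, None] for i in range(3)}
        | {f"u{i}": [0, None, 1, None, None] for i in range(3)},
        [10, 30, 50, 70, 90],
    )
    result = phase_pair(trans_reads, va, vb)
    assert result.phase == "trans" and result.evidence == "direct"


def test_insufficient_support_is_unknown():
    va = SmallVariant("chr1", 11, "A", "T")
    vb = SmallVariant("chr1", 51, "A", "T")
    reads = hand_reads({"x": [1, None, 1, None, None]}, [10, 30, 50, 70, 90])
    result = phase_pair(reads, va, vb)
    assert result.phase == "unknown" and result.reason == "insufficient support"


def test_conflicting_votes_are_unknown():
    va = SmallVariant("chr1", 11, "A", "T")
    vb = SmallVariant("chr1", 51, "A", "T")
    alleles = {f"c{i}": [1, None, 1, None, None] for i in range(6)}
    alleles |= {f"t{i}": [1, None, 0, None, None] for i in range(2)}
    result = phase_pair(hand_reads(alleles, [10, 30, 50, 70, 90]), va, vb)
    assert result.phase == "unknown" and result.reason == "conflicting evidence"


def test_label_swap_symmetry():
    """Relabeling haplotypes 1<->2 leaves the cis/trans call unchanged."""
    va = SmallVariant("chr1", 11, "A", "T")
    vb = SmallVariant("chr1", 91, "A", "T")
    # haplotype 1: alt at scaffold sites 10..70, ref at 90; haplotype 2 is the
    # complement, so the target pair is in trans.  No read covers both targets;
    # mid reads bridge the left and right groups.
    alleles = {f"a{i}": [1, 1, None, None, None] for i in range(4)}  # left hap1
    alleles |= {f"c{i}": [0, 0, None, None, None] for i in range(4)}  # left hap2
    alleles |= {f"m{i}": [None, 1, 1, 1, None] for i in range(4)}  # mid hap1
    alleles |= {f"n{i}": [None, 0, 0, 0, None] for i in range(4)}  # mid hap2
    alleles |= {f"b{i}": [None, None, None, 1, 0] for i in range(4)}  # right hap1
    alleles |= {f"d{i}": [None, None, None, 0, 1] for i in range(4)}  # right hap2
    reads = hand_reads(alleles, [10, 30, 50, 70, 90])
    for r in reads:
        if r.read_id.startswith(("a", "c")):
            r.blocks = [AlignmentBlock("chr1", 0, "+", [("M", 40), ("S", 60)], 0, 40)]
        elif r.read_id.startswith(("m", "n")):
            r.blocks = [
                AlignmentBlock("chr1", 20, "+", [("S", 20), ("M", 60), ("S", 20)], 20, 80)
            ]
        else:
            r.blocks = [AlignmentBlock("chr1", 60, "+", [("S", 60), ("M", 40)], 60, 100)]
    tags = assign_haplotypes(reads, VARIANTS)
    swapped = {k: (3 - v if v else None) for k, v in tags.items()}
    p1 = phase_pair(reads, va, vb, tags)
    p2 = phase_pair(reads, va, vb, swapped)
    assert p1.phase == p2.phase == "trans"


def make_paralog_fixture(n_smn1, n_smn2, seed=3, coverage=60):
    ref = ld.make_reference(1, 12_000, seed=6)
    gene_site, private = 5_500, [4_300, 4_900, 6_100, 6_700]
    s_ref = list(ref["chr1"])
    s_ref[gene_site] = "C"
    for p in private:
        s_ref[p] = "A"
    ref["chr1"] = "".join(s_ref)
    n = n_smn1 + n_smn2
    haps = []
    for i in range(n):
        variants = [("chr1", private[i], "A", "G")]
        if i >= n_smn1:  # SMN2-type copies carry T at the gene-defining site
            variants.append(("chr1", gene_site, "C", "T"))
        haps.append(
            ld.HaplotypeSpec(i + 1, variants=sorted(variants, key=lambda v: v[1]),
                             weight=1.0 / n)
        )
    sample = ld.simulate_sample(
        ref, haps, config=ld.SimulationConfig(coverage=coverage, seed=seed)
    )
    family = ParalogFamily(
        "SMN", "chr1", 4_000, 7_000,
        sites=sorted(private + [gene_site]),
        gene_site=gene_site,
        gene_alleles={"C": "SMN1", "T": "SMN2"},
        haploid_depth=coverage / 4,
    )
    return sample, family


def test_paralog_zero_four_recovery():
    sample, family = make_paralog_fixture(0, 4)
    profile = paralog_copy_number(sample.reads, family)
    assert profile.per_gene_copies == {"SMN1": 0, "SMN2": 4}
    assert profile.total_copies == 4


def test_paralog_two_two_recovery():
    sample, family = make_paralog_fixture(2, 2, seed=8)
    profile = paralog_copy_number(sample.reads, family)
    assert profile.per_gene_copies == {"SMN1": 2, "SMN2": 2}


def test_paralog_no_reads_is_no_call():
    _, family = make_paralog_fixture(0, 4)
    profile = paralog_copy_number([], family)
    assert profile.no_call and profile.total_copies == 0
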