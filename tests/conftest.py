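"""Shared fixtures: small references and simulated samples with ground truth."""

from __future__ import annotations

import pytest

import lorediag as ld
from lorediag.str_profiler import StrLocus


def alt_of(base: str) -> str:
    return "A" if base != "A" else "G"


def make_str_reference(motif: str, ref_units: int, length: int = 20_000, seed: int = 3):
    """Reference with a repeat tract planted at its center; returns (ref, locus)."""
    ref = ld.make_reference(1, length, seed=seed)
    start = length // 2
    tract = motif * ref_units
    end = start + len(tract)
    chrom = ref["chr1"]
    ref["chr1"] = chrom[:start] + tract + chrom[end:]
    return ref, (start, end)


@pytest.fixture(scope="session")
def fmr1_setup():
    ref, (start, end) = make_str_reference("CGG", 30)
    locus = StrLocus(
        "FMR1", "FMR1", "chr1", start, end, "CGG",
        normal_max=44, intermediate_max=54, premutation_max=200,
    )
    return ref, locus


@pytest.fixture(scope="session")
def atxn1_setup():
    ref, (start, end) = make_str_reference("CAG", 30, seed=5)
    locus = StrLocus(
        "ATXN1", "ATXN1", "chr1", start, end, "CAG",
        normal_max=35, intermediate_max=44, premutation_max=44,
    )
    return ref, locus


@pytest.fixture(scope="session")
def diploid_sample():
    """Plain two-haplotype 100 kb sample at 30X, no planted events."""
    ref = ld.make_reference(1, 100_000, seed=7)
    haps = [ld.HaplotypeSpec(1, weight=0.5), ld.HaplotypeSpec(2, weight=0.5)]
    sample = ld.simulate_sample(ref, haps, config=ld.SimulationConfig(coverage=30, seed=1))
    return sample
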