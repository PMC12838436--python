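"""Region-level CpG methylation aggregation and imprinting z-score calls.

Per-read CpG probability calls are thresholded symmetrically (>= p methylated,
<= 1-p unmethylated, the middle band discarded) and aggregated into a region
methylation fraction.  Aberrant imprinting is called by comparing a case's
fraction against a pool of control samples: z = (case - mean) / sd with the
sample (n-1) standard deviation, flagged when |z| exceeds a threshold
(default 3).  Whether hypermethylation maps to positive or negative z depends
on whether the scored quantity is the methylated or the unmethylated
fraction; both conventions occur in practice, so the convention is explicit,
configurable, and echoed in every result.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import ConfigurationError, InvalidArgumentError, ReadAlignment

EXPECTED_STATES = ("maternal_methylated", "paternal_methylated", "unimprinted")


@dataclass
class MethylRegion:
    region_id: str
    gene: str
    chrom: str
    start: int
    end: int
    expected_state: str = "unimprinted"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidArgumentError("region must satisfy start < end")
        if self.expected_state not in EXPECTED_STATES:
            raise InvalidArgumentError(f"unknown expected_state {self.expected_state}")


@dataclass
class MethylRegionStat:
    region: MethylRegion
    case_fraction: Optional[float]
    n_calls: int
    control_mean: Optional[float]
    control_sd: Optional[float]
    z: Optional[float]
    call: str  # hypermethylated / hypomethylated / normal / no_call
    convention: str = "methylated_fraction"
    reason: str = ""


def load_regions(bed_path: str, json_path: Optional[str] = None) -> list[MethylRegion]:
    """Regions from BED (chrom, start, end, region_id) + optional JSON sidecar."""
    sidecar = {}
    if json_path:
        with open(json_path) as fh:
            sidecar = json.load(fh)
    regions = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, region_id = line.split()[:4]
            meta = sidecar.get(region_id, {})
            regions.append(
                MethylRegion(
                    region_id=region_id,
                    gene=meta.get("gene", region_id),
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    expected_state=meta.get("expected_state", "unimprinted"),
                )
            )
    return regions


def region_methylation_fraction(
    reads: Sequence[ReadAlignment],
    region: MethylRegion,
    prob_threshold: float = 0.8,
    haplotype_filter: Optional[int] = None,
) -> tuple[Optional[float], int]:
    """Methylated fraction over all retained CpG calls in a region.

    A call with probability >= prob_threshold counts methylated, <= 1 -
    prob_threshold unmethylated; calls in between are discarded.  Returns
    (fraction, n_retained); fraction is None when no call is retained
    (no-call).  Invariant to read order and read-set duplication.
    """
    if not 0.5 < prob_threshold <= 1.0:
        raise InvalidArgumentError("prob_threshold must lie in (0.5, 1]")
    n_meth = n_unmeth = 0
    for read in reads:
        if haplotype_filter is not None and read.haplotype != haplotype_filter:
            continue
        for call in read.meth_calls:
            if (
                call.chrom != region.chrom
                or call.ref_pos is None
                or not region.start <= call.ref_pos < region.end
            ):
                continue
            if call.prob >= prob_threshold:
                n_meth += 1
            elif call.prob <= 1.0 - prob_threshold:
                n_unmeth += 1
    total = n_meth + n_unmeth
    if total == 0:
        return None, 0
    return n_meth / total, total


def imprinting_zscores(
    case_fractions: dict[str, tuple[Optional[float], int]],
    control_fraction_table: pd.DataFrame,
    regions: Sequence[MethylRegion],
    min_controls: int = 5,
    min_calls: int = 10,
    z_hyper: float = 3.0,
    z_hypo: float = -3.0,
    convention: str = "methylated_fraction",
) -> list[MethylRegionStat]:
    """Score one case against a control pool, region by region.

    ``case_fractions`` maps region_id -> (fraction, n_calls) as returned by
    :func:`region_methylation_fraction`; the control table has columns
    (sample_id, region_id, fraction, n_calls).  Under the default
    ``methylated_fraction`` convention hypermethylation yields positive z;
    under ``unmethylated_fraction`` the scored quantity is 1 - fraction and
    the sign flips.  Affine-invariant: shifting or positively scaling every
    fraction (case and controls together) leaves z unchanged.
    """
    if convention not in ("methylated_fraction", "unmethylated_fraction"):
        raise InvalidArgumentError(f"unknown sign convention {convention}")
    required = {"sample_id", "region_id", "fraction"}
    if not required.issubset(control_fraction_table.columns):
        raise ConfigurationError(f"control table needs columns {sorted(required)}")

    def score(x: float) -> float:
        return x if convention == "methylated_fraction" else 1.0 - x

    stats = []
    for region in regions:
        ctl = control_fraction_table.loc[
            control_fraction_table["region_id"] == region.region_id, "fraction"
        ].dropna()
        if len(ctl) < min_controls:
            raise ConfigurationError(
                f"control pool for {region.region_id} has {len(ctl)} samples "
                f"(need >= {min_controls})"
            )
        frac, n_calls = case_fractions.get(region.region_id, (None, 0))
        mean = statistics.fmean(score(x) for x in ctl)
        sd = statistics.stdev(score(x) for x in ctl)  # sample (n-1) sd
        if frac is None or n_calls < min_calls:
            stats.append(
                MethylRegionStat(
                    region, frac, n_calls, mean, sd, None, "no_call",
                    convention, reason="insufficient case calls",
                )
            )
            continue
        if sd == 0:
            stats.append(
                MethylRegionStat(
                    region, frac, n_calls, mean, sd, None, "no_call",
                    convention, reason="zero control variance",
                )
            )
            continue
        z = (score(frac) - mean) / sd
        if convention == "methylated_fraction":
            call = "hypermethylated" if z >= z_hyper else (
                "hypomethylated" if z <= z_hypo else "normal"
            )
        else:
            # scored quantity decreases with methylation
            call = "hypermethylated" if z <= z_hypo else (
                "hypomethylated" if z >= z_hyper else "normal"
            )
        stats.append(
            MethylRegionStat(region, frac, n_calls, mean, sd, z, call, convention)
        )
    return stats


def str_promoter_status(
    reads: Sequence[ReadAlignment],
    promoter_region: MethylRegion,
    prob_threshold: float = 0.8,
    haplotype_filter: Optional[int] = None,
) -> str:
    """Promoter methylation status for an STR locus.

    fraction >= 0.7 -> hypermethylated, <= 0.3 -> unmethylated, else
    intermediate; no retained calls -> no_call.
    """
    fraction, n_calls = region_methylation_fraction(
        reads, promoter_region, prob_threshold, haplotype_filter
    )
    if fraction is None:
        return "no_call"
    if fraction >= 0.7:
        return "hypermethylated"
    if fraction <= 0.3:
        return "unmethylated"
    return "intermediate"


def stats_to_frame(stats: Sequence[MethylRegionStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": s.region.region_id,
            "gene": s.region.gene,
            "case_fraction": s.case_fraction,
            "n_calls": s.n_calls,
            "control_mean": s.control_mean,
            "control_sd": s.control_sd,
            "z": s.z,
            "call": s.call,
            "convention": s.convention,
            "reason": s.reason,
        }
        for s in stats
    )
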