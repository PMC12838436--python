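"""Per-read STR genotyping at catalog loci with interruption-motif detection.

Repeat counting is anchor-based greedy tiling: the read is located at the
locus by matching both flank anchors (exact, with a fuzzy fallback allowing
one mismatch per 8 bp of anchor), and the tract between the anchors is tiled
left to right by the canonical motif.  A unit within the mismatch budget
counts as canonical; any other unit-length word is recorded as an
interruption with its observed motif (AGG inside CGG, CAT inside CAG, ...);
interrupting units count toward the total, and a trailing partial unit is
floored.  This is deterministic and checkable against an exhaustive oracle,
which is what a desk-scale re-analysis needs; no HMM is involved.

Haplotype-resolved sizing uses read tags when present, otherwise a 1-D
two-cluster split of the counts, accepted only when the two cluster medians
differ by more than max(2 units, 10%) — avoiding spurious splits of noisy
single-allele loci.
"""

from __future__ import annotations

import json
import logging

import edlib
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .core import (
    ConfigurationError,
    InvalidArgumentError,
    NonSpanningReadError,
    ReadAlignment,
    hamming,
    revcomp,
)

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("normal", "intermediate", "premutation", "full")


@dataclass
class StrLocus:
    """One catalog entry: repeat tract coordinates, motif and thresholds.

    Thresholds are inclusive upper bounds in repeat units: a per-haplotype
    median m is normal when m <= normal_max, intermediate when
    m <= intermediate_max, premutation when m <= premutation_max, else full.
    """

    locus_id: str
    gene: str
    chrom: str
    start: int
    end: int
    motif: str
    normal_max: Optional[float] = None
    intermediate_max: Optional[float] = None
    premutation_max: Optional[float] = None
    flank_len: int = 30

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise InvalidArgumentError("motif length must be >= 1")
        if self.start >= self.end:
            raise InvalidArgumentError("locus interval must satisfy start < end")
        ts = [self.normal_max, self.intermediate_max, self.premutation_max]
        present = [t for t in ts if t is not None]
        if present != sorted(present):
            raise InvalidArgumentError("thresholds must be non-decreasing")

    @property
    def thresholds(self):
        return (self.normal_max, self.intermediate_max, self.premutation_max)


# Default locus thresholds, in repeat units, for the two loci the package
# ships out of the box; coordinates are filled in per reference by the caller.
DEFAULT_THRESHOLDS = {
    "FMR1": dict(motif="CGG", normal_max=44, intermediate_max=54, premutation_max=200),
    "ATXN1": dict(motif="CAG", normal_max=35, intermediate_max=44, premutation_max=44),
}


def default_catalog(coords: dict[str, tuple[str, int, int]], flank_len: int = 30):
    """Build the shipped FMR1/ATXN1 catalog on caller-supplied coordinates."""
    catalog = {}
    for gene, (chrom, start, end) in coords.items():
        if gene not in DEFAULT_THRESHOLDS:
            raise ConfigurationError(f"no default thresholds for {gene}")
        catalog[gene] = StrLocus(
            locus_id=gene,
            gene=gene,
            chrom=chrom,
            start=start,
            end=end,
            flank_len=flank_len,
            **DEFAULT_THRESHOLDS[gene],
        )
    return catalog


def load_catalog(bed_path: str, json_path: str) -> dict[str, StrLocus]:
    """Catalog from a BED file (chrom, start, end, locus_id) + JSON sidecar."""
    with open(json_path) as fh:
        sidecar = json.load(fh)
    catalog = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, locus_id = line.split()[:4]
            meta = sidecar[locus_id]
            catalog[locus_id] = StrLocus(
                locus_id=locus_id,
                gene=meta.get("gene", locus_id),
                chrom=chrom,
                start=int(start),
                end=int(end),
                motif=meta["motif"],
                normal_max=meta.get("normal_max"),
                intermediate_max=meta.get("intermediate_max"),
                premutation_max=meta.get("premutation_max"),
                flank_len=int(meta.get("flank_len", 30)),
            )
    return catalog


@dataclass
class StrReadCall:
    read_id: str
    repeat_count: int
    interruptions: list[tuple[int, str]]
    haplotype: Optional[int] = None
    tract_sequence: str = ""


@dataclass
class HaplotypeSize:
    haplotype: Union[int, str]
    median: float
    min: int
    max: int
    n_reads: int
    classification: Optional[str] = None


@dataclass
class StrProfile:
    locus: StrLocus
    read_calls: list[StrReadCall]
    haplotype_sizes: list[HaplotypeSize]
    overall_median: Optional[float]
    no_call: bool = False
    promoter_methylation: Optional[float] = None

    @property
    def classifications(self) -> dict:
        return {h.haplotype: h.classification for h in self.haplotype_sizes}


# ---------------------------------------------------------------------------
# anchor matching and tiling
# ---------------------------------------------------------------------------


def _find_anchor(seq: str, anchor: str, from_pos: int = 0) -> Optional[tuple[int, int]]:
    """Locate an anchor: exact match first, then fuzzy within an edit-distance
    budget of one error per 8 bp of anchor.  Returns the matched span."""
    hit = seq.find(anchor, from_pos)
    if hit >= 0:
        return hit, hit + len(anchor)
    budget = len(anchor) // 8
    if budget == 0:
        return None
    res = edlib.align(anchor, seq[from_pos:], mode="HW", task="locations", k=budget)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return from_pos + start, from_pos + end + 1


def tile_tract(
    tract: str, motif: str, max_unit_mismatch: int = 0
) -> tuple[int, list[tuple[int, str]]]:
    """Greedy left-to-right tiling of a tract by a canonical motif.

    Returns (repeat_count, interruptions); interruptions are (unit_index,
    observed motif) for unit-length windows outside the mismatch budget.
    Trailing bases short of a full unit are floored away.
    """
    k = len(motif)
    count = 0
    interruptions = []
    for i in range(0, len(tract) - k + 1, k):
        window = tract[i : i + k]
        if hamming(window, motif) > max_unit_mismatch:
            interruptions.append((count, window))
        count += 1
    return count, interruptions


def count_repeats_in_read(
    read: Union[ReadAlignment, str],
    locus: StrLocus,
    reference: dict[str, str],
    max_unit_mismatch: int = 0,
    try_revcomp: bool = False,
) -> StrReadCall:
    """Count repeat units in one read at ``locus``.

    The read must span both flank anchors; otherwise NonSpanningReadError is
    raised (callers exclude and log such reads).  ``read`` may be a raw
    sequence string; pass ``try_revcomp=True`` for raw reads of unknown
    orientation (aligned reads are used in reference-forward orientation).
    """
    left = reference[locus.chrom][locus.start - locus.flank_len : locus.start].upper()
    right = reference[locus.chrom][locus.end : locus.end + locus.flank_len].upper()
    if isinstance(read, ReadAlignment):
        seq = read.aligned_forward_seq().upper()
        read_id = read.read_id
        haplotype = read.haplotype
    else:
        seq, read_id, haplotype = read.upper(), "anonymous", None
    tract = _extract_tract(seq, left, right)
    if tract is None and try_revcomp:
        tract = _extract_tract(revcomp(seq), left, right)
    if tract is None:
        raise NonSpanningReadError(
            f"read {read_id} does not span both anchors of {locus.locus_id}"
        )
    count, interruptions = tile_tract(tract, locus.motif.upper(), max_unit_mismatch)
    return StrReadCall(
        read_id=read_id,
        repeat_count=count,
        interruptions=interruptions,
        haplotype=haplotype,
        tract_sequence=tract,
    )


def _extract_tract(seq: str, left: str, right: str) -> Optional[str]:
    left_span = _find_anchor(seq, left)
    if left_span is None:
        return None
    right_span = _find_anchor(seq, right, left_span[1])
    if right_span is None:
        return None
    return seq[left_span[1] : right_span[0]]


# ---------------------------------------------------------------------------
# locus profiling
# ---------------------------------------------------------------------------


def _best_two_cluster_split(counts: list[int]) -> tuple[list[int], list[int]]:
    """1-D two-cluster partition minimizing within-cluster sum of squares."""
    xs = sorted(counts)
    best_cut, best_cost = 1, float("inf")
    for cut in range(1, len(xs)):
        lo, hi = xs[:cut], xs[cut:]
        cost = sum((x - statistics.fmean(lo)) ** 2 for x in lo) + sum(
            (x - statistics.fmean(hi)) ** 2 for x in hi
        )
        if cost < best_cost:
            best_cut, best_cost = cut, cost
    return xs[:best_cut], xs[best_cut:]


def _bimodal(lo: list[int], hi: list[int]) -> bool:
    m1, m2 = statistics.median(lo), statistics.median(hi)
    return abs(m2 - m1) > max(2.0, 0.1 * max(m1, m2))


def profile_locus(
    reads: Sequence[Union[ReadAlignment, str]],
    locus: StrLocus,
    reference: dict[str, str],
    haplotype_assignments: Optional[dict[str, int]] = None,
    min_spanning_reads: int = 3,
    max_unit_mismatch: int = 0,
) -> StrProfile:
    """Size a locus from all spanning reads, haplotype-resolved when possible.

    Non-spanning reads are excluded and logged.  Zero spanning reads (or fewer
    than ``min_spanning_reads``) yield a no-call profile, not an error.
    """
    calls: list[StrReadCall] = []
    for read in reads:
        try:
            call = count_repeats_in_read(read, locus, reference, max_unit_mismatch)
        except NonSpanningReadError as exc:
            logger.debug("%s", exc)
            continue
        if haplotype_assignments is not None:
            call.haplotype = haplotype_assignments.get(call.read_id)
        calls.append(call)

    if len(calls) < min_spanning_reads:
        return StrProfile(
            locus=locus,
            read_calls=calls,
            haplotype_sizes=[],
            overall_median=(
                statistics.median(c.repeat_count for c in calls) if calls else None
            ),
            no_call=True,
        )

    overall = statistics.median(c.repeat_count for c in calls)
    groups: dict[Union[int, str], list[int]] = {}
    tagged = [c for c in calls if c.haplotype in (1, 2)]
    if tagged:
        for call in tagged:
            groups.setdefault(call.haplotype, []).append(call.repeat_count)
    else:
        counts = [c.repeat_count for c in calls]
        if len(set(counts)) > 1:
            lo, hi = _best_two_cluster_split(counts)
            if lo and hi and _bimodal(lo, hi):
                groups = {1: lo, 2: hi}
        if not groups:
            groups = {"pooled": counts}

    sizes = [
        HaplotypeSize(
            haplotype=hap,
            median=statistics.median(vals),
            min=min(vals),
            max=max(vals),
            n_reads=len(vals),
        )
        for hap, vals in sorted(groups.items(), key=lambda kv: str(kv[0]))
    ]
    profile = StrProfile(
        locus=locus, read_calls=calls, haplotype_sizes=sizes, overall_median=overall
    )
    classify_expansion(profile)
    return profile


def classify_expansion(profile: StrProfile) -> dict:
    """Attach a threshold classification to each sized haplotype.

    Boundaries are inclusive: a median exactly at normal_max is normal.
    """
    locus = profile.locus
    if any(t is None for t in locus.thresholds):
        raise ConfigurationError(
            f"locus {locus.locus_id} is missing classification thresholds"
        )
    for size in profile.haplotype_sizes:
        m = size.median
        if m <= locus.normal_max:
            size.classification = "normal"
        elif m <= locus.intermediate_max:
            size.classification = "intermediate"
        elif m <= locus.premutation_max:
            size.classification = "premutation"
        else:
            size.classification = "full"
    return profile.classifications


def profile_to_rows(profile: StrProfile) -> list[dict]:
    """Flatten a profile to report rows (one per haplotype)."""
    rows = []
    for size in profile.haplotype_sizes:
        inter = {}
        for call in profile.read_calls:
            for _, motif in call.interruptions:
                inter[motif] = inter.get(motif, 0) + 1
        rows.append(
            {
                "locus": profile.locus.locus_id,
                "haplotype": size.haplotype,
                "median": size.median,
                "min": size.min,
                "max": size.max,
                "n_reads": size.n_reads,
                "interruption_motifs": ",".join(
                    f"{m}x{n}" for m, n in sorted(inter.items())
                ),
                "classification": size.classification,
                "promoter_methylation": profile.promoter_methylation,
            }
        )
    return rows
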