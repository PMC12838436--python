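"""Breakpoint junctions, derivative-chromosome reconstruction, mosaicism.

A junction is the fusion point of two genomic loci, evidenced by a read whose
alignment is split into a supplementary chain.  Each junction end records the
*retained* flank: orientation '+' keeps coordinates below the breakpoint,
'-' keeps coordinates at or above it — so a simple deletion produces
(L,'+')-(R,'-'), and an inversion produces like orientations.

Derivatives are reconstructed by a greedy walk along the reference that jumps
at junction ends, consuming per-interval copy counts (from read-depth copy
number, minus the one copy the intact homolog keeps) so the walk stops at
broken ends, telomeres, or when it closes on its start (ring).  The mosaic
cell fraction of a junction follows the one-of-two-homologs model: twice the
fraction of junction reads among reads spanning the breakpoint, reported both
raw and as the truncated integer percent.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import InvalidArgumentError, LorediagError, ReadAlignment

logger = logging.getLogger(__name__)

MOTIF_LABELS = (
    "DEL",
    "DUP",
    "INV",
    "DEL-INV-DUP",
    "DUP-TRP/INV-DUP",
    "RING",
    "UNBALANCED_TRANSLOCATION",
    "COMPLEX",
    "REFERENCE",
)

JunctionEnd = tuple[str, int, str]  # (chrom, 0-based pos, orientation)


@dataclass
class Junction:
    """One breakpoint junction; ends are canonically ordered (end_a <= end_b)."""

    end_a: JunctionEnd
    end_b: JunctionEnd
    support: list[str] = field(default_factory=list)
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if (self.end_a[0], self.end_a[1], self.end_a[2]) > (
            self.end_b[0],
            self.end_b[1],
            self.end_b[2],
        ):
            self.end_a, self.end_b = self.end_b, self.end_a

    @property
    def n_support(self) -> int:
        return len(self.support)


@dataclass
class SegmentCN:
    chrom: str
    start: int
    end: int
    copy_number: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidArgumentError("segment must satisfy start < end")
        if self.copy_number < 0:
            raise InvalidArgumentError("copy_number must be >= 0")


@dataclass
class DerivativeChromosome:
    segments: list[tuple[str, int, int, str]]  # (chrom, start, end, orientation)
    circular: bool
    motif_label: str
    mosaic_fraction: Optional[float]  # None = assumed constitutional
    junctions_used: list[Junction]
    resolved: bool = True
    annotations: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# junction extraction and clustering
# ---------------------------------------------------------------------------


def extract_junctions(
    reads: Sequence[ReadAlignment], min_clip: int = 20, min_mapq: int = 0
) -> list[Junction]:
    """One raw junction per adjacent alignment pair in each read's chain.

    Soft-clipped ends >= min_clip without a mate alignment are logged, not
    emitted.  Empty input yields an empty list.
    """
    raw: list[Junction] = []
    for read in reads:
        blocks = [b for b in read.blocks if b.mapq >= min_mapq]
        if len(blocks) < 2:
            if blocks:
                b = blocks[0]
                lead = b.cigar[0][1] if b.cigar[0][0] == "S" else 0
                trail = b.cigar[-1][1] if b.cigar[-1][0] == "S" else 0
                if max(lead, trail) >= min_clip:
                    logger.debug(
                        "read %s has an unmatched soft clip of %d bp",
                        read.read_id,
                        max(lead, trail),
                    )
            continue
        for left, right in zip(blocks, blocks[1:]):
            end_a: JunctionEnd = (
                (left.chrom, left.ref_end, "+")
                if left.strand == "+"
                else (left.chrom, left.ref_start, "-")
            )
            end_b: JunctionEnd = (
                (right.chrom, right.ref_start, "-")
                if right.strand == "+"
                else (right.chrom, right.ref_end, "+")
            )
            raw.append(Junction(end_a, end_b, support=[read.read_id]))
    return raw


def cluster_junctions(
    raw: Sequence[Junction], pos_tolerance: int = 50, min_support: int = 3
) -> tuple[list[Junction], int]:
    """Merge raw junctions within tolerance at both ends (same orientations).

    Cluster position is the per-end median; support is the union of read ids.
    Returns (kept clusters, number of clusters dropped for low support).
    """
    if pos_tolerance < 0:
        raise InvalidArgumentError("pos_tolerance must be >= 0")
    by_key: dict[tuple, list[Junction]] = {}
    for j in raw:
        key = (j.end_a[0], j.end_a[2], j.end_b[0], j.end_b[2])
        by_key.setdefault(key, []).append(j)
    kept: list[Junction] = []
    dropped = 0
    for key, items in by_key.items():
        items.sort(key=lambda j: (j.end_a[1], j.end_b[1]))
        clusters: list[list[Junction]] = []
        for j in items:
            placed = False
            for cluster in clusters:
                pa = statistics.median(c.end_a[1] for c in cluster)
                pb = statistics.median(c.end_b[1] for c in cluster)
                if abs(j.end_a[1] - pa) <= pos_tolerance and abs(
                    j.end_b[1] - pb
                ) <= pos_tolerance:
                    cluster.append(j)
                    placed = True
                    break
            if not placed:
                clusters.append([j])
        for cluster in clusters:
            support = sorted({rid for j in cluster for rid in j.support})
            if len(support) < min_support:
                dropped += 1
                continue
            chrom_a, orient_a, chrom_b, orient_b = key
            pa = int(statistics.median(j.end_a[1] for j in cluster))
            pb = int(statistics.median(j.end_b[1] for j in cluster))
            kept.append(
                Junction((chrom_a, pa, orient_a), (chrom_b, pb, orient_b), support)
            )
    kept.sort(key=lambda j: (j.end_a, j.end_b))
    return kept, dropped


# ---------------------------------------------------------------------------
# read-depth copy number
# ---------------------------------------------------------------------------


def segment_copy_number(
    reads: Sequence[ReadAlignment],
    chrom_lengths: dict[str, int],
    bin_size: int = 1000,
    merge_tolerance: float = 0.35,
    boundaries: Optional[dict[str, Sequence[int]]] = None,
    min_step: float = 0.5,
    min_bins: int = 15,
) -> list[SegmentCN]:
    """Binned depth normalized to the genome median, scaled to diploid copies.

    Without ``boundaries``, adjacent bins within ``merge_tolerance`` copies of
    the running segment mean are merged (with a median pre-filter).  When
    junction breakpoints are available, pass them as ``boundaries`` (per
    chromosome): segments are then delimited exactly at those positions, and
    additional depth changepoints (steps of at least ``min_step`` copies, at
    least ``min_bins`` bins per side) are found inside each interval by
    recursive binary segmentation — which is far more robust to the long-read
    depth autocorrelation than bin-local merging.
    """
    if bin_size < 100:
        raise InvalidArgumentError("bin_size must be >= 100")
    depth = {
        chrom: np.zeros(max(1, length // bin_size)) for chrom, length in chrom_lengths.items()
    }
    for read in reads:
        for b in read.blocks:
            bins = depth.get(b.chrom)
            if bins is None:
                continue
            start, end = b.ref_start, min(b.ref_end, len(bins) * bin_size)
            if end <= start:
                continue
            first, last = start // bin_size, (end - 1) // bin_size
            for i in range(first, last + 1):
                lo = max(start, i * bin_size)
                hi = min(end, (i + 1) * bin_size)
                bins[i] += (hi - lo) / bin_size
    all_bins = np.concatenate(list(depth.values()))
    median = _half_sample_mode(all_bins)
    if median <= 0:
        raise LorediagError("zero-depth genome: cannot normalize copy number")
    if boundaries is not None:
        segments = []
        for chrom, bins in depth.items():
            cn = bins / median * 2.0
            fixed = sorted(
                {0, chrom_lengths[chrom]}
                | {p for p in boundaries.get(chrom, []) if 0 < p < chrom_lengths[chrom]}
            )
            for lo, hi in zip(fixed[:-1], fixed[1:]):
                blo = lo // bin_size
                bhi = max(blo + 1, min(len(cn), -(-hi // bin_size)))
                window = cn[blo:bhi]
                for a, b in _binary_splits(window, min_step, min_bins):
                    seg_lo = lo if a == 0 else (blo + a) * bin_size
                    seg_hi = hi if b == len(window) else (blo + b) * bin_size
                    if seg_hi > seg_lo:
                        segments.append(
                            SegmentCN(
                                chrom, seg_lo, seg_hi,
                                float(np.mean(window[a:b])), b - a,
                            )
                        )
        return segments

    segments: list[SegmentCN] = []
    for chrom, bins in depth.items():
        cn = bins / median * 2.0
        # running median (window 5) suppresses single-bin noise before merging
        if len(cn) >= 5:
            padded = np.pad(cn, 2, mode="edge")
            cn = np.median(
                np.lib.stride_tricks.sliding_window_view(padded, 5), axis=1
            )
        seg_start = 0
        seg_sum = cn[0]
        seg_n = 1
        for i in range(1, len(cn)):
            if abs(cn[i] - seg_sum / seg_n) > merge_tolerance:
                segments.append(
                    SegmentCN(
                        chrom,
                        seg_start * bin_size,
                        i * bin_size,
                        seg_sum / seg_n,
                        seg_n,
                    )
                )
                seg_start, seg_sum, seg_n = i, cn[i], 1
            else:
                seg_sum += cn[i]
                seg_n += 1
        segments.append(
            SegmentCN(
                chrom,
                seg_start * bin_size,
                chrom_lengths[chrom],
                seg_sum / seg_n,
                seg_n,
            )
        )
    return _merge_adjacent(segments, merge_tolerance)


def _half_sample_mode(x: np.ndarray) -> float:
    """Modal value by the half-sample mode algorithm.

    The diploid baseline is the *most common* bin depth; unlike the median it
    stays unbiased when a sizeable fraction of the genome carries copy-number
    changes (as long as the neutral state remains the largest class).
    """
    x = np.sort(np.asarray(x, dtype=float))
    while len(x) > 3:
        h = (len(x) + 1) // 2
        ranges = x[h - 1 :] - x[: len(x) - h + 1]
        i = int(np.argmin(ranges))
        x = x[i : i + h]
    return float(np.mean(x))


def _binary_splits(
    cn: np.ndarray, min_step: float, min_bins: int
) -> list[tuple[int, int]]:
    """Recursive binary segmentation of one bin window: returns sub-intervals.

    A split is accepted where it maximizes the residual-sum-of-squares
    reduction, provided the two side means differ by at least ``min_step``
    copies and each side has at least ``min_bins`` bins.
    """
    n = len(cn)
    if n < 2 * min_bins:
        return [(0, n)]
    csum = np.cumsum(cn)
    csq = np.cumsum(cn**2)
    total_sse = csq[-1] - csum[-1] ** 2 / n
    best_k, best_gain = None, 0.0
    for k in range(min_bins, n - min_bins + 1):
        left_sse = csq[k - 1] - csum[k - 1] ** 2 / k
        right_sum = csum[-1] - csum[k - 1]
        right_sse = (csq[-1] - csq[k - 1]) - right_sum**2 / (n - k)
        gain = total_sse - left_sse - right_sse
        if gain > best_gain:
            mean_l = csum[k - 1] / k
            mean_r = right_sum / (n - k)
            if abs(mean_l - mean_r) >= min_step:
                best_k, best_gain = k, gain
    if best_k is None:
        return [(0, n)]
    left = _binary_splits(cn[:best_k], min_step, min_bins)
    right = _binary_splits(cn[best_k:], min_step, min_bins)
    return left + [(a + best_k, b + best_k) for a, b in right]


def _merge_adjacent(
    segments: list[SegmentCN], tolerance: float
) -> list[SegmentCN]:
    """Iteratively merge adjacent segments with similar means (second pass)."""
    changed = True
    while changed:
        changed = False
        out: list[SegmentCN] = []
        for seg in segments:
            prev = out[-1] if out else None
            if (
                prev is not None
                and prev.chrom == seg.chrom
                and prev.end == seg.start
                and abs(prev.copy_number - seg.copy_number) <= tolerance
            ):
                n = prev.n_bins + seg.n_bins
                cn = (
                    prev.copy_number * prev.n_bins + seg.copy_number * seg.n_bins
                ) / n
                out[-1] = SegmentCN(prev.chrom, prev.start, seg.end, cn, n)
                changed = True
            else:
                out.append(seg)
        segments = out
    return segments


# ---------------------------------------------------------------------------
# derivative reconstruction
# ---------------------------------------------------------------------------


def _snap_segments(
    segments: Sequence[SegmentCN], junctions: Sequence[Junction]
) -> list[SegmentCN]:
    """Snap bin-quantized copy-number boundaries onto nearby junction ends.

    Depth segmentation localizes a step only to bin resolution; the junction
    gives the exact breakpoint, so boundaries within ~3 bins of a junction end
    are moved onto it before the traversal budget is built.
    """
    ends_by_chrom: dict[str, list[int]] = {}
    for j in junctions:
        for chrom, pos, _ in (j.end_a, j.end_b):
            ends_by_chrom.setdefault(chrom, []).append(pos)
    def snap(chrom: str, x: int, tol: int) -> int:
        ends = ends_by_chrom.get(chrom, [])
        if not ends or x in ends:
            return x
        nearest = min(ends, key=lambda p: abs(p - x))
        return nearest if abs(nearest - x) <= tol else x

    out = []
    for seg in segments:
        tol = 3 * max(1, (seg.end - seg.start) // max(1, seg.n_bins))
        start = snap(seg.chrom, seg.start, tol)
        end = snap(seg.chrom, seg.end, tol)
        if start < end:
            out.append(SegmentCN(seg.chrom, start, end, seg.copy_number, seg.n_bins))
    return out


class _CopyBudget:
    """Per-position traversal budget: round(CN) - 1 (the intact homolog)."""

    def __init__(self, segments: Optional[Sequence[SegmentCN]], chrom_lengths: dict[str, int]):
        self.chrom_lengths = chrom_lengths
        self.boundaries: dict[str, list[tuple[int, int]]] = {}
        if segments:
            for seg in segments:
                # permissive rounding: the budget must block truly deleted
                # regions and exhausted broken ends, not punish depth
                # under-measurement of duplicated segments
                avail = max(0, int(round(seg.copy_number - 1 + 0.33)))
                self.boundaries.setdefault(seg.chrom, []).append((seg.start, avail))
            for chrom in self.boundaries:
                self.boundaries[chrom].sort()
        self.used: dict[str, list[tuple[int, int]]] = {}

    def _avail(self, chrom: str, pos: int) -> int:
        base = 1
        for start, avail in self.boundaries.get(chrom, []):
            if start <= pos:
                base = avail
            else:
                break
        return base - sum(1 for s, e in self.used.get(chrom, []) if s <= pos < e)

    def furthest(self, chrom: str, pos: int, direction: int, limit: int) -> int:
        """Furthest coordinate reachable from pos toward limit with budget > 0."""
        points = {pos, limit}
        for start, _ in self.boundaries.get(chrom, []):
            points.add(start)
        for s, e in self.used.get(chrom, []):
            points.update((s, e))
        if direction > 0:
            stops = sorted(p for p in points if pos < p <= limit)
            cur = pos
            for p in stops:
                if self._avail(chrom, cur) <= 0:
                    return cur
                cur = p
            return cur if self._avail(chrom, cur - 1 if cur > pos else cur) >= 0 else cur
        stops = sorted((p for p in points if limit <= p < pos), reverse=True)
        cur = pos
        for p in stops:
            if self._avail(chrom, cur - 1) <= 0:
                return cur
            cur = p
        return cur

    def consume(self, chrom: str, start: int, end: int) -> None:
        if end > start:
            self.used.setdefault(chrom, []).append((start, end))


def build_derivative(
    junctions: Sequence[Junction],
    segments: Optional[Sequence[SegmentCN]],
    start_anchor: tuple[str, int, int],
    chrom_lengths: dict[str, int],
    max_segments: int = 50,
    mosaic_fraction: Optional[float] = None,
) -> DerivativeChromosome:
    """Greedy walk from ``start_anchor`` (chrom, pos, direction ±1).

    The walk proceeds along the reference until it reaches a junction end
    whose retained flank faces the traversed side, jumps to the partner end
    (flipping direction as the orientation encodes), and repeats; traversal
    consumes copy budget derived from ``segments`` so it halts at exhausted
    intervals (broken ends) and telomeres, or closes a ring on re-entering the
    start.  Ties between junction ends at one position break by higher
    support, then lexicographic partner.  A walk exceeding ``max_segments``
    returns a complex-unresolved derivative rather than raising.
    """
    chrom0, pos0, dir0 = start_anchor
    if segments:
        segments = _snap_segments(segments, junctions)
    budget = _CopyBudget(segments, chrom_lengths)

    # index junction ends
    ends: list[tuple[JunctionEnd, JunctionEnd, Junction]] = []
    for j in junctions:
        ends.append((j.end_a, j.end_b, j))
        ends.append((j.end_b, j.end_a, j))
    used_junctions: dict[int, int] = {}

    out_segments: list[tuple[str, int, int, str]] = []
    used_list: list[Junction] = []
    circular = False
    chrom, pos, direction = chrom0, pos0, dir0

    if not junctions:
        return DerivativeChromosome(
            segments=[(chrom0, 0, chrom_lengths[chrom0], "+")],
            circular=False,
            motif_label="REFERENCE",
            mosaic_fraction=mosaic_fraction,
            junctions_used=[],
        )

    for _ in range(max_segments):
        want = "+" if direction > 0 else "-"
        candidates = []
        for end, partner, j in ends:
            if end[0] != chrom or end[2] != want:
                continue
            if used_junctions.get(id(j), 0) >= 1:
                continue
            if direction > 0 and end[1] > pos:
                candidates.append((end, partner, j))
            elif direction < 0 and end[1] < pos:
                candidates.append((end, partner, j))
            elif end[1] == pos and not out_segments:
                # allow a junction exactly at the anchor only after moving
                continue
        if candidates:
            if direction > 0:
                best_pos = min(c[0][1] for c in candidates)
            else:
                best_pos = max(c[0][1] for c in candidates)
            at_pos = [c for c in candidates if c[0][1] == best_pos]
            at_pos.sort(key=lambda c: (-c[2].n_support, c[1]))
            end, partner, junction = at_pos[0]
            target = end[1]
        else:
            end = partner = junction = None
            target = chrom_lengths[chrom] if direction > 0 else 0

        # traverse toward target, limited by copy budget
        reach = budget.furthest(chrom, pos, direction, target)
        seg_lo, seg_hi = (pos, reach) if direction > 0 else (reach, pos)
        if seg_hi > seg_lo:
            out_segments.append(
                (chrom, seg_lo, seg_hi, "+" if direction > 0 else "-")
            )
            budget.consume(chrom, seg_lo, seg_hi)
        if reach != target or junction is None:
            break  # broken end (budget exhausted) or telomere
        used_junctions[id(junction)] = used_junctions.get(id(junction), 0) + 1
        used_list.append(junction)
        chrom, pos = partner[0], partner[1]
        direction = 1 if partner[2] == "-" else -1
        if (chrom, pos, direction) == (chrom0, pos0, dir0):
            circular = True
            break
    else:
        return DerivativeChromosome(
            segments=out_segments,
            circular=False,
            motif_label="COMPLEX",
            mosaic_fraction=mosaic_fraction,
            junctions_used=used_list,
            resolved=False,
            annotations={"reason": "walk exceeded max_segments"},
        )

    derivative = DerivativeChromosome(
        segments=out_segments,
        circular=circular,
        motif_label="COMPLEX",
        mosaic_fraction=mosaic_fraction,
        junctions_used=used_list,
    )
    derivative.motif_label = classify_rearrangement(derivative, segments, chrom_lengths)
    return derivative


def resolve_derivative(
    junctions: Sequence[Junction],
    segments: Optional[Sequence[SegmentCN]],
    chrom_lengths: dict[str, int],
    max_segments: int = 50,
    mosaic_fraction: Optional[float] = None,
) -> DerivativeChromosome:
    """Reconstruct the derivative from the best-scoring walk anchor.

    Candidate anchors are the ends of terminally deleted copy-number segments
    (the derivative's surviving side) and both telomeres of every
    junction-bearing chromosome; the walk using the most junctions wins, with
    total reconstructed length as the tie-break.  This automates the anchor
    choice a manual derivative resolution would make by eye.
    """
    candidates: list[tuple[str, int, int]] = []
    chroms = sorted({end[0] for j in junctions for end in (j.end_a, j.end_b)})
    if not chroms:
        chroms = list(chrom_lengths)[:1]
    for chrom in chroms:
        candidates.append((chrom, 0, 1))
        candidates.append((chrom, chrom_lengths[chrom], -1))
    if segments:
        snapped = _snap_segments(segments, junctions)
        for seg in snapped:
            if seg.chrom not in chroms or seg.copy_number >= 1.5:
                continue
            if seg.start == 0:
                candidates.insert(0, (seg.chrom, seg.end, 1))
            if seg.end == chrom_lengths.get(seg.chrom):
                candidates.insert(0, (seg.chrom, seg.start, -1))
    best = None
    best_score = None
    for anchor in candidates:
        der = build_derivative(
            junctions, segments, anchor, chrom_lengths, max_segments, mosaic_fraction
        )
        score = (
            len(der.junctions_used),
            der.circular,
            sum(e - s for _, s, e, _ in der.segments),
        )
        if best_score is None or score > best_score:
            best, best_score = der, score
    return best


# ---------------------------------------------------------------------------
# motif classification
# ---------------------------------------------------------------------------


def _interval_multiplicity(
    derivative: DerivativeChromosome, chrom_lengths: dict[str, int]
) -> dict[str, list[tuple[int, int, int, int]]]:
    """Per chrom: (start, end, copies traversed, inverted copies) intervals."""
    out = {}
    chroms = {seg[0] for seg in derivative.segments}
    for chrom in chroms:
        points = {0, chrom_lengths[chrom]}
        for c, s, e, _ in derivative.segments:
            if c == chrom:
                points.update((s, e))
        pts = sorted(points)
        rows = []
        for lo, hi in zip(pts[:-1], pts[1:]):
            fwd = sum(
                1
                for c, s, e, o in derivative.segments
                if c == chrom and s <= lo and hi <= e and o == "+"
            )
            rev = sum(
                1
                for c, s, e, o in derivative.segments
                if c == chrom and s <= lo and hi <= e and o == "-"
            )
            rows.append((lo, hi, fwd + rev, rev))
        out[chrom] = rows
    return out


def classify_rearrangement(
    derivative: DerivativeChromosome,
    segments: Optional[Sequence[SegmentCN]] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> str:
    """Label the rearrangement motif from the oriented segment word.

    Rules, in order: circular -> RING; no junctions -> REFERENCE; two
    chromosomes joined by one junction -> UNBALANCED_TRANSLOCATION; then, on
    one chromosome, the interval multiplicity/orientation profile separates
    DEL, DUP, INV (annotating any breakpoint deletion), DEL-INV-DUP and
    DUP-TRP/INV-DUP; anything else is COMPLEX.
    """
    if derivative.circular:
        return "RING"
    if not derivative.junctions_used:
        return "REFERENCE"
    chroms = {seg[0] for seg in derivative.segments}
    if len(chroms) > 1:
        if len(derivative.junctions_used) == 1:
            return "UNBALANCED_TRANSLOCATION"
        return "COMPLEX"
    if chrom_lengths is None:
        chrom_lengths = {
            seg[0]: max(s[2] for s in derivative.segments) for seg in derivative.segments
        }
    (chrom,) = chroms
    rows = _interval_multiplicity(derivative, chrom_lengths)[chrom]
    zero = [(lo, hi) for lo, hi, mult, _ in rows if mult == 0]
    ones = [(lo, hi) for lo, hi, mult, _ in rows if mult == 1]
    twos = [(lo, hi, rev) for lo, hi, mult, rev in rows if mult == 2]
    threes = [(lo, hi, rev) for lo, hi, mult, rev in rows if mult == 3]
    more = [(lo, hi) for lo, hi, mult, _ in rows if mult > 3]
    inverted_once = [
        (lo, hi) for lo, hi, mult, rev in rows if mult == 1 and rev == 1
    ]

    if more:
        return "COMPLEX"
    if threes:
        if all(rev >= 1 for _, _, rev in threes) and twos:
            return "DUP-TRP/INV-DUP"
        return "COMPLEX"
    if twos:
        if any(rev >= 1 for _, _, rev in twos):
            if zero:
                return "DEL-INV-DUP"
            return "COMPLEX"
        # co-linear duplication; a small deleted interval would make it complex
        if zero:
            return "COMPLEX"
        return "DUP"
    if inverted_once:
        if zero:
            derivative.annotations["breakpoint_deletion_bp"] = sum(
                hi - lo for lo, hi in zero
            )
        return "INV"
    if zero:
        internal = [
            (lo, hi)
            for lo, hi in zero
            if lo > 0 and hi < chrom_lengths[chrom]
        ]
        if len(zero) == 1 or internal:
            return "DEL"
    return "COMPLEX"


# ---------------------------------------------------------------------------
# mosaic fraction
# ---------------------------------------------------------------------------


@dataclass
class MosaicEstimate:
    fraction: float  # raw 2 * support / spanning, capped at 1
    percent: int  # truncated integer percent
    support: int
    spanning: int


def estimate_mosaic_fraction(
    junction_support: int, spanning_read_count: int
) -> Optional[MosaicEstimate]:
    """Cell fraction of a junction under the one-of-two-homologs model.

    fraction = min(1, 2 * support / spanning); the integer percent is
    truncated, not rounded (6 of 28 reads -> 42%).  Returns None (no-call)
    when no read spans the breakpoint.
    """
    if spanning_read_count == 0:
        return None
    if junction_support > spanning_read_count:
        raise InvalidArgumentError("support cannot exceed spanning read count")
    fraction = min(1.0, 2.0 * junction_support / spanning_read_count)
    return MosaicEstimate(
        fraction=fraction,
        percent=int(math.floor(fraction * 100)),
        support=junction_support,
        spanning=spanning_read_count,
    )


def count_spanning_reads(
    reads: Sequence[ReadAlignment],
    junction: Junction,
    min_anchor: int = 50,
) -> int:
    """Reads informative at a breakpoint: junction carriers plus reads that
    align straight through either breakpoint end."""
    support = set(junction.support)
    n = len(support)
    for read in reads:
        if read.read_id in support:
            continue
        if read.spans_contiguously(
            junction.end_a[0], junction.end_a[1], min_anchor
        ) or read.spans_contiguously(junction.end_b[0], junction.end_b[1], min_anchor):
            n += 1
    return n


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def infer_start_anchor(
    junctions: Sequence[Junction],
    segments: Optional[Sequence[SegmentCN]],
    chrom_lengths: dict[str, int],
) -> tuple[str, int, int]:
    """Heuristic walk anchor: after a terminal deleted segment when one
    exists on the junction-bearing chromosome, else the chromosome start."""
    if not junctions:
        chrom = next(iter(chrom_lengths))
        return (chrom, 0, 1)
    chrom = junctions[0].end_a[0]
    if segments:
        for seg in segments:
            if seg.chrom == chrom and seg.start == 0 and seg.copy_number < 1.5:
                return (chrom, seg.end, 1)
        last = max((s for s in segments if s.chrom == chrom), key=lambda s: s.end, default=None)
        if last is not None and last.end == chrom_lengths[chrom] and last.copy_number < 1.5:
            return (chrom, last.start, -1)
    return (chrom, 0, 1)


def reconstruct_from_reads(
    reads: Sequence[ReadAlignment],
    chrom_lengths: dict[str, int],
    bin_size: int = 1000,
    pos_tolerance: int = 50,
    min_support: int = 3,
    mosaic_fraction: Optional[float] = None,
) -> tuple[DerivativeChromosome, list[Junction], list[SegmentCN]]:
    """Full pipeline: extract + cluster junctions, junction-aware copy number,
    anchor-scored derivative walk.  Returns (derivative, junctions, segments)."""
    raw = extract_junctions(reads)
    junctions, _ = cluster_junctions(raw, pos_tolerance, min_support)
    bounds: dict[str, list[int]] = {}
    for j in junctions:
        for chrom, pos, _ in (j.end_a, j.end_b):
            bounds.setdefault(chrom, []).append(pos)
    segments = segment_copy_number(
        reads, chrom_lengths, bin_size=bin_size, boundaries=bounds
    )
    derivative = resolve_derivative(
        junctions, segments, chrom_lengths, mosaic_fraction=mosaic_fraction
    )
    return derivative, junctions, segments


def junctions_to_breakend_vcf(
    junctions: Sequence[Junction], chrom_lengths: dict[str, int], path: str
) -> None:
    """Export junctions as paired VCF breakend (BND) records (1-based)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">')
    header.add_line(
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">'
    )
    for chrom, length in chrom_lengths.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    with pysam.VariantFile(path, "w", header=header) as out:
        for i, j in enumerate(junctions):
            for tag, end, mate in (
                (f"bnd_{i}_a", j.end_a, j.end_b),
                (f"bnd_{i}_b", j.end_b, j.end_a),
            ):
                chrom, pos, orient = end
                mchrom, mpos, morient = mate
                mate_ref = f"{mchrom}:{mpos + 1}"
                # '+' retains the left flank: the breakend extends to the right
                # partner; bracket direction encodes the partner's retained side
                bracket = "[" if morient == "-" else "]"
                alt = (
                    f"N{bracket}{mate_ref}{bracket}"
                    if orient == "+"
                    else f"{bracket}{mate_ref}{bracket}N"
                )
                rec = out.new_record(
                    contig=chrom,
                    start=max(0, pos - (1 if orient == "+" else 0)),
                    alleles=("N", alt),
                    id=tag,
                )
                rec.info["SVTYPE"] = "BND"
                rec.info["MATEID"] = f"bnd_{i}_{'b' if tag.endswith('a') else 'a'}"
                rec.info["SUPPORT"] = j.n_support
                out.write(rec)


def render_subway(derivative: DerivativeChromosome) -> str:
    """Deterministic text rendering of the derivative's segment path."""
    parts = [
        f"{chrom}:{start}-{end}{'(+)' if orient == '+' else '(-)'}"
        for chrom, start, end, orient in derivative.segments
    ]
    arrow = " -> ".join(parts)
    if derivative.circular:
        arrow += " -> (ring closure)"
    lines = [
        f"motif: {derivative.motif_label}",
        f"path:  {arrow}",
    ]
    if derivative.mosaic_fraction is not None:
        lines.append(f"mosaic fraction: {derivative.mosaic_fraction:.3f}")
    return "\n".join(lines) + "\n"
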