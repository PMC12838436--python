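"""Shared primitives: aligned-read container, CIGAR walking, variant support.

The in-memory unit of the whole toolkit is :class:`ReadAlignment` — one long
read together with its (possibly chimeric) alignment, per-CpG methylation
probability calls and an optional haplotype tag.  SAM round-tripping lives in
:mod:`lorediag.samio`; everything downstream (STR profiling, methylation,
phasing, SV reconstruction) consumes lists of ``ReadAlignment``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CIGAR_CONSUMES_REF = {"M", "D", "=", "X"}
CIGAR_CONSUMES_QUERY = {"M", "I", "S", "=", "X"}


class LorediagError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(LorediagError, ValueError):
    """An argument violates a documented precondition."""


class BoundsError(LorediagError, ValueError):
    """A coordinate falls outside the reference."""


class ConfigurationError(LorediagError):
    """Required configuration (catalog thresholds, control pool, ...) missing."""


class NonSpanningReadError(LorediagError):
    """Read does not span both flank anchors of an STR locus."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InvalidArgumentError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def cigar_to_string(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{length}{op}" for op, length in cigar)


def cigar_from_string(s: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


@dataclass
class MethCall:
    """One CpG methylation probability call on one read.

    ``ref_pos`` is the 0-based reference coordinate of the CpG cytosine (None
    when the cytosine lies in read sequence without a reference mapping, e.g.
    inside an expanded repeat insertion — such calls carry the projected
    position of the last mapped base instead when the simulator produced them).
    """

    chrom: Optional[str]
    ref_pos: Optional[int]
    read_pos: int  # position in the original (as-sequenced) read
    prob: float


@dataclass
class AlignmentBlock:
    """One alignment record of a (possibly chimeric) read.

    ``cigar`` is in reference-forward order and includes the soft clips that
    represent the rest of the read.  ``read_start``/``read_end`` give the
    half-open interval of the *original* read covered by this block.
    """

    chrom: str
    ref_start: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    read_start: int
    read_end: int
    mapq: int = 60

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(
            length for op, length in self.cigar if op in CIGAR_CONSUMES_REF
        )

    @property
    def aligned_length(self) -> int:
        return sum(length for op, length in self.cigar if op == "M")

    def covers(self, pos: int) -> bool:
        return self.ref_start <= pos < self.ref_end


@dataclass
class ReadAlignment:
    """A long read with alignment blocks ordered along the read."""

    read_id: str
    seq: str  # original read orientation
    blocks: list[AlignmentBlock]
    haplotype: Optional[int] = None
    meth_calls: list[MethCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.read_start)

    # -- sequence access -------------------------------------------------

    def stored_seq(self, block: AlignmentBlock) -> str:
        """Read sequence in reference-forward orientation for ``block``."""
        return self.seq if block.strand == "+" else revcomp(self.seq)

    @property
    def primary_block(self) -> AlignmentBlock:
        return max(self.blocks, key=lambda b: b.aligned_length)

    def aligned_forward_seq(self) -> str:
        """Full read sequence oriented to match the primary block's strand."""
        return self.stored_seq(self.primary_block)

    # -- coordinate queries ----------------------------------------------

    def _walk(self, block: AlignmentBlock):
        """Yield (op, length, ref_pos, stored_pos) for each CIGAR op."""
        rpos = block.ref_start
        qpos = 0
        for op, length in block.cigar:
            yield op, length, rpos, qpos
            if op in CIGAR_CONSUMES_REF:
                rpos += length
            if op in CIGAR_CONSUMES_QUERY:
                qpos += length

    def base_at(self, chrom: str, pos: int) -> Optional[str]:
        """Reference-forward read base aligned at ``(chrom, pos)``.

        Returns None when the position is not covered by an M op (deleted or
        outside all blocks).
        """
        for block in self.blocks:
            if block.chrom != chrom or not block.covers(pos):
                continue
            stored = self.stored_seq(block)
            for op, length, rpos, qpos in self._walk(block):
                if op == "M" and rpos <= pos < rpos + length:
                    return stored[qpos + (pos - rpos)].upper()
        return None

    def insertion_after(self, chrom: str, pos: int) -> Optional[str]:
        """Sequence inserted immediately after reference position ``pos``.

        Returns '' when the read covers pos and pos+1 contiguously with no
        insertion, the inserted string when there is one, and None when the
        read does not align across that point.
        """
        for block in self.blocks:
            if block.chrom != chrom or not (block.ref_start <= pos < block.ref_end - 1):
                continue
            stored = self.stored_seq(block)
            covered_left = False
            for op, length, rpos, qpos in self._walk(block):
                if op == "M" and rpos <= pos < rpos + length:
                    covered_left = True
                    if pos < rpos + length - 1:
                        return ""  # next base is a match: no insertion
                elif covered_left and op == "I":
                    return stored[qpos : qpos + length].upper()
                elif covered_left and op in ("M", "D"):
                    return ""
            return None
        return None

    def has_deletion(self, chrom: str, start: int, end: int) -> Optional[bool]:
        """True if a D op exactly covers [start, end); None if not covered."""
        for block in self.blocks:
            if block.chrom != chrom or not (
                block.ref_start < start and end < block.ref_end
            ):
                continue
            for op, length, rpos, _ in self._walk(block):
                if op == "D" and rpos == start and rpos + length == end:
                    return True
            return False
        return None

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(
            b.chrom == chrom and b.ref_start < end and b.ref_end > start
            for b in self.blocks
        )

    def spans_contiguously(self, chrom: str, pos: int, min_anchor: int = 50) -> bool:
        """Read aligns through ``pos`` with ``min_anchor`` matched bases on
        both sides within a single block (i.e. no junction at ``pos``)."""
        return any(
            b.chrom == chrom
            and b.ref_start + min_anchor <= pos
            and pos + min_anchor <= b.ref_end
            for b in self.blocks
        )


@dataclass(frozen=True)
class SmallVariant:
    """A VCF-style small variant (1-based position, normalized alleles)."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InvalidArgumentError("ref and alt alleles must differ")
        if self.pos < 1:
            raise InvalidArgumentError("VCF positions are 1-based (pos >= 1)")


def variant_support(read: ReadAlignment, variant: SmallVariant) -> Optional[bool]:
    """Does ``read`` carry the alt allele of ``variant``?

    Returns True (alt), False (ref) or None (read uninformative at the site).
    Handles SNVs and VCF-normalized insertions/deletions (ref/alt share their
    first base, as produced by standard normalization).
    """
    pos0 = variant.pos - 1
    if len(variant.ref) == 1 and len(variant.alt) == 1:
        base = read.base_at(variant.chrom, pos0)
        if base is None:
            return None
        if base == variant.alt.upper():
            return True
        if base == variant.ref.upper():
            return False
        return None
    if len(variant.alt) > len(variant.ref) and variant.alt.startswith(variant.ref):
        ins = variant.alt[len(variant.ref) :].upper()
        anchor_end = pos0 + len(variant.ref) - 1
        observed = read.insertion_after(variant.chrom, anchor_end)
        if observed is None:
            return None
        if observed == ins:
            return True
        return False if observed == "" else None  # a different insertion: uninformative
    if len(variant.ref) > len(variant.alt) and variant.ref.startswith(variant.alt):
        del_start = pos0 + len(variant.alt)
        del_end = pos0 + len(variant.ref)
        return read.has_deletion(variant.chrom, del_start, del_end)
    # Complex substitution: compare the replaced bases directly.
    bases = [read.base_at(variant.chrom, pos0 + i) for i in range(len(variant.ref))]
    if any(b is None for b in bases):
        return None
    return "".join(bases) == variant.alt.upper()


def mean_depth(reads: Iterable[ReadAlignment], chrom: str, start: int, end: int) -> float:
    """Mean aligned depth over [start, end) from block spans."""
    if end <= start:
        raise InvalidArgumentError("empty interval")
    total = 0
    for read in reads:
        for b in read.blocks:
            if b.chrom == chrom:
                total += max(0, min(b.ref_end, end) - max(b.ref_start, start))
    return total / (end - start)
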