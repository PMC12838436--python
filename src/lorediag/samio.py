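"""SAM/BAM round-tripping for :class:`~lorediag.core.ReadAlignment`.

Chimeric reads are written as one primary record plus supplementary records
linked by SA tags, with soft clips representing the rest of the read.  CpG
methylation probabilities are written as standard modified-base MM/ML tags
(``C+m?`` with probabilities scaled to 0-255) on the primary record, relative
to the original read orientation, and decoded back via pysam.
"""

from __future__ import annotations

from typing import Optional

import pysam

from .core import AlignmentBlock, MethCall, ReadAlignment, cigar_to_string

_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5}
_CODE_OP = {v: k for k, v in _OP_CODE.items()}


def _sa_entry(block: AlignmentBlock, mapq: int) -> str:
    return (
        f"{block.chrom},{block.ref_start + 1},{block.strand},"
        f"{cigar_to_string(block.cigar)},{mapq},0"
    )


def _mm_ml_tags(read: ReadAlignment) -> Optional[tuple[str, list[int]]]:
    """MM/ML strings for the read's CpG calls, in original-read orientation."""
    if not read.meth_calls:
        return None
    c_positions = [i for i, b in enumerate(read.seq) if b in "Cc"]
    c_rank = {pos: rank for rank, pos in enumerate(c_positions)}
    calls = sorted(
        (c for c in read.meth_calls if c.read_pos in c_rank),
        key=lambda c: c.read_pos,
    )
    if not calls:
        return None
    deltas = []
    probs = []
    prev_rank = -1
    for call in calls:
        rank = c_rank[call.read_pos]
        deltas.append(rank - prev_rank - 1)
        prev_rank = rank
        probs.append(max(0, min(255, int(call.prob * 256))))
    mm = "C+m?," + ",".join(str(d) for d in deltas) + ";"
    return mm, probs


def write_sam(
    reads: list[ReadAlignment], chrom_lengths: dict[str, int], path: str
) -> None:
    """Write coordinate-sorted SAM (or BAM if the path ends in .bam)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
    }
    tids = {name: i for i, name in enumerate(chrom_lengths)}
    records = []
    for read in reads:
        primary = read.primary_block
        tags = _mm_ml_tags(read)
        for block in read.blocks:
            seg = pysam.AlignedSegment()
            seg.query_name = read.read_id
            seg.flag = (16 if block.strand == "-" else 0) | (
                0 if block is primary else 2048
            )
            seg.reference_id = tids[block.chrom]
            seg.reference_start = block.ref_start
            seg.mapping_quality = block.mapq
            seg.cigartuples = [(_OP_CODE[op], length) for op, length in block.cigar]
            seg.query_sequence = read.stored_seq(block)
            if read.haplotype is not None:
                seg.set_tag("HP", int(read.haplotype))
            if len(read.blocks) > 1:
                others = [b for b in read.blocks if b is not block]
                seg.set_tag("SA", ";".join(_sa_entry(b, b.mapq) for b in others) + ";")
            if block is primary and tags is not None:
                mm, probs = tags
                seg.set_tag("MM", mm)
                seg.set_tag("ML", probs)
            records.append(seg)
    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for rec in records:
            out.write(rec)
    if path.endswith(".bam"):
        pysam.index(path)


def _block_from_record(rec: pysam.AlignedSegment) -> AlignmentBlock:
    cigar = [(_CODE_OP[code], length) for code, length in rec.cigartuples]
    lead = cigar[0][1] if cigar[0][0] in "SH" else 0
    trail = cigar[-1][1] if cigar[-1][0] in "SH" else 0
    total = sum(l for op, l in cigar if op in "MIS H".replace(" ", ""))
    strand = "-" if rec.is_reverse else "+"
    if strand == "+":
        read_start, read_end = lead, total - trail
    else:
        read_start, read_end = trail, total - lead
    return AlignmentBlock(
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        strand=strand,
        cigar=cigar,
        read_start=read_start,
        read_end=read_end,
        mapq=rec.mapping_quality,
    )


def load_sam(path: str) -> list[ReadAlignment]:
    """Load alignments back into ReadAlignment objects (grouped by read name)."""
    grouped: dict[str, dict] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            entry = grouped.setdefault(
                rec.query_name, {"blocks": [], "primary": None}
            )
            entry["blocks"].append(_block_from_record(rec))
            if not rec.is_supplementary:
                entry["primary"] = rec.to_dict() | {
                    "_seq_fwd": rec.get_forward_sequence(),
                    "_hp": rec.get_tag("HP") if rec.has_tag("HP") else None,
                    "_meth": _decode_meth(rec),
                }
    reads = []
    for name, entry in grouped.items():
        prim = entry["primary"]
        if prim is None:
            continue
        reads.append(
            ReadAlignment(
                read_id=name,
                seq=prim["_seq_fwd"],
                blocks=entry["blocks"],
                haplotype=prim["_hp"],
                meth_calls=prim["_meth"],
            )
        )
    return reads


def _decode_meth(rec: pysam.AlignedSegment) -> list[MethCall]:
    """Decode MM/ML CpG calls into MethCalls with reference coordinates."""
    mods = rec.modified_bases  # positions relative to SEQ as stored
    if not mods:
        return []
    ref_map = dict(rec.get_aligned_pairs(matches_only=True))
    length = rec.query_length
    calls = []
    for (base, _strand, code), entries in mods.items():
        if base != "C" or code != "m":
            continue
        for stored_pos, qual in entries:
            read_pos = length - 1 - stored_pos if rec.is_reverse else stored_pos
            calls.append(
                MethCall(
                    chrom=rec.reference_name,
                    ref_pos=ref_map.get(stored_pos),
                    read_pos=read_pos,
                    prob=(qual + 0.5) / 256.0,
                )
            )
    calls.sort(key=lambda c: c.read_pos)
    return calls
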