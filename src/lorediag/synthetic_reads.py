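"""Synthetic references and aligned long reads with planted ground truth.

Every downstream analysis in this package is validated as a *recovery* test:
the simulator plants two haplotypes per sample (SNVs/indels, STR alleles with
interruption motifs, per-region CpG methylation levels) and, optionally,
derivative chromosomes described as ordered oriented segment lists, then emits
reads whose alignments are computed analytically from the plant — including
supplementary-alignment chains and soft clips at rearrangement junctions, and
per-CpG methylation probability calls.  A mandatory ground-truth sidecar
records each read's donor haplotype so recovery can be scored exactly.

Read lengths follow a log-normal law fitted to the target (median, N50) pair:
``mu = ln(median)`` and, because the N50 of a log-normal is the median of its
length-biased version ``exp(mu + sigma^2)``, ``sigma = sqrt(ln(N50/median))``.
The defaults (median 5 kb, N50 16 kb, 34X) emulate nanopore sequencing of
routine clinical DNA extractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AlignmentBlock,
    BoundsError,
    InvalidArgumentError,
    MethCall,
    ReadAlignment,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# A reference-space gap at least this large in a read's mapping is modelled as
# a breakpoint junction (split alignment) rather than a CIGAR deletion.
SPLIT_GAP = 100


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class MethylOverride:
    """Per-region methylation level for one haplotype."""

    chrom: str
    start: int
    end: int
    level: float


@dataclass
class HaplotypeSpec:
    """One planted haplotype of a sample.

    ``variants`` are (0-based position, ref allele, alt allele) on a named
    chromosome; ``str_allele`` optionally replaces a catalog locus tract with
    ``repeat_count`` units of its motif, with ``interruptions`` as (unit index,
    motif) pairs; ``methyl_level`` is the baseline CpG methylation probability
    (None disables methylation emission for reads of this haplotype) and
    ``methyl_overrides`` refine it per region; ``weight`` is the fraction of
    cells carrying this haplotype.
    """

    haplotype_id: int
    variants: list[tuple[str, int, str, str]] = field(default_factory=list)
    str_allele: Optional[tuple[str, int, list[tuple[int, str]]]] = None
    methyl_level: Optional[float] = None
    methyl_overrides: list[MethylOverride] = field(default_factory=list)
    weight: float = 0.5

    def __post_init__(self) -> None:
        by_chrom: dict[str, int] = {}
        for chrom, pos, _, _ in self.variants:
            if chrom in by_chrom and pos <= by_chrom[chrom]:
                raise InvalidArgumentError(
                    "variant positions must be strictly increasing per chromosome"
                )
            by_chrom[chrom] = pos
        if self.str_allele is not None and self.str_allele[1] < 0:
            raise InvalidArgumentError("repeat_count must be >= 0")
        if self.methyl_level is not None and not 0.0 <= self.methyl_level <= 1.0:
            raise InvalidArgumentError("methyl_level must lie in [0, 1]")
        if not 0.0 <= self.weight <= 1.0:
            raise InvalidArgumentError("haplotype weight must lie in [0, 1]")


@dataclass
class DerivativePlan:
    """A derivative chromosome as an ordered, oriented segment list.

    Segments are (chrom, start, end, orientation) with half-open 0-based
    intervals; ``circular`` closes the last segment onto the first (ring
    chromosome); ``cell_fraction`` is the fraction of cells in which this
    derivative replaces one homolog (the one built from haplotype
    ``replaces_haplotype``).
    """

    segments: list[tuple[str, int, int, str]]
    circular: bool = False
    cell_fraction: float = 1.0
    replaces_haplotype: int = 2
    name: str = "der1"

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidArgumentError("a derivative needs at least one segment")
        for chrom, start, end, orient in self.segments:
            if start >= end:
                raise InvalidArgumentError("segment intervals are half-open, start < end")
            if orient not in "+-":
                raise InvalidArgumentError("orientation must be '+' or '-'")
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise InvalidArgumentError("cell_fraction must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Sequencing-emulation knobs; defaults mirror routine clinical nanopore runs."""

    coverage: float = 34.0
    read_length_median: int = 5_000
    read_length_n50: int = 16_000
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    methyl_call_noise: float = 0.05
    seed: int = 0
    both_strands: bool = True
    min_read_length: int = 100

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= rate < 1.0:
                raise InvalidArgumentError("error rates must lie in [0, 1)")
        if self.coverage <= 0:
            raise InvalidArgumentError("coverage must be positive")
        if self.read_length_median > self.read_length_n50:
            raise InvalidArgumentError("median read length cannot exceed N50")

    @property
    def lognormal_mu(self) -> float:
        return math.log(self.read_length_median)

    @property
    def lognormal_sigma(self) -> float:
        return math.sqrt(math.log(self.read_length_n50 / self.read_length_median))

    @property
    def mean_read_length(self) -> float:
        return math.exp(self.lognormal_mu + self.lognormal_sigma**2 / 2)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def make_reference(
    n_chroms: int, length_per_chrom: int, gc_fraction: float = 0.41, seed: int = 0
) -> dict[str, str]:
    """Random reference with i.i.d. bases at the requested GC fraction.

    Deterministic for a fixed seed; chromosomes are named chr1..chrN.
    """
    if n_chroms < 1 or length_per_chrom <= 0:
        raise InvalidArgumentError("need n_chroms >= 1 and a positive length")
    if not 0.0 < gc_fraction < 1.0:
        raise InvalidArgumentError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    out = {}
    for i in range(n_chroms):
        draws = rng.choice(_BASES, size=length_per_chrom, p=p)
        out[f"chr{i + 1}"] = draws.tobytes().decode("ascii")
    return out


def write_fasta(reference: dict[str, str], path: str, line_width: int = 60) -> None:
    """Write a FASTA file and build its .fai index sidecar."""
    import pysam

    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    pysam.faidx(path)


# ---------------------------------------------------------------------------
# donor construction
# ---------------------------------------------------------------------------


@dataclass
class _Molecule:
    """One simulated DNA molecule with a per-base map back to the reference."""

    name: str
    seq: np.ndarray  # uint8 ASCII
    chrom_idx: np.ndarray  # int32, -1 for inserted bases
    ref_pos: np.ndarray  # int64, -1 for inserted bases
    strand: np.ndarray  # int8 (+1/-1)
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class _Donor:
    donor_id: str
    haplotype: int
    molecules: list[_Molecule]
    weight: float
    methyl_level: Optional[float]
    methyl_overrides: list[MethylOverride]
    is_derivative: bool = False

    @property
    def total_len(self) -> int:
        return sum(len(m) for m in self.molecules)


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def build_tract(motif: str, repeat_count: int, interruptions: Sequence[tuple[int, str]]) -> str:
    """Repeat tract sequence: canonical units with planted interruptions."""
    inter = dict(interruptions)
    for idx, m in inter.items():
        if len(m) != len(motif):
            raise InvalidArgumentError("interruption motifs must preserve unit length")
        if not 0 <= idx < repeat_count:
            raise InvalidArgumentError("interruption unit index outside the tract")
    return "".join(inter.get(i, motif) for i in range(repeat_count))


def _apply_edits(
    chrom: str,
    chrom_i: int,
    ref_seq: str,
    edits: list[tuple[int, str, str]],
) -> _Molecule:
    """Apply (pos, ref, alt) replacements to one chromosome.

    The first min(len(ref), len(alt)) replacement bases stay colinear with the
    reference; surplus alt bases are unmapped insertions, surplus ref bases are
    skipped (deletions).
    """
    seq_parts: list[np.ndarray] = []
    pos_parts: list[np.ndarray] = []
    cur = 0
    ref_arr = _seq_to_arr(ref_seq)
    for pos, ref, alt in sorted(edits):
        if pos < cur:
            raise InvalidArgumentError("overlapping edits on one haplotype")
        if pos + len(ref) > len(ref_seq):
            raise BoundsError("edit extends past the chromosome end")
        if ref and ref_seq[pos : pos + len(ref)].upper() != ref.upper():
            raise InvalidArgumentError(
                f"ref allele mismatch at {chrom}:{pos} (expected {ref})"
            )
        seq_parts.append(ref_arr[cur:pos])
        pos_parts.append(np.arange(cur, pos, dtype=np.int64))
        alt_arr = _seq_to_arr(alt)
        n_colinear = min(len(ref), len(alt))
        mapped = np.full(len(alt), -1, dtype=np.int64)
        mapped[:n_colinear] = np.arange(pos, pos + n_colinear, dtype=np.int64)
        seq_parts.append(alt_arr)
        pos_parts.append(mapped)
        cur = pos + len(ref)
    seq_parts.append(ref_arr[cur:])
    pos_parts.append(np.arange(cur, len(ref_seq), dtype=np.int64))
    seq = np.concatenate(seq_parts)
    ref_pos = np.concatenate(pos_parts)
    n = len(seq)
    return _Molecule(
        name=chrom,
        seq=seq,
        chrom_idx=np.full(n, chrom_i, dtype=np.int32),
        ref_pos=ref_pos,
        strand=np.ones(n, dtype=np.int8),
        circular=False,
    )


def _build_haplotype_molecules(
    reference: dict[str, str],
    spec: HaplotypeSpec,
    str_catalog: Optional[dict] = None,
) -> dict[str, _Molecule]:
    chrom_names = list(reference)
    edits_by_chrom: dict[str, list[tuple[int, str, str]]] = {c: [] for c in chrom_names}
    for chrom, pos, ref, alt in spec.variants:
        if chrom not in reference:
            raise BoundsError(f"unknown chromosome {chrom}")
        edits_by_chrom[chrom].append((pos, ref, alt))
    if spec.str_allele is not None:
        if not str_catalog:
            raise InvalidArgumentError("str_allele given but no STR catalog supplied")
        locus_id, count, interruptions = spec.str_allele
        locus = str_catalog[locus_id]
        tract = build_tract(locus.motif, count, interruptions)
        ref_tract = reference[locus.chrom][locus.start : locus.end]
        edits_by_chrom[locus.chrom].append((locus.start, ref_tract, tract))
    return {
        chrom: _apply_edits(chrom, chrom_names.index(chrom), reference[chrom], edits)
        for chrom, edits in edits_by_chrom.items()
    }


def _build_derivative_molecule(
    plan: DerivativePlan,
    hap_molecules: dict[str, _Molecule],
    chrom_names: list[str],
    reference: dict[str, str],
) -> _Molecule:
    parts: list[_Molecule] = []
    for chrom, start, end, orient in plan.segments:
        if chrom not in reference:
            raise BoundsError(f"unknown chromosome {chrom}")
        if end > len(reference[chrom]):
            raise BoundsError(f"plan segment outside {chrom}")
        mol = hap_molecules[chrom]
        # reference interval -> haplotype-molecule index range
        sel = (mol.ref_pos >= start) & (mol.ref_pos < end)
        # include inserted bases interior to the interval: take the index span
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            raise BoundsError("plan segment maps to an empty haplotype interval")
        lo, hi = idx[0], idx[-1] + 1
        seq = mol.seq[lo:hi]
        rp = mol.ref_pos[lo:hi]
        ci = mol.chrom_idx[lo:hi]
        st = mol.strand[lo:hi]
        if orient == "-":
            comp = np.full(256, ord("N"), dtype=np.uint8)
            for a, b in zip(b"ACGTN", b"TGCAN"):
                comp[a] = b
            seq = comp[seq[::-1]]
            rp = rp[::-1]
            ci = ci[::-1]
            st = (-st[::-1]).astype(np.int8)
        parts.append(_Molecule("part", seq, ci, rp, st))
    return _Molecule(
        name=plan.name,
        seq=np.concatenate([p.seq for p in parts]),
        chrom_idx=np.concatenate([p.chrom_idx for p in parts]),
        ref_pos=np.concatenate([p.ref_pos for p in parts]),
        strand=np.concatenate([p.strand for p in parts]),
        circular=plan.circular,
    )


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def _cigar_core_from_refpos(rp: np.ndarray) -> list[tuple[str, int]]:
    """CIGAR (M/I/D) from a reference-forward-ordered position array."""
    ops: list[tuple[str, int]] = []
    ins = rp < 0
    change = np.flatnonzero(np.diff(ins.view(np.int8))) + 1
    bounds = np.concatenate([[0], change, [len(rp)]])
    last_mapped = None
    for a, b in zip(bounds[:-1], bounds[1:]):
        if ins[a]:
            ops.append(("I", int(b - a)))
            continue
        seg = rp[a:b]
        if last_mapped is not None and seg[0] - last_mapped > 1:
            ops.append(("D", int(seg[0] - last_mapped - 1)))
        d = np.diff(seg)
        jumps = np.flatnonzero(d != 1)
        prev = 0
        for j in jumps:
            ops.append(("M", int(j + 1 - prev)))
            ops.append(("D", int(d[j] - 1)))
            prev = int(j + 1)
        ops.append(("M", int(len(seg) - prev)))
        last_mapped = int(seg[-1])
    # merge adjacent same-op runs (I next to I across bounds cannot occur)
    merged: list[tuple[str, int]] = []
    for op, length in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    return merged


def _blocks_from_fragment(
    chrom_names: list[str],
    seq: np.ndarray,
    chrom_idx: np.ndarray,
    ref_pos: np.ndarray,
    strand: np.ndarray,
    reverse_sequenced: bool,
) -> list[AlignmentBlock]:
    """Split a fragment's per-base map into alignment blocks and build CIGARs."""
    n = len(seq)
    mapped = np.flatnonzero(ref_pos >= 0)
    if len(mapped) == 0:
        return []
    # block boundaries among mapped bases: chrom change, strand change, or a
    # reference-space jump >= SPLIT_GAP in the direction of travel
    mchrom = chrom_idx[mapped]
    mstrand = strand[mapped]
    mrp = ref_pos[mapped]
    step = np.diff(mrp) * mstrand[:-1]
    breaks = (
        (np.diff(mchrom) != 0)
        | (np.diff(mstrand) != 0)
        | (step < -(SPLIT_GAP))  # direction reversal beyond small wobble
        | (step > SPLIT_GAP)
    )
    bidx = np.flatnonzero(breaks) + 1
    bounds = np.concatenate([[0], bidx, [len(mapped)]])
    blocks: list[AlignmentBlock] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lo = mapped[a]
        hi = mapped[b - 1] + 1
        # absorb unmapped (inserted) bases interior to the block; leading or
        # trailing insertions become soft clip via the read-interval bounds
        frag_rp = ref_pos[lo:hi]
        frag_strand = int(strand[lo])
        chrom = chrom_names[int(chrom_idx[lo])]
        if frag_strand > 0:
            rp_fwd = frag_rp
        else:
            rp_fwd = frag_rp[::-1]
        core = _cigar_core_from_refpos(rp_fwd)
        # read interval in fragment coordinates
        q_start, q_end = int(lo), int(hi)
        if reverse_sequenced:
            read_start, read_end = n - q_end, n - q_start
            block_strand = "-" if frag_strand > 0 else "+"
        else:
            read_start, read_end = q_start, q_end
            block_strand = "+" if frag_strand > 0 else "-"
        lead = read_start if block_strand == "+" else n - read_end
        trail = n - read_end if block_strand == "+" else read_start
        cigar = []
        if lead:
            cigar.append(("S", lead))
        cigar += core
        if trail:
            cigar.append(("S", trail))
        blocks.append(
            AlignmentBlock(
                chrom=chrom,
                ref_start=int(rp_fwd[rp_fwd >= 0][0]),
                strand=block_strand,
                cigar=cigar,
                read_start=read_start,
                read_end=read_end,
            )
        )
    return blocks


@dataclass
class SimulatedSample:
    """Reads plus mandatory ground-truth sidecar from one simulation."""

    reads: list[ReadAlignment]
    truth: pd.DataFrame
    reference: dict[str, str]
    config: SimulationConfig

    def write_sam(self, path: str) -> None:
        from .samio import write_sam

        write_sam(self.reads, {c: len(s) for c, s in self.reference.items()}, path)

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_sample(
    reference: dict[str, str],
    haplotype_specs: Sequence[HaplotypeSpec],
    derivative_plans: Sequence[DerivativePlan] = (),
    config: Optional[SimulationConfig] = None,
    str_catalog: Optional[dict] = None,
) -> SimulatedSample:
    """Simulate an aligned long-read sample with planted ground truth.

    Haplotype weights must sum to 1; each derivative plan replaces its source
    haplotype in ``cell_fraction`` of cells, so junction-bearing reads appear
    at an expected rate of ``weight * cell_fraction`` among reads from the
    region (``cell_fraction / 2`` for the canonical two-haplotype sample).
    """
    config = config or SimulationConfig()
    if not haplotype_specs:
        raise InvalidArgumentError("need at least one haplotype spec")
    wsum = sum(h.weight for h in haplotype_specs)
    if abs(wsum - 1.0) > 1e-9:
        raise InvalidArgumentError(f"haplotype weights must sum to 1 (got {wsum})")
    chrom_names = list(reference)
    rng = np.random.default_rng(config.seed)

    hap_ids = {h.haplotype_id for h in haplotype_specs}
    for plan in derivative_plans:
        if plan.replaces_haplotype not in hap_ids:
            raise InvalidArgumentError(
                f"derivative {plan.name} replaces haplotype "
                f"{plan.replaces_haplotype}, which is not among the specs"
            )

    donors: list[_Donor] = []
    for spec in haplotype_specs:
        mols = _build_haplotype_molecules(reference, spec, str_catalog)
        plans = [p for p in derivative_plans if p.replaces_haplotype == spec.haplotype_id]
        f_total = sum(p.cell_fraction for p in plans)
        if f_total > 1.0 + 1e-9:
            raise InvalidArgumentError("cell fractions replacing one haplotype exceed 1")
        base_weight = spec.weight * (1.0 - f_total)
        donors.append(
            _Donor(
                donor_id=f"hap{spec.haplotype_id}",
                haplotype=spec.haplotype_id,
                molecules=list(mols.values()),
                weight=base_weight,
                methyl_level=spec.methyl_level,
                methyl_overrides=spec.methyl_overrides,
            )
        )
        for plan in plans:
            der_mol = _build_derivative_molecule(plan, mols, chrom_names, reference)
            affected = {seg[0] for seg in plan.segments}
            other = [m for c, m in mols.items() if c not in affected]
            donors.append(
                _Donor(
                    donor_id=plan.name,
                    haplotype=spec.haplotype_id,
                    molecules=[der_mol] + other,
                    weight=spec.weight * plan.cell_fraction,
                    methyl_level=spec.methyl_level,
                    methyl_overrides=spec.methyl_overrides,
                    is_derivative=True,
                )
            )

    total_ref_len = sum(len(s) for s in reference.values())
    target_bases = config.coverage * total_ref_len

    # flatten (donor, molecule) sampling units
    units = []
    probs = []
    for donor in donors:
        dlen = donor.total_len
        for mol in donor.molecules:
            units.append((donor, mol))
            probs.append(donor.weight * len(mol) / dlen if dlen else 0.0)
    probs_arr = np.array(probs)
    probs_arr = probs_arr / probs_arr.sum()

    comp_lut = np.full(256, ord("N"), dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp_lut[a] = b

    # Linear molecules are sampled as windows of a longer chromosome: the
    # start may fall before the molecule and the read is clipped to it, which
    # makes expected coverage exactly uniform along the molecule.  Reads are
    # emitted until the base budget is met, so coverage is conserved.
    reads: list[ReadAlignment] = []
    truth_rows = []
    emitted_bases = 0
    i = -1
    max_reads = int(10 * target_bases / config.read_length_median) + 100
    while emitted_bases < target_bases and i < max_reads:
        i += 1
        donor, mol = units[int(rng.choice(len(units), p=probs_arr))]
        mlen = len(mol)
        L = max(
            int(rng.lognormal(config.lognormal_mu, config.lognormal_sigma)),
            config.min_read_length,
        )
        if mol.circular:
            L = min(L, mlen)
            start = int(rng.integers(0, mlen))
            idx = (start + np.arange(L)) % mlen
        else:
            start = int(rng.integers(-(L - 1), mlen))
            lo, hi = max(0, start), min(mlen, start + L)
            if hi - lo < max(50, config.min_read_length // 2):
                continue
            start = lo
            L = hi - lo
            idx = np.arange(lo, hi)
        seq = mol.seq[idx]
        rp = mol.ref_pos[idx]
        ci = mol.chrom_idx[idx]
        st = mol.strand[idx]

        # sequencing errors
        if config.deletion_rate > 0:
            keep = rng.random(L) >= config.deletion_rate
            seq, rp, ci, st = seq[keep], rp[keep], ci[keep], st[keep]
        if config.substitution_rate > 0 and len(seq):
            sub = rng.random(len(seq)) < config.substitution_rate
            n_sub = int(sub.sum())
            if n_sub:
                shift = rng.integers(1, 4, size=n_sub)
                cur = np.searchsorted(_BASES, seq[sub])
                cur[cur > 3] = 0  # N -> treat as A
                seq = seq.copy()
                seq[sub] = _BASES[(cur + shift) % 4]
        if config.insertion_rate > 0 and len(seq):
            ins = rng.random(len(seq)) < config.insertion_rate
            counts = 1 + ins.astype(np.int64)
            rep = np.repeat(np.arange(len(seq)), counts)
            firsts = np.cumsum(counts) - counts
            first_mask = np.zeros(len(rep), dtype=bool)
            first_mask[firsts] = True
            new_seq = seq[rep]
            new_seq[~first_mask] = rng.choice(_BASES, size=int((~first_mask).sum()))
            seq = new_seq
            rp = rp[rep].copy()
            rp[~first_mask] = -1
            ci = ci[rep]
            st = st[rep]
        if len(seq) < config.min_read_length // 2:
            continue
        emitted_bases += len(seq)

        reverse = bool(rng.random() < 0.5) if config.both_strands else False
        blocks = _blocks_from_fragment(chrom_names, seq, ci, rp, st, reverse)
        if not blocks:
            continue
        frag_str = seq.tobytes().decode("ascii")
        read_seq = (
            comp_lut[seq[::-1]].tobytes().decode("ascii") if reverse else frag_str
        )

        meth_calls: list[MethCall] = []
        if donor.methyl_level is not None:
            cpg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
            if len(cpg):
                # project unmapped positions onto the last mapped base for the
                # level lookup and the recorded coordinate
                filled = rp.copy()
                bad = filled < 0
                if bad.any():
                    idxs = np.arange(len(filled))
                    idxs[bad] = 0
                    np.maximum.accumulate(idxs, out=idxs)
                    filled = filled[idxs]
                levels = np.full(len(cpg), donor.methyl_level)
                cpos = filled[cpg]
                cchrom = ci[cpg]
                for ov in donor.methyl_overrides:
                    ci_ov = chrom_names.index(ov.chrom)
                    mask = (cchrom == ci_ov) & (cpos >= ov.start) & (cpos < ov.end)
                    levels[mask] = ov.level
                # each CpG on each molecule is either methylated or not
                # (Bernoulli at the haplotype's level); the emitted call is a
                # probability near 0 or 1 with caller noise on top
                states = (rng.random(len(cpg)) < levels).astype(float)
                probs_meth = np.clip(
                    rng.normal(states, config.methyl_call_noise), 0.0, 1.0
                )
                Lr = len(seq)
                for j, p in zip(cpg, probs_meth):
                    # a reverse-sequenced read reports the CpG on the opposite
                    # strand: its cytosine pairs with the plus-strand G at +1
                    read_pos = int(Lr - 2 - j) if reverse else int(j)
                    ref_pos = int(filled[j]) + (1 if reverse else 0)
                    meth_calls.append(
                        MethCall(
                            chrom=chrom_names[int(ci[j])],
                            ref_pos=ref_pos if filled[j] >= 0 else None,
                            read_pos=read_pos,
                            prob=float(p),
                        )
                    )

        read = ReadAlignment(
            read_id=f"r{i:06d}",
            seq=read_seq,
            blocks=blocks,
            haplotype=donor.haplotype,
            meth_calls=meth_calls,
        )
        reads.append(read)
        truth_rows.append(
            {
                "read_id": read.read_id,
                "donor": donor.donor_id,
                "haplotype": donor.haplotype,
                "molecule": mol.name,
                "start": start,
                "length": L,
                "n_blocks": len(blocks),
                "has_junction": len(blocks) > 1,
                "reverse": reverse,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "donor",
            "haplotype",
            "molecule",
            "start",
            "length",
            "n_blocks",
            "has_junction",
            "reverse",
        ],
    )
    return SimulatedSample(reads=reads, truth=truth, reference=reference, config=config)


# Findings-table fixture (defined with the reporting types it returns).
from .panel_report import table2_fixture  # noqa: E402,F401
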