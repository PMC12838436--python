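"""Gene-panel SV triage, local SV-frequency database, and cohort reporting.

The triage mirrors a two-tier clinical workflow: large SVs (affected span
over a size threshold, default 10 kb) are assessed genome-wide; smaller ones
are kept only when they touch a gene-panel region — except that events with
more than two breakpoints are always kept, whatever their size.  A local
frequency database over the cohort's clustered junction calls supports
filtering recurrent (likely artefactual or benign) junctions.  Cohort
aggregation summarizes a findings table into diagnostic-yield figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import InvalidArgumentError
from .sv_reconstruction import (
    DerivativeChromosome,
    Junction,
    _interval_multiplicity,
)

logger = logging.getLogger(__name__)

VARIANT_TYPES = ("SNV/INDEL", "SV", "STR", "OTHER")
CLASSIFICATIONS = ("P", "LP", "VUS_hot", "VUS", "LB", "B")
_CLASS_RANK = {c: i for i, c in enumerate(CLASSIFICATIONS)}


@dataclass
class GenePanel:
    panel_id: str
    regions: dict[str, list[tuple[str, int, int]]]  # gene -> intervals

    def __post_init__(self) -> None:
        for gene, intervals in self.regions.items():
            if not intervals:
                raise InvalidArgumentError(f"panel gene {gene} has no regions")

    @property
    def genes(self) -> set:
        return set(self.regions)

    def intersects(self, chrom: str, start: int, end: int) -> Optional[str]:
        for gene, intervals in self.regions.items():
            for c, s, e in intervals:
                if c == chrom and s < end and e > start:
                    return gene
        return None


def load_panel(bed_path: str, panel_id: str = "panel") -> GenePanel:
    """Panel from a BED file with a gene-symbol fourth column."""
    regions: dict[str, list[tuple[str, int, int]]] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, gene = line.split()[:4]
            regions.setdefault(gene, []).append((chrom, int(start), int(end)))
    return GenePanel(panel_id=panel_id, regions=regions)


@dataclass
class FindingsRecord:
    individual_id: str
    variant_id: str
    variant_type: str
    genes: str
    classification: str
    added_value_note: str = ""
    reported: bool = True

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise InvalidArgumentError(f"unknown variant type {self.variant_type}")
        if self.classification not in CLASSIFICATIONS:
            raise InvalidArgumentError(
                f"unknown classification {self.classification}"
            )
        if not self.reported and self.classification not in ("LB", "B"):
            raise InvalidArgumentError(
                "non-reported records are only permitted for LB/B findings"
            )


# ---------------------------------------------------------------------------
# SV triage
# ---------------------------------------------------------------------------


def affected_span(
    derivative: DerivativeChromosome, chrom_lengths: dict[str, int]
) -> int:
    """Span over which the derivative departs from one reference homolog.

    Sum of |multiplicity - 1|-weighted interval lengths plus the lengths of
    inverted intervals, so balanced inversions are sized too.
    """
    total = 0
    for chrom, rows in _interval_multiplicity(derivative, chrom_lengths).items():
        for lo, hi, mult, rev in rows:
            total += abs(mult - 1) * (hi - lo)
            if rev and mult == 1:
                total += hi - lo
    return total


def filter_svs_by_panel(
    derivatives: Sequence[DerivativeChromosome],
    panel: Optional[GenePanel],
    chrom_lengths: dict[str, int],
    size_threshold: int = 10_000,
) -> tuple[list[DerivativeChromosome], list[tuple[DerivativeChromosome, str]]]:
    """Two-tier triage: keep an SV if its affected span reaches the
    genome-wide threshold, if any breakpoint or segment touches a panel
    region, or if it involves more than two breakpoints.

    Returns (kept, drop_log); each dropped SV carries the rule that dropped
    it.  Idempotent.
    """
    if size_threshold <= 0:
        raise InvalidArgumentError("size_threshold must be positive")
    if panel is not None and not panel.regions:
        panel = None
    kept: list[DerivativeChromosome] = []
    drop_log: list[tuple[DerivativeChromosome, str]] = []
    warned_empty = False
    for der in derivatives:
        span = affected_span(der, chrom_lengths)
        if span >= size_threshold:
            der.annotations["triage"] = "genome_wide_tier"
            kept.append(der)
            continue
        if len(der.junctions_used) > 2:
            der.annotations["triage"] = "breakpoint_count"
            kept.append(der)
            continue
        if panel is None:
            if not warned_empty:
                logger.warning(
                    "no gene panel configured: sub-threshold SVs are dropped"
                )
                warned_empty = True
            drop_log.append((der, "sub_threshold_no_panel"))
            continue
        hit = None
        for j in der.junctions_used:
            for chrom, pos, _ in (j.end_a, j.end_b):
                hit = hit or panel.intersects(chrom, pos, pos + 1)
        # affected intervals only: where the derivative departs from one
        # reference homolog (lost, gained or inverted sequence)
        for chrom, rows in _interval_multiplicity(der, chrom_lengths).items():
            for lo, hi, mult, rev in rows:
                if mult != 1 or rev:
                    hit = hit or panel.intersects(chrom, lo, hi)
        if hit:
            der.annotations["triage"] = f"panel:{hit}"
            kept.append(der)
        else:
            drop_log.append((der, "sub_threshold_outside_panel"))
    return kept, drop_log


# ---------------------------------------------------------------------------
# local SV frequency database
# ---------------------------------------------------------------------------


@dataclass
class SvFrequencyDb:
    entries: list[tuple[Junction, set]]  # (signature junction, sample ids)
    n_samples: int
    pos_tolerance: int = 50

    def _match(self, junction: Junction) -> Optional[tuple[Junction, set]]:
        for sig, samples in self.entries:
            if (
                sig.end_a[0] == junction.end_a[0]
                and sig.end_a[2] == junction.end_a[2]
                and sig.end_b[0] == junction.end_b[0]
                and sig.end_b[2] == junction.end_b[2]
                and abs(sig.end_a[1] - junction.end_a[1]) <= self.pos_tolerance
                and abs(sig.end_b[1] - junction.end_b[1]) <= self.pos_tolerance
            ):
                return sig, samples
        return None

    def frequency(self, junction: Junction) -> float:
        hit = self._match(junction)
        if hit is None:
            return 0.0
        return len(hit[1]) / self.n_samples


def build_sv_db(
    cohort_junction_sets: dict[str, Sequence[Junction]], pos_tolerance: int = 50
) -> SvFrequencyDb:
    """Count distinct samples per junction signature across a cohort.

    Signatures merge junctions within ``pos_tolerance`` at both ends with
    matching orientations — the same merge semantics as junction clustering.
    """
    db = SvFrequencyDb(entries=[], n_samples=len(cohort_junction_sets),
                       pos_tolerance=pos_tolerance)
    for sample_id, junctions in cohort_junction_sets.items():
        for j in junctions:
            hit = db._match(j)
            if hit is None:
                db.entries.append((Junction(j.end_a, j.end_b, list(j.support)), {sample_id}))
            else:
                hit[1].add(sample_id)
    return db


def annotate_frequency(
    junctions: Sequence[Junction], db: SvFrequencyDb
) -> list[tuple[Junction, float]]:
    return [(j, db.frequency(j)) for j in junctions]


def filter_unique(
    junctions: Sequence[Junction],
    db: SvFrequencyDb,
    query_sample: Optional[str] = None,
    max_frequency: float = 0.05,
) -> list[Junction]:
    """Keep junctions rarer than ``max_frequency``, or seen only in the query."""
    out = []
    for j in junctions:
        hit = db._match(j)
        if hit is None:
            out.append(j)
            continue
        samples = hit[1]
        if query_sample is not None and samples == {query_sample}:
            out.append(j)
        elif len(samples) / db.n_samples < max_frequency:
            out.append(j)
    return out


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    cohort_size: int
    n_variants: int
    n_individuals: int
    individuals_by_best_class: dict[str, int]
    diagnostic_yield_pct: float  # P/LP individuals over the cohort
    hot_vus_yield_pct: float
    per_type_variants: dict[str, int]
    per_type_individuals: dict[str, int]
    variants_by_class: dict[str, int]


def aggregate_cohort(
    findings: Sequence[FindingsRecord], cohort_size: int
) -> CohortSummary:
    """Summarize a findings table into diagnostic-yield figures.

    Individuals carrying several findings count once, under their best
    (most pathogenic) classification; deduplication is by (individual,
    variant) key, so the summary is invariant to row order and duplicates.
    """
    seen: dict[tuple[str, str], FindingsRecord] = {}
    for rec in findings:
        seen.setdefault((rec.individual_id, rec.variant_id), rec)
    records = list(seen.values())
    individuals = {r.individual_id for r in records}
    if cohort_size < len(individuals):
        raise InvalidArgumentError(
            "cohort_size is smaller than the number of individuals with findings"
        )
    best: dict[str, str] = {}
    for rec in records:
        cur = best.get(rec.individual_id)
        if cur is None or _CLASS_RANK[rec.classification] < _CLASS_RANK[cur]:
            best[rec.individual_id] = rec.classification
    by_best: dict[str, int] = {}
    for cls in best.values():
        by_best[cls] = by_best.get(cls, 0) + 1
    n_plp = sum(1 for c in best.values() if c in ("P", "LP"))
    n_hot = sum(1 for c in best.values() if c == "VUS_hot")
    per_type_variants: dict[str, int] = {t: 0 for t in VARIANT_TYPES}
    per_type_individuals: dict[str, set] = {t: set() for t in VARIANT_TYPES}
    variants_by_class: dict[str, int] = {}
    for rec in records:
        per_type_variants[rec.variant_type] += 1
        per_type_individuals[rec.variant_type].add(rec.individual_id)
        variants_by_class[rec.classification] = (
            variants_by_class.get(rec.classification, 0) + 1
        )
    return CohortSummary(
        cohort_size=cohort_size,
        n_variants=len(records),
        n_individuals=len(individuals),
        individuals_by_best_class=by_best,
        diagnostic_yield_pct=100.0 * n_plp / cohort_size,
        hot_vus_yield_pct=100.0 * n_hot / cohort_size,
        per_type_variants=per_type_variants,
        per_type_individuals={t: len(s) for t, s in per_type_individuals.items()},
        variants_by_class=variants_by_class,
    )


def findings_to_frame(findings: Sequence[FindingsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": r.individual_id,
            "variant_id": r.variant_id,
            "variant_type": r.variant_type,
            "genes": r.genes,
            "classification": r.classification,
            "added_value_note": r.added_value_note,
            "reported": r.reported,
        }
        for r in findings
    )


def load_findings(path: str) -> list[FindingsRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        FindingsRecord(
            individual_id=str(row.individual_id),
            variant_id=str(row.variant_id),
            variant_type=row.variant_type,
            genes=str(row.genes),
            classification=row.classification,
            added_value_note=str(getattr(row, "added_value_note", "")),
            reported=bool(getattr(row, "reported", True)),
        )
        for row in df.itertuples()
    ]


def render_report(
    summary: CohortSummary, findings: Sequence[FindingsRecord]
) -> str:
    """Deterministic human-readable report.

    Non-reported (NR) records are excluded from the clinical section but
    retained, de-identified only by their synthetic ids, in the audit section.
    """
    lines = []
    lines.append("# Cohort findings report")
    lines.append(f"cohort size\t{summary.cohort_size}")
    lines.append(f"distinct variants\t{summary.n_variants}")
    lines.append(f"individuals with findings\t{summary.n_individuals}")
    lines.append(
        f"diagnostic yield (P/LP)\t{summary.diagnostic_yield_pct:.1f}%"
    )
    lines.append(f"hot-VUS yield\t{summary.hot_vus_yield_pct:.1f}%")
    lines.append("")
    lines.append("## Individuals by best classification")
    for cls in CLASSIFICATIONS:
        if cls in summary.individuals_by_best_class:
            lines.append(f"{cls}\t{summary.individuals_by_best_class[cls]}")
    lines.append("")
    lines.append("## Variants and individuals per type")
    for vtype in VARIANT_TYPES:
        lines.append(
            f"{vtype}\t{summary.per_type_variants[vtype]} variants\t"
            f"{summary.per_type_individuals[vtype]} individuals"
        )
    lines.append("")
    header = "individual\tvariant\ttype\tgenes\tclassification\tnote"
    lines.append("## Clinical findings (reported)")
    lines.append(header)
    ordered = sorted(
        findings, key=lambda r: (r.individual_id, r.variant_id)
    )
    for r in ordered:
        if r.reported:
            lines.append(
                f"{r.individual_id}\t{r.variant_id}\t{r.variant_type}\t"
                f"{r.genes}\t{r.classification}\t{r.added_value_note}"
            )
    lines.append("")
    lines.append("## Audit section (all records incl. non-reported)")
    lines.append(header + "\treported")
    for r in ordered:
        lines.append(
            f"{r.individual_id}\t{r.variant_id}\t{r.variant_type}\t"
            f"{r.genes}\t{r.classification}\t{r.added_value_note}\t{r.reported}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reference findings-table fixture for cohort-level tests
# ---------------------------------------------------------------------------


def table2_fixture() -> list[FindingsRecord]:
    """A reference added-value findings table as FindingsRecords.

    17 variants across 13 individuals, grouped by variant type.  Rows whose
    identifying information was removed in the source (non-reported, NR)
    carry distinct synthetic individual identifiers (NA_1..NA_4).
    """
    R = FindingsRecord
    return [
        # --- SNV/INDEL ---
        R("RD_P694", "SGCA_c.557A>T", "SNV/INDEL", "SGCA", "LP",
          "SNV and INDEL 585 bp apart phased in trans"),
        R("RD_P694", "SGCA_c.348_352dup", "SNV/INDEL", "SGCA", "LP",
          "SNV and INDEL 585 bp apart phased in trans"),
        R("RD_P712", "COL12A1_c.8861G>A", "SNV/INDEL", "COL12A1", "VUS_hot",
          "two SNVs 105 kb apart phased in trans"),
        R("RD_P712", "COL12A1_c.165C>G", "SNV/INDEL", "COL12A1", "VUS_hot",
          "two SNVs 105 kb apart phased in trans"),
        # --- SV ---
        R("RD_P623", "SMN1_homozygous_del", "SV", "SMN1", "P",
          "paralog phasing: no SMN1 copy, four SMN2 copies"),
        R("RD_P695", "FGF14_inv13", "SV", "FGF14", "P",
          "breakpoint mapping; 7.6 kb deletion at one breakpoint"),
        R("RD_P695", "inv10_pericentric", "SV", "none", "LB",
          "detection of a pericentric inversion of chromosome 10"),
        R("RD_P633", "der14_t8_14", "SV", "multiple", "P",
          "telomeric sequence at one breakpoint; acrocentric p-arm link"),
        R("RD_P651", "complex_9p_del_inv_dup", "SV", "multiple", "P",
          "resolved complex rearrangement structure"),
        R("RD_P655", "ring18_mosaic", "SV", "multiple", "P",
          "resolved complex rearrangement structure"),
        R("NA_1", "complex_sv_9p", "SV", "none", "LB",
          "breakpoints mapped, no disease gene disrupted", reported=False),
        R("NA_1", "complex_sv_10p", "SV", "none", "LB",
          "breakpoints mapped, no disease gene disrupted", reported=False),
        R("NA_2", "complex_sv_1p", "SV", "none", "LB",
          "breakpoints mapped, no disease gene disrupted", reported=False),
        # --- STR ---
        R("RD_P698", "FMR1_full_654", "STR", "FMR1", "P",
          "size, loss of interrupting motifs, hypermethylation"),
        R("NA_3", "FMR1_premutation_60", "STR", "FMR1", "LB",
          "sizing and interruption motifs", reported=False),
        R("NA_4", "ATXN1_37", "STR", "ATXN1", "LB",
          "sizing and interruption motifs", reported=False),
        # --- other ---
        R("RD_P706", "UPD15_maternal_isodisomy", "OTHER", "multiple", "P",
          "methylation analysis confirms the imprinting diagnosis"),
    ]
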