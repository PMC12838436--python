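"""Read-backed haplotype assignment, cis/trans phasing, and paralog copy number.

Haplotype assignment is a greedy two-partition over heterozygous sites: the
read observing the most sites seeds haplotype 1, whose per-site consensus is
the majority allele of reads assigned so far (haplotype 2's consensus is its
complement, since every site is heterozygous).  Each further read joins the
side its alleles agree with; exact ties and reads sharing fewer than
``min_informative`` sites stay unassigned.

Variant pairs are phased by direct spanning reads when any read covers both
positions (cis when it carries both alts or neither, trans otherwise); when
none does, votes are routed through haplotype tags.  Direct evidence outranks
tag-routed evidence; when both exist and disagree the pair is reported
unknown with a conflict flag — the conservative clinical posture.

Paralog copy number (the SMN1/SMN2 problem) clusters reads over the shared
region by their alleles at discriminating sites; clusters are labelled by the
allele at the gene-defining site and corroborated against relative depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    ConfigurationError,
    InvalidArgumentError,
    ReadAlignment,
    SmallVariant,
    mean_depth,
    variant_support,
)


@dataclass
class PhaseResult:
    variant_a: SmallVariant
    variant_b: SmallVariant
    phase: str  # cis / trans / unknown
    n_reads_both: int
    n_cis_support: int
    n_trans_support: int
    conflict_fraction: float
    evidence: str = ""  # direct / tag_routed / none
    reason: str = ""


def assign_haplotypes(
    reads: Sequence[ReadAlignment],
    het_variants: Sequence[SmallVariant],
    min_informative: int = 1,
) -> dict[str, Optional[int]]:
    """Two-partition reads by agreement over heterozygous sites.

    Returns read_id -> 1, 2 or None.  If no read covers any site, all reads
    are unassigned (not an error).  Haplotype labels are arbitrary (defined up
    to the 1<->2 swap).
    """
    if not het_variants:
        raise InvalidArgumentError("need at least one heterozygous site")
    observations = {}
    for read in reads:
        obs = {}
        for i, v in enumerate(het_variants):
            support = variant_support(read, v)
            if support is not None:
                obs[i] = 1 if support else 0
        observations[read.read_id] = obs

    order = sorted(
        observations, key=lambda rid: len(observations[rid]), reverse=True
    )
    assignments: dict[str, Optional[int]] = {rid: None for rid in observations}
    # votes[i] > 0 means haplotype 1 consensus carries the alt at site i
    votes: dict[int, int] = {}
    for rid in order:
        obs = observations[rid]
        if len(obs) < min_informative:
            continue
        if not votes:
            assignments[rid] = 1
            for site, allele in obs.items():
                votes[site] = votes.get(site, 0) + (1 if allele else -1)
            continue
        shared = [site for site in obs if votes.get(site)]
        if len(shared) < min_informative:
            continue
        score = sum(
            1 if (votes[site] > 0) == bool(obs[site]) else -1 for site in shared
        )
        if score > 0:
            hap = 1
        elif score < 0:
            hap = 2
        else:
            continue  # exact tie stays unassigned
        assignments[rid] = hap
        sign = 1 if hap == 1 else -1
        for site, allele in obs.items():
            votes[site] = votes.get(site, 0) + sign * (1 if allele else -1)
    return assignments


def phase_pair(
    reads: Sequence[ReadAlignment],
    variant_a: SmallVariant,
    variant_b: SmallVariant,
    haplotype_tags: Optional[dict[str, Optional[int]]] = None,
    min_support: int = 3,
    max_conflict: float = 0.1,
) -> PhaseResult:
    """Resolve whether two heterozygous variants lie in cis or in trans."""
    n_both = n_cis = n_trans = 0
    for read in reads:
        sa = variant_support(read, variant_a)
        sb = variant_support(read, variant_b)
        if sa is None or sb is None:
            continue
        n_both += 1
        if sa == sb:
            n_cis += 1
        else:
            n_trans += 1

    def decide(cis: int, trans: int) -> tuple[str, float, str]:
        total = cis + trans
        if total == 0:
            return "unknown", 0.0, "no coverage"
        win, lose = max(cis, trans), min(cis, trans)
        conflict = lose / total
        if win < min_support:
            return "unknown", conflict, "insufficient support"
        if conflict > max_conflict:
            return "unknown", conflict, "conflicting evidence"
        return ("cis" if cis > trans else "trans"), conflict, ""

    direct_phase, direct_conflict, direct_reason = decide(n_cis, n_trans)

    routed_phase, routed_cis, routed_trans, routed_conflict = "unknown", 0, 0, 0.0
    if haplotype_tags:
        hap_a = _alt_haplotype(reads, variant_a, haplotype_tags)
        hap_b = _alt_haplotype(reads, variant_b, haplotype_tags)
        if hap_a and hap_b and hap_a[1] >= min_support and hap_b[1] >= min_support:
            routed_conflict = max(hap_a[2], hap_b[2])
            if routed_conflict <= max_conflict:
                routed_phase = "cis" if hap_a[0] == hap_b[0] else "trans"
                routed_cis = min(hap_a[1], hap_b[1]) if routed_phase == "cis" else 0
                routed_trans = min(hap_a[1], hap_b[1]) if routed_phase == "trans" else 0

    if direct_phase != "unknown" and routed_phase != "unknown":
        if direct_phase != routed_phase:
            return PhaseResult(
                variant_a, variant_b, "unknown", n_both, n_cis, n_trans,
                max(direct_conflict, routed_conflict),
                evidence="direct+tag_routed", reason="direct and routed evidence disagree",
            )
        return PhaseResult(
            variant_a, variant_b, direct_phase, n_both, n_cis, n_trans,
            direct_conflict, evidence="direct",
        )
    if direct_phase != "unknown":
        return PhaseResult(
            variant_a, variant_b, direct_phase, n_both, n_cis, n_trans,
            direct_conflict, evidence="direct",
        )
    if routed_phase != "unknown":
        return PhaseResult(
            variant_a, variant_b, routed_phase, n_both, routed_cis, routed_trans,
            routed_conflict, evidence="tag_routed",
        )
    return PhaseResult(
        variant_a, variant_b, "unknown", n_both, n_cis, n_trans,
        direct_conflict, evidence="none", reason=direct_reason,
    )


def _alt_haplotype(
    reads: Sequence[ReadAlignment],
    variant: SmallVariant,
    tags: dict[str, Optional[int]],
) -> Optional[tuple[int, int, float]]:
    """Majority haplotype carrying the alt allele: (hap, support, conflict)."""
    counts = {1: 0, 2: 0}
    for read in reads:
        hap = tags.get(read.read_id)
        if hap not in (1, 2):
            continue
        support = variant_support(read, variant)
        if support is True:
            counts[hap] += 1
        elif support is False:
            counts[3 - hap] += 1  # ref carrier votes for the other haplotype
    total = counts[1] + counts[2]
    if total == 0:
        return None
    hap = 1 if counts[1] >= counts[2] else 2
    return hap, counts[hap], counts[3 - hap] / total


# ---------------------------------------------------------------------------
# paralog copy number
# ---------------------------------------------------------------------------


@dataclass
class ParalogFamily:
    """Shared-region definition for a paralog family.

    ``sites`` are 0-based positions of discriminating sites (including
    copy-private markers); ``gene_site`` is the position whose allele defines
    gene identity, with ``gene_alleles`` mapping base -> gene symbol.
    ``haploid_depth`` (optional) enables the depth corroboration of the
    cluster count.
    """

    family_id: str
    chrom: str
    start: int
    end: int
    sites: list[int]
    gene_site: int
    gene_alleles: dict[str, str]
    haploid_depth: Optional[float] = None

    @classmethod
    def from_json(cls, path: str) -> "ParalogFamily":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class ParalogProfile:
    family_id: str
    total_copies: int
    per_gene_copies: dict[str, int]
    discriminating_sites: list[int]
    haplotype_clusters: dict[tuple, int] = field(default_factory=dict)
    depth_copies: Optional[float] = None
    no_call: bool = False


def paralog_copy_number(
    reads: Sequence[ReadAlignment],
    family: ParalogFamily,
    min_cluster_reads: int = 3,
) -> ParalogProfile:
    """Resolve per-gene copy number of a paralog family from read clusters.

    Reads covering every discriminating site are clustered by their allele
    tuple; each cluster is one haplotype copy, labelled by the allele at the
    gene-defining site.  When a haploid depth is supplied, the depth-implied
    copy number is reported alongside and, if it exceeds the cluster count,
    extra copies are attributed to clusters proportionally to their read
    support (ties round toward the depth estimate).
    """
    clusters: dict[tuple, int] = {}
    for read in reads:
        alleles = tuple(read.base_at(family.chrom, pos) for pos in family.sites)
        if any(a is None for a in alleles):
            continue
        clusters[alleles] = clusters.get(alleles, 0) + 1
    clusters = {k: v for k, v in clusters.items() if v >= min_cluster_reads}
    if not clusters:
        covering = [r for r in reads if r.overlaps(family.chrom, family.start, family.end)]
        if not covering:
            return ParalogProfile(
                family.family_id, 0, {g: 0 for g in set(family.gene_alleles.values())},
                family.sites, no_call=True,
            )
    gene_site_idx = family.sites.index(family.gene_site)
    per_gene = {gene: 0 for gene in set(family.gene_alleles.values())}
    for alleles in clusters:
        gene = family.gene_alleles.get(alleles[gene_site_idx])
        if gene is None:
            raise ConfigurationError(
                f"allele {alleles[gene_site_idx]} at the gene-defining site is not "
                "listed in gene_alleles"
            )
        per_gene[gene] += 1

    depth_copies = None
    if family.haploid_depth:
        depth = mean_depth(reads, family.chrom, family.start, family.end)
        depth_copies = depth / family.haploid_depth
        extra = int(round(depth_copies)) - len(clusters)
        if extra > 0 and clusters:
            # attribute unresolved extra copies to the best-supported clusters
            ranked = sorted(clusters.items(), key=lambda kv: -kv[1])
            for i in range(extra):
                alleles = ranked[i % len(ranked)][0]
                gene = family.gene_alleles[alleles[gene_site_idx]]
                per_gene[gene] += 1

    return ParalogProfile(
        family_id=family.family_id,
        total_copies=sum(per_gene.values()),
        per_gene_copies=per_gene,
        discriminating_sites=family.sites,
        haplotype_clusters=clusters,
        depth_copies=depth_copies,
    )
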