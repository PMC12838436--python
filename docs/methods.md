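# Methods

This note documents the models behind each analysis, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Synthetic aligned reads

The generator is the package's validation substrate: every downstream
analysis is tested as a recovery problem against reads with planted ground
truth.

**Genome model.** References are i.i.d. random sequence at a configurable GC
fraction (default 0.41, human-like). A sample is a set of haplotypes, each a
copy of the reference with planted SNVs/indels, an optional STR allele
(repeat count plus interruption motifs at given unit indices), and per-region
CpG methylation levels; haplotype weights are cell fractions summing to 1.
A derivative chromosome is an ordered, oriented segment list (optionally
circular) that replaces one haplotype's chromosome in a configurable fraction
of cells, so a junction is expected in `weight x cell_fraction` of reads over
the breakpoint — `cell_fraction / 2` for the canonical two-haplotype sample.

**Read lengths** follow a log-normal law fitted to a (median, N50) pair:
`mu = ln(median)` and, since the N50 of a log-normal is the median of its
length-biased version `exp(mu + sigma^2)`, `sigma = sqrt(ln(N50/median))`.
The defaults (median 5 kb, N50 16 kb, 34X coverage) emulate nanopore
sequencing of routine clinical DNA extractions. Linear molecules are sampled
as windows of a notionally longer chromosome (starts may fall before the
molecule and reads are clipped to it), which makes expected coverage exactly
uniform along the molecule — a miniature reference has no room for the edge
ramps that would otherwise distort copy-number estimates; reads are emitted
until the base budget is met, so total coverage is conserved. Circular
molecules (rings) are sampled with wrap-around, which is what produces the
ring junction reads.

**Alignments are computed analytically, not by running an aligner.** Each
read carries a per-base map back to the reference; sequencing errors
(substitution / insertion / deletion rates, all default 0 and configurable —
the platform's error rate is not a fixed constant) are applied directly to
that map, and the CIGAR follows from it. A reference-space discontinuity of
100 bp or more, a strand flip, or a chromosome change splits the read into a
supplementary-alignment chain with consistent soft clips, mirroring what a
long-read aligner emits at rearrangement breakpoints. SAM round-tripping
(including SA tags and MM/ML modified-base tags, written relative to the
original read orientation) goes through pysam and is covered by tests.

**Methylation.** Each CpG on each simulated molecule is methylated with the
haplotype's regional probability (Bernoulli), and the emitted call is that
binary state plus Gaussian caller noise (sd `methyl_call_noise`, default
0.05), clipped to [0, 1]. This reproduces the bimodal per-call probability
distribution real callers produce, so the thresholded region fraction
estimates the underlying methylation level. For reverse-sequenced reads the
recorded reference coordinate is the opposite-strand cytosine (one base
offset), matching how the tags decode.

**What is not emulated:** raw signal and basecalling, sequence-context error
biases, mapping ambiguity in repetitive or paralogous sequence, chimeric
artifacts, and reference errors. Passing recovery tests therefore shows the
*interpretive* layer is correct given reasonable alignments; it does not
certify performance on real nanopore data in hard genomic regions.

## STR profiling

Anchor-based greedy tiling, chosen over an HMM because it is deterministic
and verifiable against an exhaustive oracle, which is the right trade-off at
desk scale. The flank anchors (default 30 bp) are located exactly or by
edit-distance search (edlib, budget one error per 8 bp of anchor), which
keeps reads usable at several percent indel noise. The tract between anchors
is tiled by the canonical motif with a per-unit mismatch budget of 0 by
default: any non-canonical unit-length window is an interruption and counts
toward the total; a trailing partial unit is floored. Under indel noise the
unit count tracks tract length (`len/k`), which is why the pooled median
stays within a few units of the planted size while individual interruption
lists become noisy — on clean reads they are exact.

Haplotype resolution uses read tags when present; otherwise counts are split
by the best 1-D two-cluster partition (minimum within-cluster sum of
squares), accepted only when the cluster medians differ by more than
max(2 units, 10%) — the guard against splitting a noisy single allele. A
locus with fewer than `min_spanning_reads` (default 3) spanning calls is a
no-call, not an error. Classification thresholds are inclusive upper bounds
in repeat units; the shipped defaults are FMR1 (44 / 54 / 200, motif CGG) and
ATXN1 (35 / 44 / 44, motif CAG) and the catalog (BED + JSON sidecar) is fully
configurable.

## Imprinting methylation z-scores

Calls with probability ≥ `prob_threshold` (default 0.8) count methylated,
≤ 1−threshold unmethylated, the symmetric middle band is discarded. The
control pool uses the sample (n−1) standard deviation — pools are small — and
requires at least 5 control samples per region (configuration error
otherwise); zero control variance yields a no-call with a reason. Aberration
thresholds default to ±3, below the smallest aberrant magnitude one would
want to flag. Because published pipelines differ in whether they score the
methylated or the unmethylated fraction (the sign of z flips between the
two), the convention is an explicit parameter echoed in every result; the
default scores the methylated fraction, so hypermethylation gives positive z.
Promoter status for STR loci uses fixed bands: fraction ≥ 0.7 hypermethylated,
≤ 0.3 unmethylated, else intermediate.

## Phasing and paralog copy number

Haplotype assignment is a greedy two-partition: the read observing the most
heterozygous sites seeds haplotype 1; since every site is heterozygous,
haplotype 2's consensus is the complement, and each subsequent read joins the
side its alleles agree with (majority over shared sites, processed in order
of decreasing informativeness, consensus updated incrementally). Exact ties
and reads with fewer than `min_informative` (default 1) shared sites remain
unassigned. Labels are defined only up to the 1↔2 swap.

Pair phasing: reads covering both variants vote directly (cis if both alts
or neither); otherwise votes route through haplotype tags by majority. A
phase is declared when the winning side has ≥ `min_support` (default 3,
matched to the ~34X regime) and the conflict fraction is ≤ `max_conflict`
(default 0.1). Direct evidence outranks tag-routed evidence; if both exist
and disagree the result is unknown with a conflict flag — the conservative
clinical posture. Insertions and deletions are matched through their
VCF-normalized alleles via the CIGAR; a read carrying a *different* insertion
at the site is treated as uninformative rather than as a reference carrier.

Paralog copy number clusters reads that cover all discriminating sites by
their allele tuple (clusters below 3 reads are discarded as error artifacts);
each cluster is one haplotype copy, labelled by its allele at the
gene-defining site. When a haploid depth is supplied the depth-implied copy
number is reported alongside, and any excess over the cluster count is
attributed to the best-supported clusters. The simplification relative to
full paralog haplotype assembly is that reads must individually span the
discriminating sites — appropriate at the fixture scale used here, where the
shared region is a few kb.

## Derivative-chromosome reconstruction

A junction end stores the *retained* flank ('+' keeps coordinates below the
breakpoint, '−' at or above), which avoids the ambiguity of raw breakend
notation; an export to standard VCF BND records is provided. Raw junctions
come one per adjacent pair in each read's supplementary chain; clustering
merges within `pos_tolerance` (default 50 bp) at both ends with matching
orientations, takes per-end medians, and drops (but counts) clusters below
`min_support` (default 3).

Copy number is binned depth (default 1 kb bins) normalized to the diploid
baseline and scaled to copies. The baseline is the *modal* bin depth
(half-sample mode) rather than the median: on a miniature genome an SV can
occupy a large fraction of all bins and bias the median. Two segmentations
are provided: a generic median-filtered greedy merge, and — preferred when
junctions are available — junction-delimited intervals with internal
changepoints found by recursive binary segmentation (accepted when the step
is ≥ 0.5 copies with ≥ 15 bins per side). The latter is markedly more robust
to the strong autocorrelation of long-read depth, and is what
`reconstruct_from_reads` uses.

The derivative is built by a greedy walk: proceed along the reference from an
anchor, jump at the first junction end whose retained flank faces the
traversed side (ties break by higher support, then lexicographic partner),
flip direction as the orientation encodes, and repeat. Traversal consumes a
per-interval copy budget of `round(CN − 1 + 0.33)` (one copy belongs to the
intact homolog; the +0.33 bias is deliberate — the budget exists to block
truly deleted regions and exhausted broken ends, and should not punish
slight depth under-measurement of duplicated segments). The walk stops at
telomeres, at budget exhaustion (a broken end), or when it re-enters its
start (circular = ring); exceeding `max_segments` (default 50) returns a
complex-unresolved result rather than raising — recurrent events flanked by
segmental duplications are deliberately out of reach. Because the right
anchor depends on which end of the derivative survives,
`resolve_derivative` tries the ends of terminally deleted CN segments and
both telomeres of every junction-bearing chromosome and keeps the walk that
uses the most junctions (then circularity, then reconstructed length).

Motif classification works on the interval multiplicity/orientation profile
of the reconstructed word: circular → RING; no junctions → REFERENCE; two
chromosomes, one junction → unbalanced translocation; a doubly-covered
interval with one inverted copy next to a zero-covered terminal interval →
DEL-INV-DUP; triply-covered inverted middle → DUP-TRP/INV-DUP; single
inverted interval → INV (with any adjacent zero-covered interval annotated
as a breakpoint deletion); and so on, falling back to COMPLEX.

One identifiability caveat: for the terminal DEL-INV-DUP geometry, the single
inverted junction plus the copy-number profile admit two derivative words
(spacer forward or inverted between the mirrored duplicated segments) that no
read-level evidence in this model distinguishes; the walk returns one of them
deterministically, and the broken-end coordinate is resolved only to
copy-number (bin) resolution, unlike junction breakpoints which are
base-precise.

Mosaic fraction: for a junction with s supporting reads among n spanning
(junction carriers plus reads aligning straight through either breakpoint
with ≥ 50 bp anchors), the cell fraction under the one-of-two-homologs model
is min(1, 2s/n), reported both raw and truncated (not rounded) to an integer
percent — 6 of 28 gives 42%, the truncation convention matching how such
fractions are conventionally quoted.

## Panel triage and cohort reporting

The two-tier rule keeps an SV genome-wide when its *affected span* — the sum
of |multiplicity − 1|-weighted interval lengths plus inverted interval
lengths, so balanced inversions are sized too — reaches 10 kb; smaller events
survive only if a breakpoint or an affected interval touches a panel region,
except that events with more than two breakpoints are always kept. Every
dropped SV appears in the drop log with the rule that dropped it, and the
filter is idempotent. The local SV-frequency database counts distinct samples
per junction signature, with the same ±50 bp merge semantics as junction
clustering (one knob for both). Cohort aggregation deduplicates by
(individual, variant), counts each individual once under their most
pathogenic classification, and reports per-type tallies both as variants and
as individuals, since the two views differ whenever an individual carries
several findings. Non-reported (LB/B only) records are excluded from the
clinical report section but retained in the audit section.

## Problem sizes used in the test suite

Recovery suites run on miniature references (12–400 kb, 1–2 chromosomes) at
30X: large enough for every statistical property exercised, small enough that
the full suite completes in well under a minute per module. The SV round-trip
fixtures use a narrower read-length distribution (median 2 kb, N50 3.5 kb)
than the package default: at a few-hundred-kb toy scale the heavy 16 kb-N50
tail makes binned depth non-ergodic (a handful of long reads dominates local
depth), which is a property of the miniature genome, not of the method —
shorter reads restore the many-independent-observations regime that a real
genome provides while still spanning every junction. The clinically observed
DEL-INV-DUP geometry (1.8 Mb deletion / 850 bp spacer / 17.8 Mb duplication)
is planted at ~1:200 scale with the spacer kept at 850 bp.

## Known limitations

- No modeling of alignment ambiguity: paralog and repeat analyses assume
  reads are placed correctly, so mapping-driven failure modes of real data
  are out of scope.
- The STR tiler reports interruptions frame-locked to the canonical motif;
  a single indel inside the tract shifts the frame for the rest of the read.
- Derivative reconstruction assumes at most one derivative per chromosome
  pair and integer copy numbers; nested or chromothriptic events return
  COMPLEX rather than a resolved word.
- The imprinting caller compares region-level fractions; it does not model
  parent-of-origin explicitly (haplotype-filtered fractions are provided for
  that purpose).
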