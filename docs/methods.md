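# Methods

This note documents the models, thresholds and numerical choices behind
`gutevol`, and what its synthetic data do and do not establish.

## The measurement problem

A pooled population sample (>1000 clones from one animal) is sequenced to a
few hundred fold coverage. Mutations present in a fraction *f* of the pool
appear as alternate alleles at frequency ≈ *f* in the pileup. The analysis
must (i) call such polymorphisms down to *f* = 0.05 while rejecting
sequencing error and mapping artifacts, (ii) detect insertions of known IS
elements that are absent from the reference, and (iii) quantify prophage
acquisition from a co-resident strain. Cohort-level questions are then
answered from per-mouse category counts.

## Read QC and partitioning

Trimming follows the pooled-sequencing protocol exactly: 4 bp windows slide
inward (step 1 bp) from the 5′ end and then the 3′ end while the window mean
quality is below Q20; survivors are kept only at ≥ 100 bp with ≥ 50% of
bases at Q20+. Two choices the protocol leaves open are fixed here and
flagged as this package's policy: trimming order is 5′ before 3′ (order
matters at window boundaries; a fixed order makes the operation
deterministic and idempotent), and a pair is discarded whenever either mate
fails. Adapter removal is out of scope — synthetic reads carry no adapters,
so the adapter step of the original protocol is satisfied vacuously.

Partitioning among invader / resident / plasmid references replaces an
external binning tool with exact shared-k-mer counting (k = 21, both mates
summed). A pair is assigned to the strictly highest-scoring reference if
that score is ≥ 10 k-mers; ties (regions identical between strains) and
sub-threshold pairs go to `unassigned`. Assigning ties to one bin — or to
both — would double-count reads downstream; setting them aside loses a
little depth in conserved regions but never miscounts.

## Alignment

The built-in aligner exists so the pipeline is testable end to end without
external mappers; externally produced SAM is ingested losslessly via pysam
and treated identically ("alignment run" is an opaque label downstream).
Design: exact 21-mer seeds on both strands; the best-voted diagonal is
evaluated ungapped; if that fails, a banded one-indel rescue enumerates
indel sizes 1–20 on either side of the seeded segment and picks the
placement minimizing mismatches, requiring each segment to be ≥ 10 bp and
to satisfy the mismatch budget (10%) *on its own* — a junction read's
foreign half cannot hide behind its matching half. Ties between equivalent
indel placements break toward splits with no mismatch adjacent to the gap,
then leftmost. Reads failing both are soft-clipped around the seeded core;
mismatch-dense read ends (X-drop score +1 match / −2 mismatch, cut at
minimum ≤ −4) are clipped rather than reported as substitutions, because
short junction overhangs otherwise masquerade as clustered SNPs. Mapping
quality is two-valued: 60 for a unique best diagonal, 0 when an unrelated
diagonal (different strand or > 20 bp away) ties — only the MQ ≥ 20
threshold matters downstream. Reads wholly inside a novel element find no
seeds and are emitted unmapped; their mates anchor the discordant-pair
evidence.

## Pileups

Pileups are MQ-filtered at build time (MQ < 20 reads excluded entirely);
base observations below Q30 are kept but flagged low-quality, so callers
can apply "quality read" counts. Insertions attach to the base before the
inserted sequence and deletions are keyed by their first deleted base
(matching the single-position presentation of indels in mutation tables);
both are normalized to their leftmost equivalent placement when counted, so
evidence for one event in a homopolymer lands in a single token. Two
further rules remove alignment-geometry bias:

* **End censoring.** The outermost 9 aligned bases of every read are never
  "quality" observations. An indel within 10 bp of a read end cannot be
  rescued as a gap, so its shifted tail shows up as terminal mismatches;
  censoring `indel_margin − 1` bases removes that artifact class uniformly,
  costing ~7% of quality depth at 250 bp.
* **Spanning counts.** Only reads extending ≥ 10 bp past a position inside
  one contiguous aligned block count as *spanning* it. Indel frequencies
  are computed as supporting/(supporting + spanning): a read must extend
  well past an indel on both sides to report it, so dividing by the full
  per-base depth (which includes uninformative reads) biases indel
  frequencies low by ~8–15%.

SNP frequencies use the plain quality-depth denominator.

## Variant calling and consensus

The filtered-pileup caller emits an alternate allele iff it has ≥ 3% of
quality reads, ≥ 5 quality reads on **each** strand, and a positive/negative
strand ratio strictly inside (0.2, 5.0). "On both strands" is read as a
per-strand minimum — the strictest interpretation consistent with the bias
window existing — and the ratio uses raw counts (the per-strand minimum
guarantees a nonzero denominator). The polymorphism-mode caller requires
depth ≥ 5, frequency ≥ 0.05, and a two-sided Fisher exact test of the 2×2
allele-by-strand table with p ≥ 0.05; no specific test being prescribed for
"absence of significant strand bias", the exact test at α = 0.05 is this
package's choice. It follows that the polymorphism-mode caller has an
intrinsic ~5% false-negative rate on true variants (the null is rejected at
rate α), which the 2-of-3 consensus tolerates: such a variant is still
reported, at 2/3 of its frequency under the divide-by-3 averaging below.

Calls inside repeat intervals or within ±10 bp of structural junctions are
masked before merging; junctions are taken from accepted IS calls plus any
position where ≥ 3 soft-clipped reads cluster (which also captures
inversion edges). False-positive SNPs cluster exactly there.

Consensus: calls are matched across runs on (position, type, allele) after
left-alignment, and a variant survives iff seen in ≥ 2 runs with mean
frequency ≥ 5%. The mean divides by the total number of runs with absent
runs contributing 0 — the stricter of the two readings of "average
frequency between the alignments"; `merge_runs(..., mean_over="detected")`
switches to dividing by the number of detecting runs. The pipeline's three
runs are the built-in aligner at seed lengths 17/21/25, the first two
feeding the filtered-pileup caller and the third the polymorphism-mode
caller. Consensus frequencies are reported rounded to 2 decimals, the
precision of the printed tables.

## IS insertions

Three in-house evidence channels replace the external IS detectors while
preserving the ≥ 2-of-3 voting contract: split reads (clipped tails ≥ 20 bp
matched by exact 20-mers against the IS library, clip positions clustered
within 10 bp), discordant pairs (unique anchors whose mates are unmapped
but match an element; innermost anchor edges bracket the junction), and
junction assembly (clipped reads merged into a contig by exact ≥ 30 bp
overlap; confirmation requires ≥ 20 bp of reference flank abutting ≥ 20 bp
of element in the contig, and fewer than 2 usable reads is "insufficient",
not a vote). An element inserted after base *p* produces right-clipped
reads ending at *p* **and** left-clipped reads starting at *p* + 1, so both
junctions cluster at the same reference base.

**Frequency estimator** (the source tables print IS frequencies without
stating one): junction reads are counted per side with matched geometry —
≥ 20 bp aligned and ≥ 20 bp clipped — and spanning reads with ≥ 20 bp on
both sides of the site. Because each carrier fragment can evidence either
of two junctions that map to the same base, the junction count is halved:
f̂ = ((left + right)/2) / ((left + right)/2 + spanning). The naive
junction/(junction + spanning) ratio double-counts carriers and would
report ≈ 0.79 for a true 0.65. Target-site duplications are not modeled;
the site is reported as the left junction base, which is genuinely
ambiguous by a few bp when the element's end happens to match the reference
continuation.

## Prophage gain

Acquisition frequency is mean read depth inside the prophage interval over
mean depth in its ± 5 kb single-copy flanks, clamped to [0, 1], on a
reference that contains the prophage (either the donor genome or the
invader backbone with the prophage integrated at its locus). Zero flanking
coverage yields a missing estimate rather than a number. With N reads over
the interval the estimator's relative error is ≈ 1/√N, so at 250× over a
2.5 kb prophage the standard error is ≈ 2%.

## Cohort statistics

Rows are classified into overlapping categories: IS (any IS insertion),
intergenic (any record in an intergenic context, including IS and indels
there), synonymous (synonymous SNP in a gene), coding (any in-gene record
that is not synonymous: missense/nonsense SNPs, frameshifts, in-frame codon
changes, partial gene deletions, gene-interrupting IS), indel (any base
insertion/deletion, excluding IS and inversions), structural (inversions),
prophage (exclusive; excluded from total counts). This overlap structure is
the unique rule set under which all six published cohort means reproduce
simultaneously from the packaged tables, and it is pinned by regression
tests. Whether the one 296 bp inversion belongs to further categories
cannot be disambiguated from the means alone; the chosen rules are one
consistent solution.

Mean ± SEM uses the n−1 sample standard deviation over √n. The
Mann–Whitney U uses midranks for ties, reports min(U₁, U₂), and computes
the two-sided p from the tie-corrected normal approximation **without**
continuity correction — the convention of the commercial graphing package
used for the source statistics; with the correction, the total-mutations
comparison would print p = 0.7 instead of the published 0.6, while without
it U = 6.0 gives p = 0.0200 exactly. An exact-enumeration oracle pins the
U statistic for all group shapes with n₁·n₂ ≤ 30; p-values are reported but
not regression-pinned. Marker trajectories report binomial SEM
(√(f(1−f)/n)) per timepoint and plot ±2·SEM bars.

## Synthetic cohort: what it emulates, what it does not

The generator emulates: a pooled population sample as 100 weighted
haplotypes (planted frequencies are exact at 1/100 resolution and recorded
in a truth table); genomes with non-overlapping genes (length a multiple of
3) at a target coding fraction, one duplicated 500 bp repeat pair, an IS
library, prophage intervals and plasmids; a resident strain as a 2%-diverged
backbone with its own plasmid; 250 bp read pairs at Poisson pair counts
(coverage·L/(2·250)), normal fragment lengths (500 ± 60 bp), and a
two-state quality model (Q35 body, Q10 tail with probability rising as the
cube of read position) so the trimmer has realistic work. Errors follow
quality — a base at phred q errs at error_rate · min(10^((35−q)/10), 10) —
so body bases err at `error_rate` (default 10⁻³) and degraded tails up to
tenfold more; `error_rate=0` disables errors exactly. Each public entry
point derives its RNG from (salt, seed) so, e.g., a genome and a resident
generated with the same seed never share an underlying bit stream.

Not emulated: cycle-resolved Illumina error profiles, indel sequencing
errors, PCR duplicates, GC-coverage bias, microbiome background beyond one
resident strain, and target-site duplications at IS junctions. A green test
therefore establishes that the *decision rules and estimators* behave as
specified under calibrated noise — not that the pipeline's error rates
match any particular instrument.

Defaults mirror the study design where stated (250 bp pairs, ~400×
coverage for old-mouse samples, planted frequencies from the printed
tables); insert-size and error-model parameters are conventional choices,
not reconstructions, because the source protocol does not state them.

## Numerical and degenerate-input choices

* Coordinates are 1-based closed everywhere; SAM (0-based) and BED
  (0-based half-open) convert at their I/O boundaries only.
* The consensus mean-frequency threshold applies with a 10⁻⁹ tolerance so
  a mean of exactly 5% is not lost to floating-point rounding.
* An empty read is a discard verdict, not an exception; an unmappable read
  is an unmapped record, not an error; a prophage interval with uncovered
  flanks yields a missing estimate.
* Cross-run indel matching and pileup token counting both use leftmost
  placement; a deletion's printed position is its (left-aligned) first
  deleted base, an insertion's its anchor base.
* `mean_sem` refuses n < 2; Mann–Whitney refuses empty groups; identical
  groups report p = 1 (the z-score is clipped at 0).

## Known limitations

* The polymorphism-mode caller's exact-test filter removes ~5% of true
  variants (α); consensus retains them at reduced reported frequency.
* Variants at exactly 5% population frequency sit on the callers' decision
  boundary; measured frequency noise makes their recovery a coin flip, as
  it is in the original filter design.
* IS sites are reported with a few bp of ambiguity when element ends match
  the reference; frequencies assume elements longer than the read length.
* The aligner handles one indel ≤ 20 bp per read and no split alignments
  across references; large deletions are only visible as coverage loss.
* Read partitioning assumes the strains are distinguishable at k = 21
  within a read pair; reads from long identical regions are set aside as
  unassigned and do not contribute depth there.
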