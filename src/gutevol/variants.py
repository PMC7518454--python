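"""Polymorphism calling, repeat/breakpoint masking, cross-run consensus and
functional annotation.

Two callers are implemented, matching the study design:

* ``call_naive`` — the filtered-pileup caller: among high-quality
  observations (MQ >= 20, BQ >= 30), an alternate allele is emitted iff it
  is supported by at least 3% of quality reads AND by at least five quality
  reads on EACH strand, with a strand ratio (pos/neg) strictly inside
  (0.2, 5.0).
* ``call_polymode`` — the polymorphism-mode caller: depth >= 5, alternate
  frequency >= 0.05, and no significant strand bias (two-sided Fisher exact
  test on the 2x2 allele-by-strand table at alpha = 0.05; the protocol
  names no specific test, so the exact test is this package's choice).

Per-run call sets are merged by the consensus rule: a variant survives iff
detected in >= 2 runs and its frequency averaged over ALL runs (absent run
counted as 0 — the stricter reading, switchable) is >= 5%. Calls inside
repeat regions or within +-10 bp of structural junctions are masked first;
false-positive SNPs cluster there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from scipy.stats import fisher_exact

from .genome import AnnotatedGenome, Gene, Interval, revcomp
from .align import Pileup


@dataclass(frozen=True)
class VariantCall:
    run: str
    position: int
    ref: str
    alt: str  # alt base, inserted sequence, or str(deleted length)
    type: str  # snp | insertion | deletion
    frequency: float
    support: tuple[int, int]  # (pos-strand, neg-strand) quality reads
    depth: int  # quality-read depth

    def key(self) -> tuple:
        return (self.position, self.type, self.ref, self.alt)


@dataclass
class ConsensusVariant:
    position: int
    ref: str
    alt: str
    type: str
    run_frequencies: dict[str, float]
    mean_frequency: float
    n_supporting_runs: int


@dataclass
class MaskSet:
    intervals: list[Interval] = field(default_factory=list)

    def __contains__(self, pos: int) -> bool:
        return any(pos in iv for iv in self.intervals)

    @classmethod
    def from_genome(cls, genome: AnnotatedGenome,
                    junctions: list[int] = (), pad: int = 10) -> "MaskSet":
        """Repeat regions plus +-pad around structural junctions (IS
        insertion sites, inversion edges)."""
        ivs = list(genome.repeats)
        for i, j in enumerate(junctions):
            ivs.append(Interval(f"bp{i}", max(1, j - pad),
                                min(len(genome), j + pad)))
        return cls(ivs)

    def to_bed(self, path: str | Path, chrom: str) -> None:
        # BED is 0-based half-open on disk; converted here at the boundary
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, *rest = line.split("\t")
                ivs.append(Interval(rest[0].strip() if rest else f"m{len(ivs)}",
                                    int(s) + 1, int(e)))
        return cls(ivs)


# ------------------------------------------------------------------ callers


def _site_calls(site, run: str, emit) -> list[VariantCall]:
    """Enumerate candidate alternate alleles at one site.

    SNP frequencies are measured against the high-quality depth; indel
    frequencies against supporting + spanning reads (only reads extending
    well past an indel on both sides can report it, so the denominator must
    be restricted the same way or frequencies bias low).
    """
    calls = []
    for allele, (p, n) in site.alleles.items():
        if isinstance(allele, str):  # base
            if allele == site.ref:
                continue
            vtype, ref, alt = "snp", site.ref, allele
            depth = site.hq_depth
        elif allele[0] == "+":
            vtype, ref, alt = "insertion", site.ref, allele[1]
            depth = p + n + site.span
        else:
            vtype, ref, alt = "deletion", site.ref, str(allele[1])
            depth = p + n + site.span
        call = emit(vtype, ref, alt, p, n, depth)
        if call is not None:
            calls.append(call)
    return calls


def call_naive(pileup: Pileup, min_fraction: float = 0.03,
               min_quality_reads: int = 5, bias_low: float = 0.2,
               bias_high: float = 5.0, run: str = "naive"
               ) -> list[VariantCall]:
    """The 3% / five-quality-reads-per-strand / strand-ratio caller."""
    calls: list[VariantCall] = []
    for pos in pileup.candidate_positions():
        site = pileup.site(int(pos))
        depth = site.hq_depth
        if depth == 0:
            continue

        def emit(vtype, ref, alt, p, n, vdepth, _pos=int(pos)):
            total = p + n
            if vdepth == 0 or total < min_fraction * vdepth:
                return None
            if p < min_quality_reads or n < min_quality_reads:
                return None
            bias = p / n
            if not bias_low < bias < bias_high:
                return None
            return VariantCall(run, _pos, ref, alt, vtype, total / vdepth,
                               (p, n), vdepth)

        calls.extend(_site_calls(site, run, emit))
    return calls


def call_polymode(pileup: Pileup, min_coverage: int = 5,
                  min_freq: float = 0.05, bias_alpha: float = 0.05,
                  run: str = "polymode") -> list[VariantCall]:
    """Coverage >= 5, frequency >= 0.05, no significant strand bias."""
    calls: list[VariantCall] = []
    for pos in pileup.candidate_positions():
        site = pileup.site(int(pos))
        depth = site.hq_depth
        if depth < min_coverage:
            continue
        rp, rn = site.alleles.get(site.ref, (0, 0))

        def emit(vtype, ref, alt, p, n, vdepth, _pos=int(pos),
                 _rp=rp, _rn=rn):
            total = p + n
            if vdepth < min_coverage or total / vdepth < min_freq:
                return None
            pval = fisher_exact([[p, n], [_rp, _rn]],
                                alternative="two-sided")[1]
            if pval < bias_alpha:
                return None
            return VariantCall(run, _pos, ref, alt, vtype, total / vdepth,
                               (p, n), vdepth)

        calls.extend(_site_calls(site, run, emit))
    return calls


def apply_mask(calls: list[VariantCall], mask: MaskSet) -> list[VariantCall]:
    return [c for c in calls if c.position not in mask]


# ----------------------------------------------------------------- consensus


def left_align_indel(position: int, vtype: str, alt: str,
                     genome: AnnotatedGenome) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement.

    Deletions start AT ``position`` (alt is the deleted length as str);
    insertions are anchored to the base BEFORE the inserted sequence.
    Different aligners place the same indel in a homopolymer/repeat at
    different offsets; normalizing makes cross-run matching exact.
    """
    seq = genome.sequence
    if vtype == "deletion":
        n = int(alt)
        p = position  # 1-based first deleted base
        while p > 1 and seq[p - 2] == seq[p + n - 2]:
            p -= 1
        return p, alt
    if vtype == "insertion":
        ins = alt
        p = position  # anchor base
        while p >= 1 and ins[-1] == seq[p - 1]:
            ins = seq[p - 1] + ins[:-1]
            p -= 1
        return p, ins
    return position, alt


def merge_runs(run_calls: list[list[VariantCall]], n_runs_total: int = 3,
               min_runs: int = 2, min_mean_freq: float = 0.05,
               genome: AnnotatedGenome | None = None,
               mean_over: str = "total") -> list[ConsensusVariant]:
    """Consensus across alignment runs.

    ``mean_over='total'`` divides the frequency sum by ``n_runs_total``
    with absent runs contributing 0 (the stricter reading of "average
    frequency between the three alignments"); ``'detected'`` divides by the
    number of runs that saw the variant.
    """
    if len(run_calls) < 2:
        raise ValueError("need at least two run call sets")
    labels = [calls[0].run if calls else f"run{i}"
              for i, calls in enumerate(run_calls)]
    if len(set(labels)) != len(labels):
        raise ValueError("run labels must be distinct")
    merged: dict[tuple, dict[str, VariantCall]] = {}
    for label, calls in zip(labels, run_calls):
        for c in calls:
            pos, alt = c.position, c.alt
            if genome is not None and c.type in ("insertion", "deletion"):
                pos, alt = left_align_indel(pos, c.type, alt, genome)
            slot = merged.setdefault((pos, c.type, alt), {})
            prev = slot.get(label)
            # two placements of one event can normalize to the same key
            # within a run; keep the better-supported one
            if prev is None or sum(c.support) > sum(prev.support):
                slot[label] = c
    out = []
    for (pos, vtype, alt), per_run in sorted(merged.items(),
                                             key=lambda kv: kv[0][:2]):
        freqs = {lab: (per_run[lab].frequency if lab in per_run else 0.0)
                 for lab in labels}
        denom = n_runs_total if mean_over == "total" else len(per_run)
        mean = sum(freqs.values()) / denom
        # tolerance keeps a mean of exactly 5% from failing on FP rounding
        if len(per_run) >= min_runs and mean >= min_mean_freq - 1e-9:
            ref = next(iter(per_run.values())).ref
            out.append(ConsensusVariant(pos, ref, alt, vtype, freqs,
                                        mean, len(per_run)))
    return out


# ---------------------------------------------------------------- annotation


@dataclass
class MutationRecord:
    """One row of a mutation table: descriptor + gene context + frequency."""

    mouse: str
    cohort: str
    position: str  # printed form; inversions span "start-end"
    mutation: str  # e.g. "C → T", "+1 T", "Δ 10 bp", "IS5", "Inversion 296 bp"
    gene: str  # gene name or "left→/right←" intergenic flank pair
    annotation: str  # "R → C", "Synonymous", "Frameshift", "Intergenic", ...
    frequency: float


def _intergenic_context(genome: AnnotatedGenome, pos: int) -> str:
    left, right = genome.flanking_genes(pos)
    l = left.arrow if left else "origin"
    r = right.arrow if right else "end"
    return f"{l}/{r}"


def _codon_effect(genome: AnnotatedGenome, gene: Gene, pos: int,
                  alt: str) -> str:
    """Translate the reference vs alternate codon for an in-gene SNP."""
    if gene.strand == "+":
        offset = pos - gene.start
    else:
        offset = gene.end - pos
    ci = offset // 3
    within = offset % 3
    if gene.strand == "+":
        cstart = gene.start + 3 * ci
        codon = genome.fetch(cstart, cstart + 2)
        mutated = codon[:within] + alt + codon[within + 1:]
    else:
        cend = gene.end - 3 * ci
        codon = revcomp(genome.fetch(cend - 2, cend))
        alt_rc = revcomp(alt)
        mutated = codon[:within] + alt_rc + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return "Synonymous"
    return f"{aa_ref} → {aa_alt}"


def annotate_position(genome: AnnotatedGenome, position: int, vtype: str,
                      alt: str = "", length: int = 0) -> tuple[str, str]:
    """(gene context, effect) for a variant at a position.

    vtype in {snp, insertion, deletion, is_insertion, inversion}.
    """
    if not 1 <= position <= len(genome):
        raise ValueError(f"position {position} outside genome")
    gene = genome.gene_at(position)
    if gene is None:
        return _intergenic_context(genome, position), "Intergenic"
    if vtype == "snp":
        return gene.name, _codon_effect(genome, gene, position, alt)
    if vtype == "is_insertion":
        return gene.name, "Gene interrupted"
    if vtype == "inversion":
        return gene.name, "Gene inverted"
    if vtype in ("insertion", "deletion"):
        n = length or len(alt)
        if n % 3:
            return gene.name, "Frameshift"
        if vtype == "insertion":
            return gene.name, "Codon insertion"
        if gene.start <= position and position + n - 1 <= gene.end:
            return gene.name, "Codons deleted"
        return gene.name, "Partial gene deletion"
    raise ValueError(f"cannot annotate type {vtype!r}")


def annotate_variant(variant, genome: AnnotatedGenome, mouse: str = "",
                     cohort: str = "") -> MutationRecord:
    """Annotate a ConsensusVariant or an ISCall into a table row."""
    from .mge import ISCall  # late import; mge imports nothing from here

    if isinstance(variant, ISCall):
        gene, ann = annotate_position(genome, variant.site, "is_insertion")
        return MutationRecord(mouse, cohort, str(variant.site),
                              variant.element, gene, ann,
                              round(variant.frequency, 2))
    v: ConsensusVariant = variant
    if v.type == "snp":
        mut = f"{v.ref} → {v.alt}"
        gene, ann = annotate_position(genome, v.position, "snp", v.alt)
    elif v.type == "insertion":
        mut = f"+{len(v.alt)} {v.alt}"
        gene, ann = annotate_position(genome, v.position, "insertion", v.alt)
    else:
        n = int(v.alt)
        mut = f"Δ {n} bp"
        gene, ann = annotate_position(genome, v.position, "deletion",
                                      length=n)
    return MutationRecord(mouse, cohort, str(v.position), mut, gene, ann,
                          round(v.mean_frequency, 2))


def describe_variant(planted, genome: AnnotatedGenome
                     ) -> tuple[str, str, str, str]:
    """Table-layout (position, mutation, gene, annotation) for a planted
    variant — the truth-side counterpart of annotate_variant."""
    v = planted
    if v.kind == "snp":
        gene, ann = annotate_position(genome, v.position, "snp", v.alt_allele)
        return str(v.position), f"{v.ref_allele} → {v.alt_allele}", gene, ann
    if v.kind == "insertion":
        gene, ann = annotate_position(genome, v.position, "insertion",
                                      v.alt_allele)
        return str(v.position), f"+{len(v.alt_allele)} {v.alt_allele}", \
            gene, ann
    if v.kind == "deletion":
        gene, ann = annotate_position(genome, v.position, "deletion",
                                      length=v.length)
        return str(v.position), f"Δ {v.length} bp", gene, ann
    if v.kind == "is_insertion":
        gene, ann = annotate_position(genome, v.position, "is_insertion")
        return str(v.position), v.element, gene, ann
    if v.kind == "inversion":
        gene, ann = annotate_position(genome, v.position, "inversion")
        span = v.end - v.position + 1
        return f"{v.position}-{v.end}", f"Inversion {span} bp", gene, ann
    if v.kind == "prophage_gain":
        return str(v.position), v.element or "prophage", "", "Prophage"
    raise ValueError(v.kind)


# ------------------------------------------------------------------- VCF


def write_vcf(variants: list[ConsensusVariant], genome: AnnotatedGenome,
              path: str | Path) -> None:
    """Consensus variants as VCF with AF / run-support INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.name},length={len(genome)}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,'
                 'Description="Mean frequency across runs">\n')
        fh.write('##INFO=<ID=NRUNS,Number=1,Type=Integer,'
                 'Description="Supporting alignment runs">\n')
        fh.write('##INFO=<ID=RUNFREQS,Number=.,Type=String,'
                 'Description="Per-run frequencies">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.position):
            if v.type == "snp":
                pos, ref, alt = v.position, v.ref, v.alt
            elif v.type == "insertion":
                pos = v.position
                ref = genome.fetch(pos, pos)
                alt = ref + v.alt
            else:  # deletion: VCF anchors at the base before
                n = int(v.alt)
                pos = v.position - 1
                ref = genome.fetch(pos, pos + n)
                alt = ref[0]
            runfreqs = ",".join(f"{k}:{f:.4f}"
                                for k, f in v.run_frequencies.items())
            fh.write(f"{genome.name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"AF={v.mean_frequency:.4f};"
                     f"NRUNS={v.n_supporting_runs};RUNFREQS={runfreqs}\n")
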