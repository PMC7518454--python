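"""Synthetic populations of an invader strain colonizing a gut.

Everything downstream (QC, alignment, variant and mobile-element calling,
cohort statistics) is exercised against data from this module: annotated
genomes, pooled populations of haplotypes carrying planted variants at known
frequencies, and paired-end reads with per-pair truth tags.

The stated world: pooled sequencing of >1000 clones is emulated by a
population of ``n_haplotypes`` (default 100) weighted haplotypes, so that a
planted frequency is realized exactly at 1/100 granularity. Reads are 250 bp
paired-end with a two-state quality model (Q35 body, Q10 tail) so the
sliding-window trimmer has realistic work to do; errors follow base quality,
scaled so body bases err at ``error_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, Gene, Interval, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

VARIANT_KINDS = ("snp", "insertion", "deletion", "is_insertion", "inversion",
                 "prophage_gain")


def _rng(seed: int, salt: int) -> np.random.Generator:
    """Independent stream per operation: salting keeps a genome generated
    with seed s and a resident derived with the same s from sharing one
    underlying bit stream (which would make 'random' sequences copies of
    each other)."""
    return np.random.default_rng([salt, seed])


class SizingError(ValueError):
    """Requested features cannot be packed into the requested length."""


class VariantConflictError(ValueError):
    """Two planted variants touch the same base on one haplotype."""


@dataclass
class PlantedVariant:
    """One variant planted into a weighted subset of haplotypes.

    ``position`` is 1-based. Insertions (plain, IS, prophage) insert AFTER
    ``position`` (left-anchored, matching the single-position presentation
    of insertions in the mutation tables); deletions start AT ``position``;
    inversions span ``position``..``end``.
    """

    kind: str
    position: int
    truth_frequency: float
    ref_allele: str | None = None
    alt_allele: str | None = None  # snp alt or inserted sequence
    element: str | None = None  # IS element or prophage name
    end: int | None = None  # inversion right edge
    length: int | None = None  # deletion length
    sequence: str | None = None  # prophage sequence (if not in genome annotation)
    # optional presentation overrides used when transcribing printed tables
    gene: str | None = None
    annotation: str | None = None
    mutation_label: str | None = None

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if not 0.0 <= self.truth_frequency <= 1.0:
            raise ValueError("truth_frequency must be in [0, 1]")
        if self.kind == "snp" and self.alt_allele is not None \
                and self.alt_allele == self.ref_allele:
            raise ValueError("snp alt allele equals ref allele")

    def span(self) -> tuple[int, int]:
        """Reference bases touched (for per-haplotype conflict checks)."""
        if self.kind == "deletion":
            return self.position, self.position + (self.length or 1) - 1
        if self.kind == "inversion":
            return self.position, self.end or self.position
        return self.position, self.position


@dataclass
class ReadPair:
    id: str
    read1: tuple[str, np.ndarray]  # (bases, phred qualities)
    read2: tuple[str, np.ndarray]
    fragment_length: int
    source_label: str


# --------------------------------------------------------------- genomes


def generate_genome(length: int, gene_fraction: float, n_is_elements: int = 3,
                    n_prophages: int = 2, seed: int = 0, *,
                    mean_gene_length: int = 900, repeat_length: int = 500,
                    prophage_length: int = 3000,
                    name: str = "invader") -> AnnotatedGenome:
    """Generate a random annotated genome.

    Genes are non-overlapping with intergenic gaps sized so the coding
    fraction comes out near ``gene_fraction``; gene lengths are multiples of
    3. One duplicated segment is always emitted as a repeat pair so repeat
    masking has something to mask.
    """
    if length < 10_000:
        raise SizingError(f"genome length {length} < 10000")
    if not 0 < gene_fraction < 1:
        raise ValueError("gene_fraction must be in (0, 1)")
    min_gap = 30
    if gene_fraction > mean_gene_length / (mean_gene_length + min_gap):
        raise SizingError(
            f"gene_fraction {gene_fraction} cannot be packed with "
            f"{min_gap} bp intergenic gaps")
    if n_prophages * prophage_length > length // 2:
        raise SizingError(
            f"{n_prophages} prophages of {prophage_length} bp do not fit "
            f"in half of a {length} bp genome")
    rng = _rng(seed, 1)
    seq = rng.choice(_BASES, size=length).tobytes().decode()

    # duplicated segment -> two repeat intervals
    rep = rng.choice(_BASES, size=repeat_length).tobytes().decode()
    third = max(length // 3, repeat_length + 1)
    p1 = int(rng.integers(200, third - repeat_length))
    p2 = int(rng.integers(2 * third, length - repeat_length - 200))
    seq = seq[:p1] + rep + seq[p1 + repeat_length:]
    seq = seq[:p2] + rep + seq[p2 + repeat_length:]
    repeats = [Interval("rep1a", p1 + 1, p1 + repeat_length),
               Interval("rep1b", p2 + 1, p2 + repeat_length)]

    genes: list[Gene] = []
    pos = int(rng.integers(100, 200))
    i = 0
    while True:
        glen = int(rng.normal(mean_gene_length, mean_gene_length / 3))
        glen = max(150, glen - glen % 3)
        gap = max(min_gap, int(glen * (1 - gene_fraction) / gene_fraction))
        if pos + glen > length - 100:
            break
        i += 1
        genes.append(Gene(f"gene{i:04d}", pos + 1, pos + glen,
                          "+" if rng.random() < 0.5 else "-"))
        pos += glen + gap

    is_library = [(f"IS{j + 1}",
                   rng.choice(_BASES, size=int(rng.integers(800, 1400)))
                   .tobytes().decode())
                  for j in range(n_is_elements)]

    prophages = []
    for j in range(n_prophages):
        start = int(rng.integers(1, length - prophage_length))
        prophages.append(Interval(f"phage{j + 1}", start,
                                  start + prophage_length - 1))

    plasmid = rng.choice(_BASES, size=5000).tobytes().decode()
    return AnnotatedGenome(name=name, sequence=seq, genes=genes,
                           repeats=repeats, is_library=is_library,
                           prophages=prophages,
                           plasmids=[("plasmid1", plasmid)])


def make_resident(invader: AnnotatedGenome, divergence: float = 0.02,
                  seed: int = 0, name: str = "resident") -> AnnotatedGenome:
    """A resident strain: the invader's backbone diverged at ``divergence``
    substitutions per site, with its own plasmid. Source of contaminating
    reads and (via its prophages) of horizontally transferred material."""
    rng = _rng(seed, 2)
    arr = np.frombuffer(invader.sequence.encode(), dtype=np.uint8).copy()
    n_sub = rng.binomial(len(arr), divergence)
    sites = rng.choice(len(arr), size=n_sub, replace=False)
    arr[sites] = _BASES[(np.searchsorted(np.sort(_BASES), arr[sites])
                         + rng.integers(1, 4, size=n_sub)) % 4]
    plasmid = rng.choice(_BASES, size=8000).tobytes().decode()
    return AnnotatedGenome(name=name, sequence=arr.tobytes().decode(),
                           prophages=list(invader.prophages),
                           plasmids=[("res_plasmid1", plasmid)])


# ------------------------------------------------------------ populations


def _apply_edits(sequence: str, edits: list[PlantedVariant],
                 genome: AnnotatedGenome) -> str:
    """Apply edits right-to-left so earlier coordinates stay valid."""
    s = sequence
    for v in sorted(edits, key=lambda v: v.position, reverse=True):
        p = v.position
        if v.kind == "snp":
            s = s[:p - 1] + v.alt_allele + s[p:]
        elif v.kind == "insertion":
            s = s[:p] + v.alt_allele + s[p:]
        elif v.kind == "deletion":
            s = s[:p - 1] + s[p - 1 + v.length:]
        elif v.kind == "is_insertion":
            elem = dict(genome.is_library)[v.element]
            s = s[:p] + elem + s[p:]
        elif v.kind == "inversion":
            s = s[:p - 1] + revcomp(s[p - 1:v.end]) + s[v.end:]
        elif v.kind == "prophage_gain":
            phage = v.sequence
            if phage is None:
                iv = {x.name: x for x in genome.prophages}[v.element]
                phage = genome.fetch(iv.start, iv.end)
            s = s[:p] + phage + s[p:]
    return s


def plant_variants(genome: AnnotatedGenome, variants: list[PlantedVariant],
                   n_haplotypes: int = 100, seed: int = 0,
                   ) -> tuple[list[tuple[str, float]], pd.DataFrame]:
    """Realize a polymorphic population as weighted haplotypes.

    Each variant is carried by ``round(truth_frequency * n_haplotypes)``
    haplotypes chosen at random, so the realized frequency is exact to
    1/n_haplotypes and recorded in the returned truth table.
    """
    rng = _rng(seed, 3)
    n = n_haplotypes
    filled = []
    for v in variants:
        if not 1 <= v.position <= len(genome):
            raise ValueError(f"variant position {v.position} outside genome")
        if v.kind == "snp":
            ref = genome.fetch(v.position, v.position)
            if v.ref_allele is None:
                v = replace(v, ref_allele=ref)
            elif v.ref_allele != ref:
                raise ValueError(f"ref allele mismatch at {v.position}")
            if v.alt_allele == v.ref_allele:
                raise ValueError("snp alt allele equals ref allele")
        if v.kind == "deletion":
            if v.length is None:
                v = replace(v, length=len(v.ref_allele or "A"))
            v = replace(v, ref_allele=genome.fetch(
                v.position, v.position + v.length - 1))
        filled.append(v)

    carriers: list[np.ndarray] = []
    per_hap: list[list[PlantedVariant]] = [[] for _ in range(n)]
    for v in filled:
        k = int(round(v.truth_frequency * n))
        who = rng.choice(n, size=k, replace=False)
        carriers.append(who)
        lo, hi = v.span()
        for h in who:
            for u in per_hap[h]:
                ulo, uhi = u.span()
                if lo <= uhi and ulo <= hi:
                    raise VariantConflictError(
                        f"variants at {u.position} and {v.position} overlap "
                        f"on haplotype {h}")
            per_hap[h].append(v)

    population = [(_apply_edits(genome.sequence, edits, genome), 1.0 / n)
                  for edits in per_hap]
    rows = []
    for v, who in zip(filled, carriers):
        rows.append({
            "kind": v.kind, "position": v.position,
            "ref": v.ref_allele or "", "alt": v.alt_allele or "",
            "element": v.element or "",
            "end": v.end if v.end is not None else "",
            "length": v.length if v.length is not None else "",
            "truth_frequency": v.truth_frequency,
            "realized_frequency": len(who) / n,
            "carriers": ",".join(map(str, sorted(int(x) for x in who))),
        })
    return population, pd.DataFrame(rows)


# ------------------------------------------------------------------ reads


@dataclass
class QualityModel:
    """Two-state per-base quality: a Q-``high`` body with a Q-``low`` tail.

    P(low state at cycle i) = tail_max * (i / (L-1)) ** tail_shape, so read
    starts are clean and ends degrade — the regime the sliding-window
    trimmer exists for.
    """

    high: int = 35
    low: int = 10
    tail_max: float = 0.5
    tail_shape: float = 3.0

    def draw(self, rng: np.random.Generator, length: int) -> np.ndarray:
        x = np.arange(length) / max(length - 1, 1)
        p_low = self.tail_max * x ** self.tail_shape
        return np.where(rng.random(length) < p_low, self.low,
                        self.high).astype(np.int64)


def simulate_reads(population: list[tuple[str, float]], coverage: float,
                   read_length: int = 250, fragment_mean: float = 500,
                   fragment_sd: float = 60, error_rate: float = 0.001,
                   contamination: tuple[AnnotatedGenome, float] | None = None,
                   seed: int = 0, quality_model: QualityModel | None = None,
                   sample: str = "sim") -> list[ReadPair]:
    """Paired-end reads from a weighted haplotype population.

    The pair count is Poisson with mean coverage * L / (2 * read_length).
    Per-base error probability follows quality: a base at phred q errs with
    probability error_rate * min(10**((high - q) / 10), 10), so body bases
    err at ``error_rate`` exactly and degraded tail bases up to tenfold
    more, as on a real flow cell. error_rate=0 disables errors everywhere.
    """
    if not population:
        raise ValueError("empty population")
    if read_length > fragment_mean:
        raise ValueError("read_length exceeds fragment_mean")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    qm = quality_model or QualityModel()
    rng = _rng(seed, 4)

    sources: list[tuple[str, str]] = []  # (label, sequence)
    probs: list[float] = []
    cfrac = contamination[1] if contamination else 0.0
    for j, (hap, w) in enumerate(population):
        sources.append((f"hap{j}", hap))
        probs.append(w * (1 - cfrac))
    if contamination:
        resident, _ = contamination
        pool = [("resident", resident.sequence)] + \
               [(f"plasmid:{nm}", sq) for nm, sq in resident.plasmids]
        total = sum(len(s) for _, s in pool)
        for nm, sq in pool:
            sources.append((nm, sq))
            probs.append(cfrac * len(sq) / total)
    probs_arr = np.asarray(probs)
    probs_arr = probs_arr / probs_arr.sum()

    mean_len = sum(len(s) for (_, s), w in zip(sources, probs_arr) if w > 0) \
        / max(1, sum(1 for w in probs_arr if w > 0))
    n_pairs = rng.poisson(coverage * mean_len / (2 * read_length))
    counts = rng.multinomial(n_pairs, probs_arr)

    err_scale = error_rate if error_rate > 0 else 0.0
    pairs: list[ReadPair] = []
    serial = 0
    for (label, src), k in zip(sources, counts):
        L = len(src)
        for _ in range(k):
            flen = int(np.clip(rng.normal(fragment_mean, fragment_sd),
                               read_length, L))
            start = int(rng.integers(0, L - flen + 1))
            frag = src[start:start + flen]
            r1 = frag[:read_length]
            r2 = revcomp(frag)[:read_length]
            mates = []
            for bases in (r1, r2):
                q = qm.draw(rng, len(bases))
                if err_scale > 0:
                    boost = np.minimum(10.0 ** ((qm.high - q) / 10), 10.0)
                    p_err = np.minimum(err_scale * boost, 0.75)
                    hits = np.nonzero(rng.random(len(bases)) < p_err)[0]
                    if hits.size:
                        arr = np.frombuffer(bases.encode(), np.uint8).copy()
                        shift = rng.integers(1, 4, size=hits.size)
                        idx = np.searchsorted(_BASES, arr[hits])
                        arr[hits] = _BASES[(idx + shift) % 4]
                        bases = arr.tobytes().decode()
                mates.append((bases, q))
            pairs.append(ReadPair(f"{sample}:{serial:07d}", mates[0],
                                  mates[1], flen, label))
            serial += 1
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def write_fastq(pairs: list[ReadPair], prefix: str | Path,
                truth_path: str | Path | None = None) -> tuple[Path, Path]:
    """Write a read set as <prefix>.R1.fastq / .R2.fastq (phred+33) plus an
    optional truth-tag TSV (read id -> source label)."""
    prefix = Path(prefix)
    p1, p2 = Path(f"{prefix}.R1.fastq"), Path(f"{prefix}.R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pr in pairs:
            for fh, (bases, quals), mate in ((f1, pr.read1, 1),
                                             (f2, pr.read2, 2)):
                qstr = "".join(chr(int(q) + 33) for q in quals)
                fh.write(f"@{pr.id}/{mate}\n{bases}\n+\n{qstr}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tsource_label\n")
            for pr in pairs:
                fh.write(f"{pr.id}\t{pr.source_label}\n")
    return p1, p2


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path
                     ) -> list[ReadPair]:
    from Bio import SeqIO

    out = []
    for rec1, rec2 in zip(SeqIO.parse(str(r1_path), "fastq"),
                          SeqIO.parse(str(r2_path), "fastq")):
        q1 = np.asarray(rec1.letter_annotations["phred_quality"])
        q2 = np.asarray(rec2.letter_annotations["phred_quality"])
        rid = rec1.id.rsplit("/", 1)[0]
        out.append(ReadPair(rid, (str(rec1.seq), q1), (str(rec2.seq), q2),
                            0, ""))
    return out


# ------------------------------------------------------------------ cohort


@dataclass
class MouseSpec:
    mouse: str
    cohort: str  # 'old' | 'young'
    variants: list[PlantedVariant] = field(default_factory=list)


TRUTH_COLUMNS = ["mouse", "cohort", "position", "mutation", "gene",
                 "annotation", "frequency"]


def _truth_row(v: PlantedVariant, genome: AnnotatedGenome | None) -> dict:
    from .variants import describe_variant  # late import: no cycle at load

    if v.mutation_label is not None and v.gene is not None:
        mut, gene, ann = v.mutation_label, v.gene, v.annotation or ""
        pos = (f"{v.position}-{v.end}" if v.kind == "inversion"
               else str(v.position))
    else:
        if genome is None:
            raise ValueError("need a genome to annotate unlabeled variants")
        pos, mut, gene, ann = describe_variant(v, genome)
    return {"position": pos, "mutation": mut, "gene": gene,
            "annotation": ann, "frequency": v.truth_frequency}


def simulate_cohort(cohort_spec: list[MouseSpec], seed: int = 0,
                    genome: AnnotatedGenome | None = None,
                    coverage: float = 0, out_dir: str | Path | None = None,
                    **read_kwargs) -> pd.DataFrame:
    """Per-mouse populations/read sets plus a cohort truth table.

    The truth table uses the same column layout as the packaged mutation
    tables (mouse, cohort, position, mutation, gene, annotation, frequency),
    so cohort statistics computed on it are directly comparable. If
    ``coverage`` > 0 a genome is required and one FASTQ pair + truth-tag
    file per mouse is written under ``out_dir``.
    """
    groups = {m.cohort for m in cohort_spec}
    bad = groups - {"old", "young"}
    if bad:
        raise ValueError(f"unknown cohort labels: {sorted(bad)}")
    rows = []
    rng = _rng(seed, 5)
    for m in cohort_spec:
        for v in m.variants:
            rows.append({"mouse": m.mouse, "cohort": m.cohort,
                         **_truth_row(v, genome)})
        if coverage > 0:
            if genome is None or out_dir is None:
                raise ValueError("reads need a genome and an out_dir")
            sub = int(rng.integers(0, 2 ** 31 - 1))
            pop, _ = plant_variants(genome, m.variants, seed=sub)
            pairs = simulate_reads(pop, coverage, seed=sub, sample=m.mouse,
                                   **read_kwargs)
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_fastq(pairs, out / m.mouse, out / f"{m.mouse}.truth.tsv")
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / "cohort_truth.tsv", sep="\t", index=False)
    return df


def cohort_spec_from_table(df: pd.DataFrame) -> list[MouseSpec]:
    """Turn a mutation table (mouse, cohort, position, mutation, gene,
    annotation, frequency) into per-mouse planted-variant lists.

    The printed descriptor/gene/annotation strings are carried as overrides
    so a truth table written back out reproduces the input rows; positions
    stay in the printed coordinate frame (rescale before planting into a
    synthetic genome).
    """
    import re

    specs: list[MouseSpec] = []
    for mouse, grp in df.groupby("mouse", sort=True):
        variants = []
        for _, row in grp.iterrows():
            mut = str(row["mutation"]).strip()
            pos_s = str(row["position"]).strip()
            freq = row["frequency"]
            freq = float(freq) if pd.notna(freq) else 0.0
            common = dict(truth_frequency=freq, gene=str(row.get("gene", "")),
                          annotation=str(row["annotation"]).strip(),
                          mutation_label=mut)
            if "Prophage" in str(row["annotation"]):
                pos = int(pos_s.split("-")[0]) if pos_s and pos_s != "nan" \
                    else 1
                variants.append(PlantedVariant("prophage_gain", pos,
                                               element=mut, **common))
                continue
            m = re.match(r"^\+(\d+)\s+([ACGT]+)$", mut)
            if m:
                variants.append(PlantedVariant(
                    "insertion", int(pos_s), alt_allele=m.group(2), **common))
                continue
            m = re.match(r"^Δ\s*(\d+)\s*bp$", mut)
            if m:
                variants.append(PlantedVariant(
                    "deletion", int(pos_s), length=int(m.group(1)), **common))
                continue
            if re.match(r"^IS\w+$", mut):
                variants.append(PlantedVariant(
                    "is_insertion", int(pos_s), element=mut, **common))
                continue
            m = re.match(r"^Inversion\s+(\d+)\s*bp$", mut)
            if m:
                start, end = (int(x) for x in pos_s.split("-"))
                variants.append(PlantedVariant(
                    "inversion", start, end=end, **common))
                continue
            m = re.match(r"^([ACGT]) → ([ACGT])$", mut)
            if m:
                variants.append(PlantedVariant(
                    "snp", int(pos_s), ref_allele=m.group(1),
                    alt_allele=m.group(2), **common))
                continue
            raise ValueError(f"cannot parse mutation descriptor {mut!r}")
        specs.append(MouseSpec(str(mouse), str(grp["cohort"].iloc[0]),
                               variants))
    return specs


def draw_cohort_spec(n_mice: int, cohort: str, rates: dict[str, float],
                     genome: AnnotatedGenome, seed: int = 0,
                     prefix: str | None = None) -> list[MouseSpec]:
    """Draw per-mouse variant lists from per-category Poisson rates.

    ``rates`` maps kind (snp/insertion/deletion/is_insertion) to the mean
    number planted per mouse; frequencies are Uniform(0.05, 1.0), the band
    the study's callers are sensitive to.
    """
    rng = _rng(seed, 6)
    prefix = prefix or cohort[0].upper()
    out = []
    for i in range(n_mice):
        variants: list[PlantedVariant] = []
        used: list[tuple[int, int]] = []
        for kind, rate in rates.items():
            for _ in range(rng.poisson(rate)):
                for _attempt in range(100):
                    pos = int(rng.integers(500, len(genome) - 500))
                    v = _random_variant(kind, pos, rng, genome)
                    lo, hi = v.span()
                    if all(hi < a - 5 or lo > b + 5 for a, b in used):
                        used.append((lo, hi))
                        variants.append(v)
                        break
        out.append(MouseSpec(f"{prefix}{i + 1}", cohort, variants))
    return out


def _random_variant(kind: str, pos: int, rng: np.random.Generator,
                    genome: AnnotatedGenome) -> PlantedVariant:
    freq = float(np.round(rng.uniform(0.05, 1.0), 2))
    if kind == "snp":
        ref = genome.fetch(pos, pos)
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        return PlantedVariant("snp", pos, freq, ref_allele=ref, alt_allele=alt)
    if kind == "insertion":
        ins = "".join(rng.choice(list("ACGT"),
                                 size=int(rng.choice([1, 3, 6]))))
        return PlantedVariant("insertion", pos, freq, alt_allele=ins)
    if kind == "deletion":
        return PlantedVariant("deletion", pos, freq,
                              length=int(rng.choice([1, 9, 10, 12])))
    if kind == "is_insertion":
        name = genome.is_library[int(rng.integers(len(genome.is_library)))][0]
        return PlantedVariant("is_insertion", pos, freq, element=name)
    raise ValueError(f"cannot draw kind {kind!r}")
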