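"""Annotated reference genomes and their on-disk formats.

Coordinates are 1-based closed intervals throughout the package, matching
the way bacterial genome tables are printed. The only conversions happen at
format boundaries (SAM/BED are handled in their own modules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad gene interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def arrow(self) -> str:
        """Gene name decorated with its strand arrow, e.g. ``ymgF→``."""
        return self.name + ("→" if self.strand == "+" else "←")


@dataclass(frozen=True)
class Interval:
    name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class AnnotatedGenome:
    """A reference sequence plus the annotation every caller needs.

    ``genes`` are non-overlapping protein-coding spans, ``repeats`` are
    intervals where read placement is ambiguous (masked during variant
    calling), ``is_library`` holds the known insertion-sequence elements,
    ``prophages`` the predicted prophage intervals and ``plasmids`` any
    extrachromosomal sequences carried by the strain.
    """

    name: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    repeats: list[Interval] = field(default_factory=list)
    is_library: list[tuple[str, str]] = field(default_factory=list)
    prophages: list[Interval] = field(default_factory=list)
    plasmids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for feats, kind in ((self.genes, "gene"), (self.repeats, "repeat"),
                            (self.prophages, "prophage")):
            names = [f.name for f in feats]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate {kind} names")
            for f in feats:
                if f.end > n:
                    raise ValueError(
                        f"{kind} {f.name} extends past genome end ({f.end} > {n})")

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_at(self, pos: int) -> Gene | None:
        for g in self.genes:
            if pos in g:
                return g
        return None

    def flanking_genes(self, pos: int) -> tuple[Gene | None, Gene | None]:
        """The nearest genes left and right of an intergenic position."""
        left = right = None
        for g in sorted(self.genes, key=lambda g: g.start):
            if g.end < pos:
                left = g
            elif g.start > pos and right is None:
                right = g
        return left, right

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on 1-based closed coordinates."""
        if not 1 <= start <= end <= len(self.sequence):
            raise ValueError(f"fetch out of range: {start}-{end}")
        return self.sequence[start - 1:end]

    # ---------------------------------------------------------------- I/O

    def to_fasta(self, path: str | Path, include_plasmids: bool = True) -> None:
        records = [SeqRecord(Seq(self.sequence), id=self.name, description="")]
        if include_plasmids:
            records += [SeqRecord(Seq(s), id=n, description="plasmid")
                        for n, s in self.plasmids]
        SeqIO.write(records, str(path), "fasta")

    def is_library_to_fasta(self, path: str | Path) -> None:
        SeqIO.write([SeqRecord(Seq(s), id=n, description="IS element")
                     for n, s in self.is_library], str(path), "fasta")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.name} 1 {len(self)}\n")
            for g in self.genes:
                fh.write("\t".join([self.name, "gutevol", "gene",
                                    str(g.start), str(g.end), ".", g.strand,
                                    "0", f"ID={g.name};Name={g.name}"]) + "\n")
            for r in self.repeats:
                fh.write("\t".join([self.name, "gutevol", "repeat_region",
                                    str(r.start), str(r.end), ".", ".", ".",
                                    f"ID={r.name}"]) + "\n")
            for p in self.prophages:
                fh.write("\t".join([self.name, "gutevol", "prophage",
                                    str(p.start), str(p.end), ".", ".", ".",
                                    f"ID={p.name}"]) + "\n")


def read_genome(fasta: str | Path, gff3: str | Path | None = None,
                is_fasta: str | Path | None = None) -> AnnotatedGenome:
    """Load a genome (+ optional annotation and IS library) from disk.

    The first FASTA record is the chromosome; any further records are
    treated as plasmids.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta}")
    genome = AnnotatedGenome(
        name=records[0].id, sequence=str(records[0].seq),
        plasmids=[(r.id, str(r.seq)) for r in records[1:]])
    if gff3 is not None:
        genes, repeats, prophages = [], [], []
        with open(gff3) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                _, _, ftype, start, end, _, strand, _, attrs = parts
                name = dict(kv.split("=", 1) for kv in attrs.split(";")
                            if "=" in kv).get("ID", f"{ftype}_{start}")
                if ftype == "gene":
                    genes.append(Gene(name, int(start), int(end), strand))
                elif ftype == "repeat_region":
                    repeats.append(Interval(name, int(start), int(end)))
                elif ftype == "prophage":
                    prophages.append(Interval(name, int(start), int(end)))
        genome.genes, genome.repeats, genome.prophages = genes, repeats, prophages
        genome.__post_init__()
    if is_fasta is not None:
        genome.is_library = [(r.id, str(r.seq))
                             for r in SeqIO.parse(str(is_fasta), "fasta")]
    return genome


def read_prophage_table(path: str | Path) -> list[Interval]:
    """Prophage intervals from a TSV with columns start, end, name (+extras)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    out = []
    for i, row in df.iterrows():
        name = str(row[cols["name"]]) if "name" in cols else f"phage{i + 1}"
        out.append(Interval(name, int(row[cols["start"]]), int(row[cols["end"]])))
    return out
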