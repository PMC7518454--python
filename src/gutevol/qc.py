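"""Quality trimming and multi-reference read partitioning.

Trimming follows the pooled-sequencing protocol exactly: 4 bp sliding
windows (step 1) are consumed from the 5' end and then the 3' end while the
window's mean phred is below 20; a read survives only if at least 100 bp
remain and at least half of the remaining bases are Q20 or better. Mates are
trimmed independently and a pair is kept only if both mates survive
(a deliberate, documented policy — the pairing rule is not part of the
protocol).

Partitioning resolves invader/resident/plasmid contamination by shared
k-mer scoring against each reference; a pair lands in the bin with the
strictly highest score, ties and weak matches go to ``unassigned`` so
downstream calling never double-counts a read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotatedGenome, revcomp
from .simulate import ReadPair

BINS = ("invader", "resident", "plasmid", "unassigned")


@dataclass(frozen=True)
class QCParams:
    window: int = 4
    min_window_q: float = 20.0
    min_length: int = 100
    min_q20_fraction: float = 0.5
    q20: int = 20

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")


def trim_read(read: tuple[str, np.ndarray], params: QCParams = QCParams()
              ) -> tuple[str, np.ndarray] | None:
    """Trim one read; returns the surviving (bases, quals) or None.

    The window slides one base at a time: while the leading ``window`` bases
    average below ``min_window_q`` the first base is dropped, then the same
    from the tail. A short remainder is judged on whatever is left.
    """
    bases, quals = read
    if len(bases) != len(quals):
        raise ValueError("bases and qualities differ in length")
    q = np.asarray(quals, dtype=float)
    lo, hi = 0, len(q)  # live half-open window into the read
    w = params.window
    while lo < hi and q[lo:min(lo + w, hi)].mean() < params.min_window_q:
        lo += 1
    while lo < hi and q[max(hi - w, lo):hi].mean() < params.min_window_q:
        hi -= 1
    if hi - lo < params.min_length:
        return None
    kept = q[lo:hi]
    if (kept >= params.q20).mean() < params.min_q20_fraction:
        return None
    return bases[lo:hi], np.asarray(quals)[lo:hi]


def filter_pair(pair: ReadPair, params: QCParams = QCParams()
                ) -> ReadPair | None:
    """Both mates must survive trimming or the whole pair is discarded."""
    t1 = trim_read(pair.read1, params)
    t2 = trim_read(pair.read2, params)
    if t1 is None or t2 is None:
        return None
    return ReadPair(pair.id, t1, t2, pair.fragment_length, pair.source_label)


def qc_pairs(pairs: list[ReadPair], params: QCParams = QCParams()
             ) -> list[ReadPair]:
    out = []
    for p in pairs:
        kept = filter_pair(p, params)
        if kept is not None:
            out.append(kept)
    return out


# ------------------------------------------------------------ partitioning


class KmerIndex:
    """Set of canonical k-mers of a reference sequence."""

    def __init__(self, sequences: list[str], k: int = 21):
        self.k = k
        kmers: set[str] = set()
        for seq in sequences:
            seq = seq.upper()
            rc = revcomp(seq)
            n = len(seq)
            for i in range(n - k + 1):
                fwd = seq[i:i + k]
                rev = rc[n - k - i:n - i]
                kmers.add(min(fwd, rev))
        self.kmers = kmers

    def score(self, bases: str) -> int:
        k = self.k
        if len(bases) < k:
            return 0
        rc = revcomp(bases)
        n = len(bases)
        hits = 0
        for i in range(n - k + 1):
            if min(bases[i:i + k], rc[n - k - i:n - i]) in self.kmers:
                hits += 1
        return hits


@dataclass
class PartitionResult:
    bins: dict[str, list[ReadPair]] = field(
        default_factory=lambda: {b: [] for b in BINS})
    scores: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {b: len(v) for b, v in self.bins.items()}


def partition_reads(pairs: list[ReadPair], invader: AnnotatedGenome,
                    resident: AnnotatedGenome,
                    plasmids: list[tuple[str, str]] | None = None,
                    k: int = 21, min_score: int = 10,
                    indexes: dict[str, KmerIndex] | None = None
                    ) -> PartitionResult:
    """Assign each pair to invader / resident / plasmid / unassigned.

    Both mates of a pair are scored together against each reference's k-mer
    set. Strictly-highest score >= min_score wins; anything else — including
    a tie between references, as in a region identical between the two
    strains — is unassigned, which also captures reads matching neither
    strain (foreign contamination).
    """
    for p in pairs:
        if len(p.read1[0]) < k or len(p.read2[0]) < k:
            raise ValueError(f"k={k} exceeds a mate length in pair {p.id}")
    if indexes is None:
        indexes = build_partition_indexes(invader, resident, plasmids, k)
    result = PartitionResult()
    for p in pairs:
        s = {b: indexes[b].score(p.read1[0]) + indexes[b].score(p.read2[0])
             for b in ("invader", "resident", "plasmid")}
        best = max(s, key=s.get)
        top = s[best]
        tie = sum(1 for v in s.values() if v == top) > 1
        bin_ = "unassigned" if tie or top < min_score else best
        result.bins[bin_].append(p)
        result.scores[p.id] = (s["invader"], s["resident"], s["plasmid"])
    assert sum(len(v) for v in result.bins.values()) == len(pairs)
    return result


def build_partition_indexes(invader: AnnotatedGenome,
                            resident: AnnotatedGenome,
                            plasmids: list[tuple[str, str]] | None = None,
                            k: int = 21) -> dict[str, KmerIndex]:
    """Indexes are the expensive part; build once, reuse across samples."""
    if plasmids is None:
        plasmids = list(resident.plasmids)
    return {
        "invader": KmerIndex([invader.sequence], k),
        "resident": KmerIndex([resident.sequence], k),
        "plasmid": KmerIndex([s for _, s in plasmids] or ["A" * k], k),
    }
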