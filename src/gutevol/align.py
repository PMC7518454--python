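"""Minimal deterministic seed-and-extend aligner, SAM I/O and pileups.

The aligner exists so the whole pipeline is testable without external
mappers: exact-k-mer seeding, ungapped extension with a mismatch budget,
a two-diagonal rescue for indels up to 20 bp, and soft-clipping at
structural junctions (IS insertions, inversion edges). Mapping quality is
two-valued — 60 for a unique best diagonal, 0 for a tie — because the only
threshold that matters downstream is MQ >= 20.

Externally produced alignments are ingested from SAM via pysam; "alignment
run" is an opaque label downstream, so consensus logic never cares whether
a run came from this aligner or from BWA/minimap2.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .genome import AnnotatedGenome, revcomp
from .simulate import ReadPair

OPS = ("match", "mismatch", "insert", "delete", "clip")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


class ParseError(ValueError):
    pass


@dataclass
class AlignmentRecord:
    read_id: str
    ref_id: str | None  # None = unmapped
    start: int  # 1-based leftmost reference position (0 if unmapped)
    strand: str  # '+'/'-' ('.' if unmapped)
    ops: list[tuple[str, int]]
    mapq: int
    bases: str  # in alignment orientation (as stored in SAM)
    quals: np.ndarray
    is_read1: bool = True
    mate_ref: str | None = None
    mate_start: int = 0
    mate_unmapped: bool = True

    @property
    def mapped(self) -> bool:
        return self.ref_id is not None

    @property
    def end(self) -> int:
        """1-based rightmost aligned reference position."""
        span = sum(n for op, n in self.ops if op in
                   ("match", "mismatch", "delete"))
        return self.start + span - 1

    def clip_left(self) -> int:
        return self.ops[0][1] if self.ops and self.ops[0][0] == "clip" else 0

    def clip_right(self) -> int:
        return self.ops[-1][1] if self.ops and self.ops[-1][0] == "clip" else 0


def _runs_to_ops(mism: np.ndarray) -> list[tuple[str, int]]:
    """Collapse a per-base mismatch mask into match/mismatch runs."""
    if len(mism) == 0:
        return []
    change = np.nonzero(np.diff(mism))[0] + 1
    bounds = np.concatenate(([0], change, [len(mism)]))
    return [("mismatch" if mism[a] else "match", int(b - a))
            for a, b in zip(bounds[:-1], bounds[1:])]


def _dense_tails(mism: np.ndarray, drop: int = -4) -> tuple[int, int]:
    """X-drop terminal trimming: length of mismatch-dense prefix/suffix
    (score +1 match / -2 mismatch; cut at the score minimum if <= drop)."""
    score = np.where(mism, -2, 1)
    pre = np.cumsum(score)
    i = int(np.argmin(pre))
    lead = i + 1 if pre[i] <= drop else 0
    suf = np.cumsum(score[::-1])
    j = int(np.argmin(suf))
    tail = j + 1 if suf[j] <= drop else 0
    if lead + tail >= len(mism):
        return 0, 0
    return lead, tail


class Aligner:
    def __init__(self, reference: AnnotatedGenome, seed_length: int = 21,
                 max_mismatch_fraction: float = 0.1, max_indel: int = 20):
        self.reference = reference
        self.k = seed_length
        self.max_mm = max_mismatch_fraction
        self.max_indel = max_indel
        self.ref_arr = np.frombuffer(reference.sequence.encode(), np.uint8)
        self.index: dict[str, list[int]] = defaultdict(list)
        seq = reference.sequence
        for i in range(len(seq) - seed_length + 1):
            self.index[seq[i:i + seed_length]].append(i)
        self.index = dict(self.index)

    # ------------------------------------------------------------- core

    def _candidates(self, seq: str) -> dict[int, list[int]]:
        """Map diagonal (0-based read start on ref) -> seed offsets hitting it."""
        k, L = self.k, len(seq)
        if L < k:
            return {}
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        diags: dict[int, list[int]] = defaultdict(list)
        for o in offsets:
            for p in self.index.get(seq[o:o + k], ()):
                diags[p - o].append(o)
        return diags

    def align_sequence(self, seq: str
                       ) -> tuple[int, str, list[tuple[str, int]], int] | None:
        """Align one sequence; returns (start_1based, strand, ops, mapq)."""
        entries = []  # (-votes, strand, diag, offsets)
        all_cands = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            cands = self._candidates(s)
            all_cands[strand] = (s, cands)
            for d, offs in cands.items():
                entries.append((-len(offs), strand, d, offs))
        if not entries:
            return None
        entries.sort(key=lambda e: e[:3])
        neg_votes, strand, diag, offs = entries[0]
        mapq = 60
        for e in entries[1:]:
            if e[0] != neg_votes:
                break
            # an equal-vote diagonal on the same strand within max_indel is
            # the other half of one gapped placement, not an ambiguity
            if e[1] != strand or abs(e[2] - diag) > self.max_indel:
                mapq = 0
                break
        s, cands = all_cands[strand]

        aln = self._place(s, diag, min(offs))
        if aln is None:
            return None
        start0, ops = aln
        return start0 + 1, strand, ops, mapq

    def _place(self, s: str, diag: int, seed_off: int):
        """Ungapped if clean; otherwise banded indel rescue; otherwise
        soft-clip around the seeded core."""
        L = len(s)
        a, b, mism = self._overlap(s, diag)
        full_overlap = (a == 0 and b == L)
        c_ungapped = int(mism.sum()) if full_overlap else L
        if full_overlap and c_ungapped <= 2:
            return diag, _runs_to_ops(mism)
        gapped = self._gapped(s, diag) if full_overlap else None
        if gapped is not None and gapped[0] <= c_ungapped - 3:
            _, d1, ops = gapped
            return d1, ops
        if full_overlap and c_ungapped <= self.max_mm * L:
            # mismatch-dense read ends are foreign sequence (short junction
            # overhangs), not substitutions: clip them
            lead, tail = _dense_tails(mism)
            core = mism[lead:L - tail]
            if L - lead - tail < 30 or core.sum() > self.max_mm * len(core):
                return self._clipped(s, diag, seed_off)
            ops = _runs_to_ops(core)
            if lead:
                ops = [("clip", lead)] + ops
            if tail:
                ops = ops + [("clip", tail)]
            return diag + lead, ops
        return self._clipped(s, diag, seed_off)

    def _overlap(self, s: str, diag: int) -> tuple[int, int, np.ndarray]:
        """Read-coordinate overlap [a, b) with the reference on a diagonal,
        plus the mismatch mask over that overlap."""
        L, R = len(s), len(self.ref_arr)
        a = max(0, -diag)
        b = min(L, R - diag)
        if b <= a:
            return 0, 0, np.zeros(0, bool)
        read = np.frombuffer(s.encode(), np.uint8)[a:b]
        mism = read != self.ref_arr[diag + a:diag + b]
        return a, b, mism

    def _ungapped(self, s: str, diag: int):
        a, b, mism = self._overlap(s, diag)
        n = b - a
        if n < len(s) or n == 0:  # hangs off the contig -> handled as clip
            return None
        if mism.sum() > self.max_mm * n:
            return None
        return diag, _runs_to_ops(mism)

    def _mask_on(self, s: str, diag: int) -> np.ndarray | None:
        """Full-length mismatch mask of the read on a diagonal; None if the
        read does not fit inside the reference there."""
        a, b, _ = 0, len(s), None
        if diag < 0 or diag + len(s) > len(self.ref_arr):
            return None
        read = np.frombuffer(s.encode(), np.uint8)
        return read != self.ref_arr[diag:diag + len(s)]

    _MIN_SEGMENT = 10  # bp each side of an indel, or it is not believable

    def _gapped(self, s: str, diag: int):
        """Banded one-indel rescue against the seeded diagonal.

        Enumerates indel sizes 1..max_indel on both sides of the seeded
        segment (the seed may anchor either the left or the right part) and
        picks the (size, split) minimizing total mismatches. Both segments
        must span at least _MIN_SEGMENT bases, so a mismatch-dense tail a
        few bases long cannot masquerade as an indel.
        """
        L = len(s)
        m0 = self._mask_on(s, diag)
        if m0 is None:
            return None
        pre0 = np.concatenate(([0], np.cumsum(m0)))
        suf0 = np.concatenate((np.cumsum(m0[::-1])[::-1], [0]))
        best = None  # (cost, d1, ops)
        ms = self._MIN_SEGMENT
        for size in range(1, self.max_indel + 1):
            for kind in ("delete", "insert"):
                # the read's right part sits on d_left + size (deletion)
                # or d_left - size (insertion)
                for anchor in ("left", "right"):
                    if anchor == "left":
                        d1 = diag
                        d2 = diag + size if kind == "delete" else diag - size
                        m2 = self._mask_on(s, d2)
                        if m2 is None:
                            continue
                        pre = pre0
                        suf = np.concatenate(
                            (np.cumsum(m2[::-1])[::-1], [0]))
                    else:
                        d2 = diag
                        d1 = diag - size if kind == "delete" else diag + size
                        m1 = self._mask_on(s, d1)
                        if m1 is None:
                            continue
                        pre = np.concatenate(([0], np.cumsum(m1)))
                        suf = suf0
                    m_left = m0 if anchor == "left" else m1
                    m_right = m2 if anchor == "left" else m0
                    if kind == "insert":
                        xs = np.arange(ms, L - size - ms + 1)
                        if xs.size == 0:
                            continue
                        cost = pre[xs] + suf[xs + size]
                        adj = (m_left[xs - 1].astype(int)
                               + m_right[np.minimum(xs + size, L - 1)])
                    else:
                        xs = np.arange(ms, L - ms + 1)
                        if xs.size == 0:
                            continue
                        cost = pre[xs] + suf[xs]
                        adj = (m_left[xs - 1].astype(int)
                               + m_right[np.minimum(xs, L - 1)])
                    # break cost ties against splits that leave a mismatch
                    # touching the gap (classic misplaced-indel signature)
                    i = int(np.argmin(cost * 3 + adj))
                    c, x = int(cost[i]), int(xs[i])
                    if best is not None and c >= best[0]:
                        continue
                    # each segment must be clean on its own: a junction
                    # read's foreign half cannot hide behind the other
                    # half's matches
                    c_left = int(pre[x])
                    c_right = c - c_left
                    right_len = L - x - (size if kind == "insert" else 0)
                    if c_left > max(2, self.max_mm * x) or \
                            c_right > max(2, self.max_mm * right_len):
                        continue
                    if kind == "insert":
                        ops = (_runs_to_ops(m_left[:x]) + [("insert", size)]
                               + _runs_to_ops(m_right[x + size:]))
                        aligned = L - size
                    else:
                        ops = (_runs_to_ops(m_left[:x]) + [("delete", size)]
                               + _runs_to_ops(m_right[x:]))
                        aligned = L
                    if c <= self.max_mm * aligned:
                        best = (c, d1, ops)
        return best

    def _clipped(self, s: str, diag: int, seed_off: int):
        """Extend from the voted seed while the local neighborhood keeps
        matching; soft-clip the rest (structural junctions, contig ends)."""
        a, b, mism = self._overlap(s, diag)
        if b - a < self.k:
            return None
        match = ~mism
        o = seed_off - a  # seed position within the overlap
        o = max(0, min(o, len(match) - 1))
        left = o
        while left > 0 and (match[left - 1]
                            or match[max(0, left - 4):left].sum() >= 2):
            left -= 1
        while left < len(match) and not match[left]:
            left += 1
        right = min(o + self.k, len(match))
        while right < len(match) and (match[right]
                                      or match[right:right + 4].sum() >= 2):
            right += 1
        while right > left and not match[right - 1]:
            right -= 1
        span = right - left
        if span < 30 or mism[left:right].sum() > self.max_mm * span:
            return None
        ops: list[tuple[str, int]] = []
        lead = a + left
        if lead:
            ops.append(("clip", lead))
        ops += _runs_to_ops(mism[left:right])
        tail = len(s) - (a + right)
        if tail:
            ops.append(("clip", tail))
        return diag + a + left, ops

    # ------------------------------------------------------------ pairs

    def align_pairs(self, pairs: list[ReadPair]) -> list[AlignmentRecord]:
        records: list[AlignmentRecord] = []
        for p in pairs:
            recs = []
            for (bases, quals), is_r1 in ((p.read1, True), (p.read2, False)):
                hit = self.align_sequence(bases)
                if hit is None:
                    recs.append(AlignmentRecord(
                        p.id, None, 0, ".", [], 0, bases,
                        np.asarray(quals), is_read1=is_r1))
                else:
                    start, strand, ops, mapq = hit
                    if strand == "-":
                        bases, quals = revcomp(bases), np.asarray(quals)[::-1]
                    recs.append(AlignmentRecord(
                        p.id, self.reference.name, start, strand, ops, mapq,
                        bases, np.asarray(quals), is_read1=is_r1))
            r1, r2 = recs
            r1.mate_ref, r1.mate_start = r2.ref_id, r2.start
            r1.mate_unmapped = not r2.mapped
            r2.mate_ref, r2.mate_start = r1.ref_id, r1.start
            r2.mate_unmapped = not r1.mapped
            records.extend(recs)
        return records


def sort_records(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Coordinate sort; unmapped records go last (their mates keep them
    discoverable for discordant-pair evidence)."""
    return sorted(records, key=lambda r: (not r.mapped, r.ref_id or "~",
                                          r.start, r.read_id, not r.is_read1))


# ----------------------------------------------------------------- SAM I/O

_TO_CIGAR = {"match": 7, "mismatch": 8, "insert": 1, "delete": 2, "clip": 4}
_FROM_CIGAR = {0: "match", 7: "match", 8: "mismatch", 1: "insert",
               2: "delete", 4: "clip"}


def write_sam(records: list[AlignmentRecord], reference: AnnotatedGenome,
              path: str | Path) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": reference.name, "LN": len(reference)}]
              + [{"SN": n, "LN": len(s)} for n, s in reference.plasmids]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.query_sequence = r.bases
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in r.quals))
            flag = 0x1
            flag |= 0x40 if r.is_read1 else 0x80
            if r.mapped:
                seg.reference_name = r.ref_id
                seg.reference_start = r.start - 1
                seg.mapping_quality = r.mapq
                seg.cigartuples = [(_TO_CIGAR[op], n) for op, n in r.ops]
                if r.strand == "-":
                    flag |= 0x10
            else:
                flag |= 0x4
            if r.mate_unmapped:
                flag |= 0x8
            elif r.mate_ref is not None:
                seg.next_reference_name = r.mate_ref
                seg.next_reference_start = r.mate_start - 1
            seg.flag = flag
            out.write(seg)


def read_alignment_file(path: str | Path,
                        reference: AnnotatedGenome | None = None
                        ) -> list[AlignmentRecord]:
    """Lossless SAM import. Plain 'M' ops are read as 'match' (external
    aligners rarely emit =/X); mismatch status is irrelevant downstream
    because pileups re-derive bases from the read sequence."""
    known = None
    if reference is not None:
        known = {reference.name} | {n for n, _ in reference.plasmids}
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        it = fh.fetch(until_eof=True)
        i = 0
        while True:
            i += 1
            try:
                try:
                    seg = next(it)
                except StopIteration:
                    break
                mapped = not seg.is_unmapped
                if mapped and known is not None \
                        and seg.reference_name not in known:
                    raise ParseError(
                        f"unknown reference {seg.reference_name!r}")
                ops = []
                if mapped:
                    for code, n in seg.cigartuples or []:
                        if code == 5:
                            continue  # hard clip carries no bases
                        if code not in _FROM_CIGAR:
                            raise ParseError(f"unsupported CIGAR op {code}")
                        ops.append((_FROM_CIGAR[code], n))
                quals = (np.asarray(seg.query_qualities)
                         if seg.query_qualities is not None
                         else np.zeros(len(seg.query_sequence or ""), int))
                records.append(AlignmentRecord(
                    seg.query_name,
                    seg.reference_name if mapped else None,
                    (seg.reference_start + 1) if mapped else 0,
                    ("-" if seg.is_reverse else "+") if mapped else ".",
                    ops, seg.mapping_quality, seg.query_sequence or "",
                    quals,
                    is_read1=not seg.is_read2,
                    mate_ref=seg.next_reference_name
                    if not seg.mate_is_unmapped else None,
                    mate_start=(seg.next_reference_start + 1)
                    if not seg.mate_is_unmapped else 0,
                    mate_unmapped=seg.mate_is_unmapped))
            except ParseError:
                raise
            except Exception as exc:  # malformed record
                raise ParseError(f"malformed record at line {i}: {exc}") \
                    from exc
    return records


# ------------------------------------------------------------------ pileup


@dataclass
class SiteCounts:
    """High-quality evidence at one reference position.

    ``alleles`` maps a base 'A'/'C'/'G'/'T', an insertion token
    ('+', seq) anchored at the preceding base, or a deletion token
    ('-', length) anchored at the first deleted base, to (pos-strand,
    neg-strand) high-quality read counts. ``hq_depth`` counts high-quality
    base observations plus reads deleted across the position.
    """

    position: int
    ref: str
    alleles: dict
    hq_depth: int
    depth: int
    span: int = 0  # hq reads spanning the position with indel-proof margins


@dataclass
class PileupColumn:
    position: int
    observations: list = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


class Pileup:
    """Per-position counts over a reference, MQ-filtered at build time.

    Base observations below ``min_baseq`` are retained but flagged
    low-quality so callers can apply "quality read" thresholds; reads below
    ``min_mapq`` are excluded entirely.
    """

    def __init__(self, reference: AnnotatedGenome, min_mapq: int = 20,
                 min_baseq: int = 30, end_trim: int = 9,
                 indel_margin: int = 10):
        self.reference = reference
        self.min_mapq = min_mapq
        self.min_baseq = min_baseq
        # terminal aligned bases are never 'quality' observations: an indel
        # within indel_margin of a read end cannot be rescued as a gap, so
        # its shifted tail masquerades as terminal mismatches; censoring
        # end_trim = indel_margin - 1 bases removes that signature uniformly
        self.end_trim = end_trim
        # an indel is only reportable by reads extending indel_margin bases
        # past it on both sides; spanning counts use the same margin so the
        # indel frequency denominator is geometry-matched
        self.indel_margin = indel_margin
        L = len(reference)
        # [position 1..L, base 0..3, strand(0=+), hq(0=lq,1=hq)]
        self.base_counts = np.zeros((L + 1, 4, 2, 2), np.uint32)
        self.del_counts = np.zeros((L + 1, 2, 2), np.uint32)
        self.span_counts = np.zeros(L + 1, np.uint32)  # hq spanning reads
        self.indels: dict[int, dict] = defaultdict(
            lambda: defaultdict(lambda: np.zeros((2, 2), np.int64)))
        self.keep_observations = False
        self.observations: dict[int, list] = defaultdict(list)

    # builder -----------------------------------------------------------

    def add_records(self, records: list[AlignmentRecord]) -> None:
        last = -1
        pos_l, base_l, strand_l, hq_l, span_l = [], [], [], [], []
        L = len(self.reference)
        ms = self.indel_margin
        for r in records:
            if not r.mapped:
                continue
            if r.ref_id != self.reference.name:
                continue
            if r.start < last:
                raise ValueError("records not coordinate-sorted")
            last = r.start
            if r.mapq < self.min_mapq:
                continue
            si = 0 if r.strand == "+" else 1
            read_i, ref_p = 0, r.start
            bcodes = _CODE[np.frombuffer(r.bases.encode(), np.uint8)]
            quals = np.asarray(r.quals)
            # aligned read-index bounds for end trimming
            lead = r.ops[0][1] if r.ops and r.ops[0][0] == "clip" else 0
            tail = r.ops[-1][1] if r.ops and r.ops[-1][0] == "clip" else 0
            ri0 = lead + self.end_trim
            ri1 = len(r.bases) - tail - self.end_trim
            # current contiguous match/mismatch block (no indel inside)
            blk_ref = blk_read = blk_len = None
            for op, n in r.ops + [("clip", 0)]:  # sentinel flushes the block
                if op in ("match", "mismatch"):
                    if blk_len is None:
                        blk_ref, blk_read, blk_len = ref_p, read_i, 0
                    hi = min(n, L - ref_p + 1)
                    if hi > 0:
                        idx = np.arange(read_i, read_i + hi)
                        hq = ((quals[read_i:read_i + hi] >= self.min_baseq)
                              & (idx >= ri0) & (idx < ri1)).astype(np.int64)
                        pos_l.append(np.arange(ref_p, ref_p + hi))
                        base_l.append(bcodes[read_i:read_i + hi])
                        strand_l.append(np.full(hi, si, np.int64))
                        hq_l.append(hq)
                        if self.keep_observations:
                            for j in range(hi):
                                self.observations[ref_p + j].append(
                                    (r.bases[read_i + j],
                                     int(quals[read_i + j]), r.strand,
                                     r.mapq))
                    read_i += n
                    ref_p += n
                    blk_len += n
                    continue
                # flush the block: positions with >= ms aligned bases on
                # both sides inside it count as spanning
                if blk_len is not None and blk_len > 2 * ms:
                    lo, hi_p = blk_ref + ms, min(blk_ref + blk_len - ms - 1, L)
                    if hi_p >= lo:
                        off0 = lo - blk_ref
                        idx = np.arange(blk_read + off0,
                                        blk_read + off0 + hi_p - lo + 1)
                        good = ((quals[idx] >= self.min_baseq)
                                & (idx >= ri0) & (idx < ri1))
                        span_l.append(np.arange(lo, hi_p + 1)[good])
                blk_ref = blk_read = blk_len = None
                if op == "clip":
                    read_i += n
                elif op == "insert":
                    q = int(quals[read_i:read_i + n].min())
                    hq = 1 if q >= self.min_baseq else 0
                    anchor = ref_p - 1
                    if 1 <= anchor <= L:
                        # normalize equivalent placements so evidence for
                        # one event lands in one token (leftmost anchor)
                        ins = r.bases[read_i:read_i + n]
                        seq = self.reference.sequence
                        while anchor >= 1 and ins[-1] == seq[anchor - 1]:
                            ins = seq[anchor - 1] + ins[:-1]
                            anchor -= 1
                        self.indels[anchor][("+", ins)][si, hq] += 1
                    read_i += n
                elif op == "delete":
                    qlo = max(read_i - 1, 0)
                    q = int(quals[qlo:read_i + 1].min()) if len(quals) else 0
                    hq = 1 if q >= self.min_baseq else 0
                    if 1 <= ref_p <= L:
                        seq = self.reference.sequence
                        tok = ref_p  # leftmost equivalent first-deleted base
                        while tok > 1 and seq[tok - 2] == seq[tok + n - 2]:
                            tok -= 1
                        self.indels[tok][("-", n)][si, hq] += 1
                    for dp in range(ref_p, min(ref_p + n, L + 1)):
                        self.del_counts[dp, si, hq] += 1
                    ref_p += n
                else:
                    raise ValueError(f"unknown op {op}")
        if pos_l:
            flat = (((np.concatenate(pos_l) * 4 + np.concatenate(base_l))
                     * 2 + np.concatenate(strand_l))
                    * 2 + np.concatenate(hq_l))
            add = np.bincount(flat, minlength=self.base_counts.size)
            self.base_counts += add.reshape(self.base_counts.shape
                                            ).astype(np.uint32)
        if span_l:
            add = np.bincount(np.concatenate(span_l),
                              minlength=self.span_counts.size)
            self.span_counts += add.astype(np.uint32)

    # accessors ---------------------------------------------------------

    def coverage(self, hq_only: bool = False) -> np.ndarray:
        """Read depth per position (index 0 unused)."""
        if hq_only:
            return (self.base_counts[:, :, :, 1].sum(axis=(1, 2))
                    + self.del_counts[:, :, 1].sum(axis=1))
        return (self.base_counts.sum(axis=(1, 2, 3))
                + self.del_counts.sum(axis=(1, 2)))

    def covered_positions(self) -> np.ndarray:
        cov = self.coverage()
        return np.nonzero(cov)[0]

    def candidate_positions(self) -> np.ndarray:
        """Positions with any high-quality non-reference evidence (alternate
        base, insertion token or deletion) — the only sites a caller can
        possibly emit, so the only ones worth visiting."""
        hq = self.base_counts[:, :, :, 1].sum(axis=2)  # [pos, base]
        L = len(self.reference)
        ref_codes = _CODE[np.frombuffer(self.reference.sequence.encode(),
                                        np.uint8)]
        alt = hq[1:L + 1].copy()
        alt[np.arange(L), ref_codes] = 0
        cand = set(np.nonzero(alt.sum(axis=1))[0] + 1)
        cand |= set(np.nonzero(self.del_counts[:, :, 1].sum(axis=1))[0])
        cand |= set(self.indels.keys())
        return np.array(sorted(cand), dtype=int)

    def site(self, pos: int) -> SiteCounts:
        bc = self.base_counts[pos]
        alleles = {}
        for b, base in enumerate("ACGT"):
            p, n = int(bc[b, 0, 1]), int(bc[b, 1, 1])
            if p or n:
                alleles[base] = (p, n)
        for token, cnt in self.indels.get(pos, {}).items():
            alleles[token] = (int(cnt[0, 1]), int(cnt[1, 1]))
        hq_depth = int(bc[:, :, 1].sum() + self.del_counts[pos, :, 1].sum())
        depth = int(bc.sum() + self.del_counts[pos].sum())
        return SiteCounts(pos, self.reference.sequence[pos - 1], alleles,
                          hq_depth, depth, span=int(self.span_counts[pos]))

    def column(self, pos: int) -> PileupColumn:
        if not self.keep_observations:
            raise ValueError("pileup built without keep_observations")
        return PileupColumn(pos, list(self.observations.get(pos, [])))


def build_pileup(records: list[AlignmentRecord], reference: AnnotatedGenome,
                 min_mapq: int = 20, min_baseq: int = 30,
                 end_trim: int = 9, keep_observations: bool = False
                 ) -> Pileup:
    """One pileup over coordinate-sorted records (unsorted input raises)."""
    p = Pileup(reference, min_mapq, min_baseq, end_trim=end_trim)
    p.keep_observations = keep_observations
    p.add_records(records)
    return p
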