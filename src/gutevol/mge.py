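"""IS-insertion detection by evidence voting and prophage-gain estimation.

Three in-house evidence channels stand in for the external IS detectors,
preserving the >=2-of-3 voting contract:

* split_read — soft-clipped tails matched exactly against the IS library,
  clustered at the junction base;
* discordant_pair — pairs with one uniquely mapped anchor whose mate is
  unmapped but matches an IS element, clustered by the innermost anchor
  edges (coarser than split reads by construction);
* junction_assembly — clipped reads around a candidate merged into a
  junction contig by exact overlap, confirmed iff >= 20 bp of reference
  flank abuts >= 20 bp of element sequence.

An accepted call's frequency is estimated from junction vs spanning reads.
Because an inserted element longer than the read produces clipped reads at
BOTH junctions mapping to the same reference base, the junction count is
halved ((left+right)/2) before being compared against reads spanning the
site with the same 20 bp overhang requirement; the plain ratio would
overestimate (a true 0.65 would read ~0.79).

Prophage gain is a coverage ratio: mean depth inside the prophage interval
over mean depth in single-copy flanks, clamped to [0, 1].
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotatedGenome, Interval, revcomp
from .align import AlignmentRecord, Pileup

METHODS = ("split_read", "discordant_pair", "junction_assembly")


@dataclass
class ISCandidate:
    method: str
    element: str
    site: int  # 1-based left junction base
    support: int
    orientation: str = "+"
    side_support: tuple[int, int] = (0, 0)  # (left-junction, right-junction)
    low_support: bool = False


@dataclass
class ISCall:
    element: str
    site: int
    orientation: str
    votes: set[str]
    frequency: float
    support: dict[str, int] = field(default_factory=dict)


@dataclass
class RegionGain:
    region: str
    interval: Interval
    frequency: float | None  # None when the flank is uncovered
    interior_coverage: float
    flank_coverage: float


@dataclass
class JunctionVerdict:
    status: str  # confirms | rejects | insufficient
    site: int | None = None
    contig: str = ""


# ------------------------------------------------------------- IS library


class ISIndex:
    """Exact 20-mer lookup into the IS element library (both strands)."""

    SEED = 20

    def __init__(self, is_library: list[tuple[str, str]]):
        if not is_library:
            raise ValueError("empty IS library")
        self.elements = dict(is_library)
        self.seeds: dict[str, tuple[str, str]] = {}
        k = self.SEED
        for name, seq in is_library:
            for orient, s in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
                for i in range(len(s) - k + 1):
                    self.seeds.setdefault(s[i:i + k], (name, orient))

    def lookup(self, kmer: str) -> tuple[str, str] | None:
        return self.seeds.get(kmer)

    def match_read(self, bases: str, stride: int = 10
                   ) -> tuple[str, str] | None:
        k = self.SEED
        for i in range(0, max(1, len(bases) - k + 1), stride):
            hit = self.seeds.get(bases[i:i + k])
            if hit:
                return hit
        return None


# ------------------------------------------------------------ split reads


def _cluster_positions(items: list[tuple[int, tuple]], window: int
                       ) -> list[list[tuple[int, tuple]]]:
    """Single-linkage clustering of (position, payload) with max gap."""
    items = sorted(items, key=lambda t: t[0])
    clusters: list[list[tuple[int, tuple]]] = []
    for it in items:
        if clusters and it[0] - clusters[-1][-1][0] <= window:
            clusters[-1].append(it)
        else:
            clusters.append([it])
    return clusters


def detect_split(records: list[AlignmentRecord],
                 is_library: list[tuple[str, str]], min_clip: int = 20,
                 cluster_window: int = 10, min_anchor: int = 20
                 ) -> list[ISCandidate]:
    """Soft-clip evidence: clipped tails matched against the IS library.

    A right-clipped read crossing the LEFT junction of an insertion after
    base p clips exactly at p; a left-clipped read crossing the RIGHT
    junction starts at p+1. Both therefore cluster at junction base p.
    """
    idx = ISIndex(is_library)
    k = ISIndex.SEED
    hits: dict[str, list[tuple[int, tuple]]] = defaultdict(list)
    for r in records:
        if not r.mapped or r.mapq < 20:
            continue
        aligned_len = sum(n for op, n in r.ops if op in ("match", "mismatch"))
        if aligned_len < min_anchor:
            continue
        cr = r.clip_right()
        if cr >= min_clip:
            clipped = r.bases[len(r.bases) - cr:]
            hit = idx.lookup(clipped[:k])
            if hit:
                elem, orient = hit
                hits[elem].append((r.end, ("left", orient)))
        cl = r.clip_left()
        if cl >= min_clip:
            clipped = r.bases[:cl]
            hit = idx.lookup(clipped[-k:])
            if hit:
                elem, orient = hit
                hits[elem].append((r.start - 1, ("right", orient)))
    out = []
    for elem, items in hits.items():
        for cluster in _cluster_positions(items, cluster_window):
            sites = Counter(pos for pos, _ in cluster)
            site = min(s for s, c in sites.items()
                       if c == max(sites.values()))
            left = sum(1 for _, (side, _) in cluster if side == "left")
            right = len(cluster) - left
            orient = Counter(o for _, (_, o) in cluster).most_common(1)[0][0]
            out.append(ISCandidate("split_read", elem, site, len(cluster),
                                   orient, (left, right),
                                   low_support=len(cluster) < 3))
    return sorted(out, key=lambda c: (c.site, c.element))


# -------------------------------------------------------- discordant pairs


def detect_discordant(records: list[AlignmentRecord],
                      is_library: list[tuple[str, str]],
                      max_insert_z: float = 3.0, fragment_mean: float = 500,
                      fragment_sd: float = 60) -> list[ISCandidate]:
    """Anchored pairs whose mate lives inside an element absent from the
    reference: the mate is unmapped but matches the IS library. Innermost
    anchor edges from the two sides bracket the junction; their midpoint is
    the (coarse) site estimate."""
    idx = ISIndex(is_library)
    by_id: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        by_id[r.read_id].append(r)
    ev: dict[str, list[tuple[int, tuple]]] = defaultdict(list)
    for rid, recs in by_id.items():
        if len(recs) != 2:
            continue
        for anchor, mate in ((recs[0], recs[1]), (recs[1], recs[0])):
            if not anchor.mapped or anchor.mapq < 20 or mate.mapped:
                continue
            if anchor.clip_left() + anchor.clip_right() >= 20:
                continue  # junction-spanning anchors belong to split evidence
            hit = idx.match_read(mate.bases)
            if hit is None:
                continue
            elem, orient = hit
            if anchor.strand == "+":
                ev[elem].append((anchor.end, ("plus", orient)))
            else:
                ev[elem].append((anchor.start - 1, ("minus", orient)))
    window = int(fragment_mean + max_insert_z * fragment_sd)
    out = []
    for elem, items in ev.items():
        for cluster in _cluster_positions(items, window):
            plus = [p for p, (side, _) in cluster if side == "plus"]
            minus = [p for p, (side, _) in cluster if side == "minus"]
            if plus and minus:
                site = (max(plus) + min(minus)) // 2
            elif plus:
                site = max(plus)
            else:
                site = min(minus)
            orient = Counter(o for _, (_, o) in cluster).most_common(1)[0][0]
            out.append(ISCandidate("discordant_pair", elem, int(site),
                                   len(cluster), orient,
                                   low_support=len(cluster) < 3))
    return sorted(out, key=lambda c: (c.site, c.element))


# -------------------------------------------------------- junction assembly


def _merge_overlap(a: str, b: str, min_overlap: int) -> str | None:
    if b in a:
        return a
    if a in b:
        return b
    top = min(len(a), len(b)) - 1
    for ov in range(top, min_overlap - 1, -1):
        if a[-ov:] == b[:ov]:
            return a + b[ov:]
        if b[-ov:] == a[:ov]:
            return b + a[ov:]
    return None


def assemble_junction(records: list[AlignmentRecord], candidate: ISCandidate,
                      reference: AnnotatedGenome,
                      is_library: list[tuple[str, str]], flank: int = 200,
                      min_overlap: int = 30, min_clip: int = 20
                      ) -> JunctionVerdict:
    """Merge clipped reads near the candidate into a junction contig and
    check it for >= 20 bp of reference abutting >= 20 bp of element."""
    usable = []
    for r in records:
        if not r.mapped or r.mapq < 20:
            continue
        if r.clip_right() >= min_clip and abs(r.end - candidate.site) <= flank:
            usable.append(r.bases)
        elif r.clip_left() >= min_clip \
                and abs(r.start - 1 - candidate.site) <= flank:
            usable.append(r.bases)
    if len(usable) < 2:
        return JunctionVerdict("insufficient")
    usable.sort(key=len, reverse=True)
    contig = usable[0]
    pending = usable[1:]
    progress = True
    while progress:
        progress = False
        rest = []
        for s in pending:
            merged = _merge_overlap(contig, s, min_overlap)
            if merged is not None:
                contig, progress = merged, True
            else:
                rest.append(s)
        pending = rest

    elem_seq = dict(is_library)[candidate.element].upper()
    lo = max(0, candidate.site - flank - 20)
    hi = min(len(reference), candidate.site + flank + 20)
    ref_window = reference.sequence[lo:hi]
    for elem in (elem_seq, revcomp(elem_seq)):
        head, tail = elem[:20], elem[-20:]
        for a in range(20, len(contig) - 19):
            left20, right20 = contig[a - 20:a], contig[a:a + 20]
            # left junction: reference | element-start
            if right20 == head:
                j = ref_window.find(left20)
                if j >= 0:
                    return JunctionVerdict("confirms", lo + j + 20, contig)
            # right junction: element-end | reference
            if left20 == tail:
                j = ref_window.find(right20)
                if j >= 0:
                    return JunctionVerdict("confirms", lo + j, contig)
    return JunctionVerdict("rejects")


# ------------------------------------------------------- voting + frequency


def _junction_counts(records: list[AlignmentRecord], site: int,
                     min_clip: int = 20, min_anchor: int = 20,
                     window: int = 5) -> tuple[int, int, int]:
    """(left-junction, right-junction, spanning) read counts at a site,
    all with a matched >= 20 bp requirement on both sides of the junction."""
    n_left = n_right = n_span = 0
    for r in records:
        if not r.mapped or r.mapq < 20:
            continue
        cr, cl = r.clip_right(), r.clip_left()
        if cr >= min_clip and abs(r.end - site) <= window \
                and r.end - r.start + 1 >= min_anchor:
            n_left += 1
        elif cl >= min_clip and abs(r.start - 1 - site) <= window \
                and r.end - r.start + 1 >= min_anchor:
            n_right += 1
        elif cr < min_clip and cl < min_clip \
                and r.start <= site - min_anchor + 1 \
                and r.end >= site + min_anchor:
            n_span += 1
    return n_left, n_right, n_span


def vote_and_quantify(candidates: list[ISCandidate],
                      records: list[AlignmentRecord],
                      merge_window: int = 15, min_votes: int = 2
                      ) -> list[ISCall]:
    """Merge per-method candidates within ``merge_window`` and accept sites
    with >= ``min_votes`` method votes; frequency from junction/spanning
    counting (see module docstring for the halving)."""
    by_elem: dict[str, list[tuple[int, tuple]]] = defaultdict(list)
    for c in candidates:
        by_elem[c.element].append((c.site, (c,)))
    calls = []
    for elem, items in by_elem.items():
        for cluster in _cluster_positions(items, merge_window):
            cands = [payload[0] for _, payload in cluster]
            votes = {c.method for c in cands}
            if len(votes) < min_votes:
                continue
            by_pref = sorted(cands, key=lambda c: (
                METHODS.index(c.method) if c.method in METHODS else 9,
                -c.support))
            site = next((c.site for c in by_pref
                         if c.method == "split_read"), by_pref[0].site)
            orient = by_pref[0].orientation
            n_left, n_right, n_span = _junction_counts(records, site)
            j_eff = (n_left + n_right) / 2
            denom = j_eff + n_span
            freq = min(1.0, max(0.0, j_eff / denom)) if denom > 0 else 0.0
            calls.append(ISCall(elem, site, orient, votes, freq,
                                {c.method: c.support for c in cands}))
    return sorted(calls, key=lambda c: (c.site, c.element))


def find_is_insertions(records: list[AlignmentRecord],
                       reference: AnnotatedGenome,
                       is_library: list[tuple[str, str]] | None = None,
                       merge_window: int = 15, fragment_mean: float = 500,
                       fragment_sd: float = 60) -> list[ISCall]:
    """The full IS pipeline: split + discordant detection, junction assembly
    on every candidate, then >=2-of-3 voting with frequency estimation."""
    lib = is_library if is_library is not None else reference.is_library
    split = detect_split(records, lib)
    disc = detect_discordant(records, lib, fragment_mean=fragment_mean,
                             fragment_sd=fragment_sd)
    assembled = []
    seen: set[tuple[str, int]] = set()
    for cand in split + disc:
        key = (cand.element, cand.site // max(merge_window, 1))
        if key in seen:
            continue
        seen.add(key)
        verdict = assemble_junction(records, cand, reference, lib)
        if verdict.status == "confirms":
            assembled.append(ISCandidate("junction_assembly", cand.element,
                                         verdict.site, 1, cand.orientation))
    return vote_and_quantify(split + disc + assembled, records,
                             merge_window=merge_window)


def detect_breakpoints(records: list[AlignmentRecord], min_reads: int = 3,
                       window: int = 10, min_clip: int = 20) -> list[int]:
    """Positions where soft-clips cluster — structural junctions of any
    origin (IS insertions, inversion edges, contig ends). Used to build the
    breakpoint part of the variant mask: false-positive SNPs cluster at
    these junctions."""
    edges = []
    for r in records:
        if not r.mapped:
            continue
        if r.clip_right() >= min_clip:
            edges.append((r.end, ()))
        if r.clip_left() >= min_clip:
            edges.append((r.start - 1, ()))
    out = []
    for cluster in _cluster_positions(edges, window):
        if len(cluster) >= min_reads:
            out.append(int(Counter(p for p, _ in cluster).most_common(1)[0][0]))
    return out


# ---------------------------------------------------------- prophage gain


def estimate_region_gain(pileup: Pileup, region: Interval,
                         flank: int = 5000) -> RegionGain:
    """Coverage-ratio estimate of the fraction of the population carrying a
    region (prophage) on a reference that contains it."""
    cov = pileup.coverage().astype(float)
    L = len(pileup.reference)
    if not (1 <= region.start <= region.end <= L):
        raise ValueError(f"region {region.name} outside reference")
    interior = cov[region.start:region.end + 1].mean()
    flank_vals = np.concatenate([
        cov[max(1, region.start - flank):region.start],
        cov[region.end + 1:min(L, region.end + flank) + 1]])
    flank_cov = float(flank_vals.mean()) if flank_vals.size else 0.0
    if flank_cov == 0:
        return RegionGain(region.name, region, None, float(interior), 0.0)
    freq = min(1.0, max(0.0, float(interior) / flank_cov))
    return RegionGain(region.name, region, freq, float(interior), flank_cov)
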