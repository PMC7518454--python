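"""Shared fixtures: one small annotated genome and one moderate-depth
simulated sample, reused session-wide so the suite stays fast."""

from __future__ import annotations

import numpy as np
import pytest

from gutevol import (Aligner, build_pileup, generate_genome, plant_variants,
                     qc_pairs, simulate_reads, sort_records)
from gutevol.align import AlignmentRecord
from gutevol.simulate import PlantedVariant


def safe_positions(genome, n, spacing=1500, margin=600, start=1000):
    """Deterministic positions away from repeats and genome ends."""
    out = []
    pos = start
    while len(out) < n and pos < len(genome) - 1000:
        if all(not (r.start - margin <= pos <= r.end + margin)
               for r in genome.repeats):
            out.append(pos)
            pos += spacing
        else:
            pos += 200
    assert len(out) == n, "could not place positions clear of repeats"
    return out


@pytest.fixture(scope="session")
def genome15():
    return generate_genome(15_000, 0.7, n_is_elements=5, n_prophages=0,
                           seed=7)


@pytest.fixture(scope="session")
def snp_sim(genome15):
    """Planted SNP/indel population sequenced at 300x, aligned and piled."""
    g = genome15
    p_snp, p_ins, p_del = safe_positions(g, 3, spacing=3000)
    ref = g.fetch(p_snp, p_snp)
    alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    variants = [
        PlantedVariant("snp", p_snp, 0.10, ref_allele=ref, alt_allele=alt),
        PlantedVariant("insertion", p_ins, 0.50, alt_allele="TCA"),
        PlantedVariant("deletion", p_del, 0.30, length=2),
    ]
    pop, truth = plant_variants(g, variants, seed=8)
    pairs = simulate_reads(pop, coverage=300, seed=9)
    kept = qc_pairs(pairs)
    records = sort_records(Aligner(g, seed_length=21).align_pairs(kept))
    pileup = build_pileup(records, g)
    return {"genome": g, "variants": variants, "truth": truth,
            "pairs": kept, "records": records, "pileup": pileup}


def make_record(genome, start, bases, strand="+", mapq=60, q=35,
                ops=None, read_id=None, is_read1=True):
    """Hand-built alignment record for constructed-pileup tests."""
    return AlignmentRecord(
        read_id or f"r{start}_{strand}_{np.random.randint(1 << 30)}",
        genome.name, start, strand,
        ops or [("match", len(bases))], mapq, bases,
        np.full(len(bases), q), is_read1=is_read1,
        mate_unmapped=True)


def reads_at(genome, pos, n_pos, n_neg, alt=None, read_len=61, q=35,
             mapq=60, start_id=0):
    """n_pos/n_neg reads covering ``pos`` at their center (margin 30 beats
    the pileup's end trim), optionally carrying ``alt`` at that position."""
    half = read_len // 2
    start = pos - half
    bases = genome.fetch(start, start + read_len - 1)
    if alt is not None:
        bases = bases[:half] + alt + bases[half + 1:]
    recs = []
    for i in range(n_pos):
        recs.append(make_record(genome, start, bases, "+", mapq, q,
                                read_id=f"p{start_id + i}"))
    for i in range(n_neg):
        recs.append(make_record(genome, start, bases, "-", mapq, q,
                                read_id=f"n{start_id + i}"))
    return recs
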