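"""IS-insertion evidence channels, 2-of-3 voting, frequency estimation and
the coverage-based prophage-gain estimator."""

import numpy as np
import pytest

from gutevol import (Aligner, AnnotatedGenome, build_pileup, generate_genome,
                     plant_variants, qc_pairs, simulate_reads, sort_records)
from gutevol.genome import Interval, revcomp
from gutevol.mge import (ISCandidate, assemble_junction, detect_breakpoints,
                         detect_discordant, detect_split,
                         estimate_region_gain, find_is_insertions,
                         vote_and_quantify)
from gutevol.simulate import PlantedVariant

from conftest import make_record, safe_positions


@pytest.fixture(scope="module")
def is_sim(genome15):
    """One IS5 planted at 0.65, sequenced at 300x."""
    g = genome15
    pos = safe_positions(g, 1, start=6000)[0]
    pop, truth = plant_variants(
        g, [PlantedVariant("is_insertion", pos, 0.65, element="IS5")],
        seed=30)
    pairs = simulate_reads(pop, coverage=300, seed=31)
    records = sort_records(Aligner(g).align_pairs(qc_pairs(pairs)))
    return {"genome": g, "site": pos, "records": records}


@pytest.fixture(scope="module")
def clean_sim(genome15):
    """Variant-free control at the same depth."""
    pairs = simulate_reads([(genome15.sequence, 1.0)], coverage=300, seed=32)
    return sort_records(Aligner(genome15).align_pairs(qc_pairs(pairs)))


class TestDetectSplit:
    def test_planted_element_clusters_at_junction(self, is_sim):
        cands = detect_split(is_sim["records"], is_sim["genome"].is_library)
        top = max(cands, key=lambda c: c.support)
        assert top.element == "IS5"
        assert abs(top.site - is_sim["site"]) <= 5
        assert top.support >= 20

    def test_no_candidates_without_elements(self, genome15, clean_sim):
        assert detect_split(clean_sim, genome15.is_library) == []

    def test_two_nearby_elements_stay_separate(self, genome15):
        g = genome15
        base = safe_positions(g, 1, start=3000)[0]
        pop, _ = plant_variants(
            g, [PlantedVariant("is_insertion", base, 0.5, element="IS1"),
                PlantedVariant("is_insertion", base + 30, 0.5,
                               element="IS2")], seed=33)
        pairs = simulate_reads(pop, coverage=120, seed=34)
        recs = sort_records(Aligner(g).align_pairs(qc_pairs(pairs)))
        cands = detect_split(recs, g.is_library)
        sites = {c.element: c.site for c in cands if c.support >= 5}
        # junction bases where element ends coincide with the reference are
        # genuinely ambiguous by a few bp; the clusters must stay separate
        assert abs(sites["IS1"] - base) <= 10
        assert abs(sites["IS2"] - (base + 30)) <= 10
        assert sites["IS1"] != sites["IS2"]

    def test_empty_library_raises(self, clean_sim):
        with pytest.raises(ValueError):
            detect_split(clean_sim, [])


class TestDetectDiscordant:
    def test_candidate_near_truth(self, is_sim):
        cands = detect_discordant(is_sim["records"],
                                  is_sim["genome"].is_library)
        top = max(cands, key=lambda c: c.support)
        assert top.element == "IS5"
        assert abs(top.site - is_sim["site"]) <= 500 + 3 * 60

    def test_clean_control_empty(self, genome15, clean_sim):
        assert detect_discordant(clean_sim, genome15.is_library) == []

    def test_low_support_flagged(self, genome15):
        g = genome15
        pos = safe_positions(g, 1, start=9000)[0]
        pop, _ = plant_variants(
            g, [PlantedVariant("is_insertion", pos, 0.05, element="IS3")],
            seed=35)
        pairs = simulate_reads(pop, coverage=150, seed=36)
        recs = sort_records(Aligner(g).align_pairs(qc_pairs(pairs)))
        cands = [c for c in detect_discordant(recs, g.is_library)
                 if c.element == "IS3"]
        if cands:  # expectation ~2 pairs; when seen, it must be flagged
            assert all(c.low_support or c.support >= 3 for c in cands)


class TestAssembleJunction:
    def test_clean_junction_confirmed_exactly(self, is_sim):
        cand = max(detect_split(is_sim["records"],
                                is_sim["genome"].is_library),
                   key=lambda c: c.support)
        verdict = assemble_junction(is_sim["records"], cand,
                                    is_sim["genome"],
                                    is_sim["genome"].is_library)
        assert verdict.status == "confirms"
        assert verdict.site == is_sim["site"]

    def test_insufficient_with_one_read(self, genome15):
        g = genome15
        elem = dict(g.is_library)["IS5"]
        bases = g.fetch(4000, 4099) + elem[:100]
        rec = make_record(g, 4000, bases,
                          ops=[("match", 100), ("clip", 100)])
        cand = ISCandidate("split_read", "IS5", 4099, 1)
        verdict = assemble_junction([rec], cand, g, g.is_library)
        assert verdict.status == "insufficient"

    def test_random_clip_noise_rejected(self, genome15):
        g = genome15
        rng = np.random.default_rng(1)
        recs = []
        for i in range(6):
            noise = "".join(rng.choice(list("ACGT"), size=60))
            bases = g.fetch(4000, 4099) + noise
            recs.append(make_record(g, 4000, bases, read_id=f"n{i}",
                                    ops=[("match", 100), ("clip", 60)]))
        cand = ISCandidate("split_read", "IS5", 4099, 6)
        verdict = assemble_junction(recs, cand, g, g.is_library)
        assert verdict.status == "rejects"


class TestVoting:
    def _junction_records(self, g, site, n_left, n_right, n_span):
        """Synthetic clipped/spanning reads at an exact junction."""
        elem = dict(g.is_library)["IS5"]
        recs = []
        for i in range(n_left):
            bases = g.fetch(site - 59, site) + elem[:40]
            recs.append(make_record(g, site - 59, bases, read_id=f"L{i}",
                                    strand="+" if i % 2 else "-",
                                    ops=[("match", 60), ("clip", 40)]))
        for i in range(n_right):
            bases = elem[-40:] + g.fetch(site + 1, site + 60)
            recs.append(make_record(g, site + 1, bases, read_id=f"R{i}",
                                    strand="+" if i % 2 else "-",
                                    ops=[("clip", 40), ("match", 60)]))
        for i in range(n_span):
            bases = g.fetch(site - 30, site + 30)
            recs.append(make_record(g, site - 30, bases, read_id=f"S{i}"))
        return sort_records(recs)

    def test_two_votes_accept_with_printed_arithmetic(self, genome15):
        g = genome15
        recs = self._junction_records(g, 5000, 65, 65, 35)
        cands = [ISCandidate("split_read", "IS5", 5000, 130),
                 ISCandidate("discordant_pair", "IS5", 4995, 40)]
        calls = vote_and_quantify(cands, recs)
        assert len(calls) == 1
        assert calls[0].frequency == pytest.approx(65 / (65 + 35))
        assert calls[0].votes == {"split_read", "discordant_pair"}

    def test_single_method_rejected(self, genome15):
        cands = [ISCandidate("split_read", "IS5", 5000, 130)]
        assert vote_and_quantify(cands, []) == []

    def test_voting_is_monotone(self, genome15):
        g = genome15
        recs = self._junction_records(g, 5000, 20, 20, 20)
        base = [ISCandidate("split_read", "IS5", 5000, 40),
                ISCandidate("discordant_pair", "IS5", 4998, 10)]
        extra = base + [ISCandidate("junction_assembly", "IS5", 5000, 1)]
        before = {(c.element, c.site) for c in vote_and_quantify(base, recs)}
        after = {(c.element, c.site) for c in vote_and_quantify(extra, recs)}
        assert before <= after

    def test_end_to_end_frequency_accuracy(self, is_sim):
        calls = find_is_insertions(is_sim["records"], is_sim["genome"])
        assert len(calls) == 1
        c = calls[0]
        assert abs(c.site - is_sim["site"]) <= 5
        sd = np.sqrt(0.65 * 0.35 / 300)
        assert abs(c.frequency - 0.65) <= 3 * sd

    def test_no_calls_on_clean_control(self, genome15, clean_sim):
        assert find_is_insertions(clean_sim, genome15) == []


class TestBreakpoints:
    def test_clip_clusters_found(self, genome15):
        g = genome15
        recs = []
        for i in range(4):
            bases = g.fetch(4000 - i, 4099 - i) + "X" * 0 + \
                revcomp(g.fetch(6000, 6039))
            recs.append(make_record(g, 4000 - i, bases, read_id=f"c{i}",
                                    ops=[("match", 100), ("clip", 40)]))
        bps = detect_breakpoints(sort_records(recs), min_reads=3)
        assert any(abs(b - 4099) <= 10 for b in bps)

    def test_below_threshold_ignored(self, genome15):
        g = genome15
        recs = [make_record(g, 4000, g.fetch(4000, 4099) + "A" * 40,
                            ops=[("match", 100), ("clip", 40)])]
        assert detect_breakpoints(recs, min_reads=3) == []


class TestRegionGain:
    def _scenario(self, genome15, fraction, seed):
        g = genome15
        donor = generate_genome(10_000, 0.5, n_is_elements=2, n_prophages=1,
                                prophage_length=2000, seed=41, name="donor")
        ph = donor.prophages[0]
        phage = donor.fetch(ph.start, ph.end)
        locus = 8000
        vs = ([PlantedVariant("prophage_gain", locus, fraction,
                              element="Nef", sequence=phage)]
              if fraction > 0 else [])
        pop, _ = plant_variants(g, vs, seed=seed)
        pairs = simulate_reads(pop, coverage=80, seed=seed + 1)
        aug = AnnotatedGenome(
            "aug", g.sequence[:locus] + phage + g.sequence[locus:])
        recs = sort_records(Aligner(aug).align_pairs(qc_pairs(pairs)))
        pil = build_pileup(recs, aug, min_mapq=0, min_baseq=0)
        region = Interval("Nef", locus + 1, locus + len(phage))
        return estimate_region_gain(pil, region)

    def test_half_lysogenized(self, genome15):
        gain = self._scenario(genome15, 0.5, seed=50)
        assert gain.frequency == pytest.approx(0.5, abs=0.05)

    def test_boundaries(self, genome15):
        assert self._scenario(genome15, 0.0, seed=52).frequency \
            == pytest.approx(0.0, abs=0.05)
        assert self._scenario(genome15, 1.0, seed=54).frequency \
            == pytest.approx(1.0, abs=0.05)

    def test_zero_flank_coverage_is_missing(self, genome15):
        g = genome15
        recs = sort_records([make_record(g, 5000, g.fetch(5000, 5099))])
        pil = build_pileup(recs, g, min_mapq=0, min_baseq=0)
        gain = estimate_region_gain(pil, Interval("r", 4990, 5110),
                                    flank=500)
        assert gain.frequency is None

    def test_region_outside_reference_raises(self, genome15):
        pil = build_pileup([], genome15)
        with pytest.raises(ValueError):
            estimate_region_gain(pil, Interval("r", 1, len(genome15) + 10))
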