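"""The two polymorphism callers, masking, cross-run consensus and
annotation — the filter thresholds here are the heart of the pipeline."""

import pytest
from scipy.stats import fisher_exact

from gutevol import (build_pileup, call_naive, call_polymode, merge_runs,
                     sort_records)
from gutevol.genome import AnnotatedGenome, Gene, Interval
from gutevol.variants import (MaskSet, VariantCall, annotate_position,
                              apply_mask, left_align_indel)

from conftest import reads_at


def pileup_with_alt(genome, pos, ref_pos_neg, alt_pos_neg, alt=None):
    """Constructed pileup: (ref+, ref-) and (alt+, alt-) quality reads."""
    ref_base = genome.fetch(pos, pos)
    if alt is None:
        alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
    recs = reads_at(genome, pos, *ref_pos_neg)
    recs += reads_at(genome, pos, *alt_pos_neg, alt=alt, start_id=1000)
    return build_pileup(sort_records(recs), genome), alt


class TestCallNaive:
    def test_balanced_support_called(self, genome15):
        p, alt = pileup_with_alt(genome15, 2000, (45, 45), (5, 5))
        calls = call_naive(p)
        assert len(calls) == 1
        c = calls[0]
        assert (c.position, c.alt, c.type) == (2000, alt, "snp")
        assert c.frequency == pytest.approx(0.10)
        assert c.support == (5, 5)

    def test_one_strand_below_minimum_rejected(self, genome15):
        p, _ = pileup_with_alt(genome15, 2000, (43, 43), (13, 1))
        assert call_naive(p) == []

    def test_fraction_rule_at_depth_400(self, genome15):
        # 10 alt reads out of 400 is 2.5% < 3%
        p, _ = pileup_with_alt(genome15, 2000, (195, 195), (5, 5))
        assert call_naive(p) == []

    def test_strand_bias_bounds_strict(self, genome15):
        p, _ = pileup_with_alt(genome15, 2000, (100, 100), (25, 5))
        assert call_naive(p) == []  # ratio exactly 5.0 is excluded
        p2, _ = pileup_with_alt(genome15, 2000, (100, 100), (24, 5))
        assert len(call_naive(p2)) == 1  # 4.8 is inside (0.2, 5.0)

    def test_frequency_equals_support_over_depth(self, genome15):
        p, _ = pileup_with_alt(genome15, 2000, (60, 60), (12, 8))
        c = call_naive(p)[0]
        assert c.frequency == pytest.approx(sum(c.support) / c.depth)


class TestCallPolymode:
    def test_coverage_floor(self, genome15):
        p, _ = pileup_with_alt(genome15, 2000, (1, 1), (1, 1))
        assert call_polymode(p) == []  # depth 4 never calls

    def test_balanced_table_called(self, genome15):
        p, alt = pileup_with_alt(genome15, 2000, (40, 40), (10, 10))
        calls = call_polymode(p)
        assert len(calls) == 1
        assert calls[0].frequency == pytest.approx(0.20)
        # oracle: the exact test on this table is exactly 1
        assert fisher_exact([[10, 10], [40, 40]])[1] == pytest.approx(1.0)

    def test_significant_strand_bias_rejected(self, genome15):
        p, _ = pileup_with_alt(genome15, 2000, (30, 50), (20, 0))
        assert call_polymode(p) == []
        assert fisher_exact([[20, 0], [30, 50]])[1] < 0.05  # oracle

    def test_frequency_floor(self, genome15):
        p, _ = pileup_with_alt(genome15, 2000, (98, 98), (2, 2))
        assert call_polymode(p) == []  # 4/200 = 2% < 5%


class TestMask:
    def test_repeat_call_removed_and_outside_kept(self):
        calls = [VariantCall("r", 150, "A", "C", "snp", 0.2, (5, 5), 50),
                 VariantCall("r", 900, "A", "C", "snp", 0.2, (5, 5), 50)]
        mask = MaskSet([Interval("rep", 100, 200)])
        kept = apply_mask(calls, mask)
        assert [c.position for c in kept] == [900]

    def test_empty_mask_is_identity(self):
        calls = [VariantCall("r", 5, "A", "C", "snp", 0.2, (5, 5), 50)]
        assert apply_mask(calls, MaskSet([])) == calls

    def test_breakpoint_padding(self):
        bare = AnnotatedGenome("t", "A" * 10_000)
        mask = MaskSet.from_genome(bare, junctions=[5000], pad=10)
        assert 4990 in mask and 5010 in mask
        assert 4989 not in mask and 5011 not in mask

    def test_bed_round_trip(self, genome15, tmp_path):
        mask = MaskSet.from_genome(genome15, junctions=[5000])
        mask.to_bed(tmp_path / "m.bed", genome15.name)
        back = MaskSet.from_bed(tmp_path / "m.bed")
        assert [(i.start, i.end) for i in back.intervals] == \
            [(i.start, i.end) for i in mask.intervals]

    def test_pipeline_masks_repeat_region_calls(self, genome15, snp_sim):
        """True planted variants sit outside repeats and survive masking."""
        mask = MaskSet.from_genome(genome15)
        calls = apply_mask(call_naive(snp_sim["pileup"]), mask)
        norm = {left_align_indel(c.position, c.type, c.alt, genome15)[0]
                if c.type != "snp" else c.position for c in calls}
        for v in snp_sim["variants"]:
            if v.kind == "snp":
                assert v.position in norm
            elif v.kind == "insertion":
                assert left_align_indel(v.position, "insertion",
                                        v.alt_allele, genome15)[0] in norm
            else:
                assert left_align_indel(v.position, "deletion",
                                        str(v.length), genome15)[0] in norm


def _vc(run, pos, freq, vtype="snp", ref="A", alt="C"):
    n = max(1, int(freq * 100))
    return VariantCall(run, pos, ref, alt, vtype, freq,
                       (n // 2 + n % 2, n // 2), 100)


class TestMergeRuns:
    def test_present_in_all_runs(self):
        runs = [[_vc(f"run{i}", 10, 0.10)] for i in range(3)]
        out = merge_runs(runs)
        assert len(out) == 1
        assert out[0].mean_frequency == pytest.approx(0.10)
        assert out[0].n_supporting_runs == 3

    def test_single_run_dropped(self):
        runs = [[_vc("a", 10, 0.90)], [], []]
        assert merge_runs(runs) == []

    def test_absent_run_counts_as_zero(self):
        runs = [[_vc("a", 10, 0.06)], [_vc("b", 10, 0.07)], []]
        assert merge_runs(runs) == []  # (0.06+0.07+0)/3 = 0.043 < 0.05
        out = merge_runs(runs, mean_over="detected")
        assert len(out) == 1  # 0.065 under the divide-by-detected reading
        assert out[0].mean_frequency == pytest.approx(0.065)

    def test_symmetric_in_run_order(self):
        runs = [[_vc("a", 10, 0.2)], [_vc("b", 10, 0.4)], [_vc("c", 10, 0.3)]]
        fwd = merge_runs(runs)
        rev = merge_runs(runs[::-1])
        assert fwd[0].mean_frequency == pytest.approx(rev[0].mean_frequency)
        assert fwd[0].mean_frequency == pytest.approx((0.2 + 0.4 + 0.3) / 3)

    def test_fewer_than_two_runs_raises(self):
        with pytest.raises(ValueError):
            merge_runs([[_vc("a", 10, 0.2)]])

    def test_indels_matched_after_left_alignment(self, genome15):
        g = genome15
        # place the same deletion at two equivalent offsets of a homopolymer
        seq = g.sequence
        run = seq.find("AA")
        pos = run + 1  # 1-based first A
        a = [_vc("a", pos, 0.2, vtype="deletion", alt="1")]
        b = [_vc("b", pos + 1, 0.2, vtype="deletion", alt="1")]
        out = merge_runs([a, b, []], genome=g)
        assert len(out) == 1
        assert out[0].position == left_align_indel(pos, "deletion", "1", g)[0]


class TestLeftAlign:
    def test_deletion_in_homopolymer(self):
        g = AnnotatedGenome("t", "CCAAAAGG")
        # deleting any single A normalizes to the first A (position 3)
        for p in (3, 4, 5, 6):
            assert left_align_indel(p, "deletion", "1", g)[0] == 3

    def test_insertion_rotates_with_reference(self):
        g = AnnotatedGenome("t", "CCAAAAGG")
        pos, ins = left_align_indel(6, "insertion", "A", g)
        assert (pos, ins) == (2, "A")

    def test_non_repetitive_context_unchanged(self):
        g = AnnotatedGenome("t", "ACGTACGT")
        assert left_align_indel(4, "deletion", "1", g) == (4, "1")


@pytest.fixture(scope="module")
def toy():
    #        1-12: fwd gene        21-32: rev gene
    # fwd codons: ATG CGT GGA TAA
    seq = "ATGCGTGGATAACCCCCCCCTTATCCACGCATAGCCCC"
    fwd = Gene("fwdA", 1, 12, "+")
    rev = Gene("revB", 21, 32, "-")
    return AnnotatedGenome("toy", seq, genes=[fwd, rev])


class TestAnnotate:

    def test_missense_forward(self, toy):
        # codon 2 CGT (R); C->T at its first base gives TGT (C)
        gene, eff = annotate_position(toy, 4, "snp", "T")
        assert (gene, eff) == ("fwdA", "R → C")

    def test_synonymous_third_position(self, toy):
        # codon 3 GGA (G); A->G gives GGG (G)
        gene, eff = annotate_position(toy, 9, "snp", "G")
        assert (gene, eff) == ("fwdA", "Synonymous")

    def test_reverse_strand_codon(self, toy):
        # rev gene 21..32 reads ATG CGT GGA TAA on the minus strand;
        # genomic position 29 is codon 2 base 1 (C of CGT): G->A on the
        # genome is C->T on the gene -> TGT (R -> C)
        gene, eff = annotate_position(toy, 29, "snp", "A")
        assert (gene, eff) == ("revB", "R → C")

    def test_frameshift_and_inframe(self, toy):
        assert annotate_position(toy, 5, "deletion", length=10)[1] == \
            "Frameshift"
        assert annotate_position(toy, 4, "deletion", length=3)[1] == \
            "Codons deleted"
        assert annotate_position(toy, 4, "insertion", alt="TCGAGG")[1] == \
            "Codon insertion"

    def test_gene_interrupted_by_is(self, toy):
        assert annotate_position(toy, 6, "is_insertion")[1] == \
            "Gene interrupted"

    def test_intergenic_flank_arrows(self, toy):
        gene, eff = annotate_position(toy, 16, "snp", "A")
        assert eff == "Intergenic"
        assert gene == "fwdA→/revB←"

    def test_outside_genome_raises(self, toy):
        with pytest.raises(ValueError):
            annotate_position(toy, 999, "snp", "A")

    def test_pure_function(self, toy):
        a = annotate_position(toy, 4, "snp", "T")
        b = annotate_position(toy, 4, "snp", "T")
        assert a == b


class TestVcf:
    def test_write_and_read_back(self, genome15, tmp_path):
        import pysam

        from gutevol.variants import ConsensusVariant, write_vcf

        vs = [ConsensusVariant(2000, genome15.fetch(2000, 2000), "T", "snp",
                               {"a": 0.1, "b": 0.12, "c": 0.0}, 0.0733, 2),
              ConsensusVariant(3000, genome15.fetch(3000, 3000), "2",
                               "deletion", {"a": 0.3, "b": 0.3, "c": 0.3},
                               0.3, 3)]
        path = tmp_path / "out.vcf"
        write_vcf(vs, genome15, path)
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == 2
        assert recs[0].pos == 2000
        assert recs[0].info["AF"] == pytest.approx(0.0733, abs=1e-4)
        assert recs[0].info["NRUNS"] == 2
        assert recs[1].pos == 2999  # deletion anchored one base left
        assert len(recs[1].ref) == 3
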