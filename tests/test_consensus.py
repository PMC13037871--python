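"""Damage classification, masking/trimming, contamination gating, and the
depth/agreement consensus rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomt.consensus import (
    AlignedFragment,
    ConsensusPolicy,
    ContaminationEstimate,
    UnprocessableSampleError,
    call_consensus,
    classify_deaminated,
    contamination_gate,
    dedup_fragments,
    mask_and_trim,
    process_sample,
    read_sam,
)
from paleomt.simulate import DamageProfile, fragment_and_damage, random_genome


def frag(bases, start=1, quals=None, mismatches=(), strand="+", ref_length=100, rid="r"):
    quals = np.full(len(bases), 40) if quals is None else np.asarray(quals)
    return AlignedFragment(
        read_id=rid, start=start, strand=strand, bases=bases,
        quals=quals, mismatches=list(mismatches), ref_length=ref_length,
    )


class TestClassifyDeaminated:
    def test_ct_at_first_position(self):
        f = frag("TAAAAA", start=10, mismatches=[(10, "C", "T")])
        assert classify_deaminated(f, window=3)

    def test_ga_at_last_position_counts(self):
        f = frag("AAAAAA" + "A", start=10, mismatches=[(16, "G", "A")])
        assert classify_deaminated(f, window=3)

    def test_no_mismatch_is_false(self):
        assert not classify_deaminated(frag("ACGTAC"), window=3)

    def test_interior_damage_outside_window(self):
        # only C->T at position 5 from both ends of a 9-bp read
        f = frag("AAAATAAAA", start=1, mismatches=[(5, "C", "T")])
        assert not classify_deaminated(f, window=3)

    def test_non_damage_mismatch_ignored(self):
        f = frag("GAAAAA", start=1, mismatches=[(1, "C", "G")])
        assert not classify_deaminated(f, window=3)


class TestMaskAndTrim:
    def test_high_quality_fragment_unchanged(self):
        f = frag("ACGTACGT")
        out = mask_and_trim(f)
        assert out.bases == f.bases and out.start == f.start

    def test_exactly_three_low_quality_bases_trimmed(self):
        f = frag("ACGTACGT", quals=[5, 5, 5, 40, 40, 40, 40, 40], start=7)
        out = mask_and_trim(f)
        assert out.bases == "TACGT"
        assert out.start == 10

    def test_fourth_low_quality_base_retained(self):
        f = frag("ACGTACGT", quals=[5, 5, 5, 5, 40, 40, 40, 40])
        out = mask_and_trim(f)
        assert out.bases == "TACGT"  # trim capped at 3; 4th low-q base kept
        assert out.quals[0] == 5

    def test_damage_positions_masked_to_zero_quality(self):
        f = frag("ACGTTCGT", start=1, mismatches=[(5, "C", "T")])
        out = mask_and_trim(f)
        assert out.quals[4] == 0
        assert out.bases == f.bases  # interior, not trimmed

    def test_trims_both_ends_independently(self):
        f = frag("ACGTAC", quals=[5, 40, 40, 40, 5, 5])
        out = mask_and_trim(f)
        assert out.bases == "CGT"
        assert out.start == 2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(quals=st.lists(st.integers(0, 45), min_size=1, max_size=30))
    def test_trim_invariants_for_any_quality_profile(self, quals):
        """At most 3 bases leave each end, the kept window is contiguous,
        and interior qualities are untouched."""
        f = frag("A" * len(quals), quals=quals)
        out = mask_and_trim(f)
        left = out.start - f.start
        assert 0 <= left <= 3
        assert 0 <= len(f) - len(out) - left <= 3
        assert list(out.quals) == quals[left : left + len(out)]


class TestContaminationGate:
    def make(self, n_deam, n_clean):
        frags = [
            frag("TAAA", start=1, mismatches=[(1, "C", "T")], rid=f"d{i}")
            for i in range(n_deam)
        ]
        frags += [frag("AAAA", start=1, rid=f"c{i}") for i in range(n_clean)]
        return frags

    def test_low_contamination_keeps_all(self):
        decision, kept = contamination_gate(
            ContaminationEstimate(0.02), self.make(3, 7)
        )
        assert decision == "all_reads" and len(kept) == 10

    def test_high_contamination_keeps_deaminated_only(self):
        decision, kept = contamination_gate(
            ContaminationEstimate(0.25), self.make(30, 70)
        )
        assert decision == "deaminated_only" and len(kept) == 30

    def test_boundary_ten_percent_is_all_reads(self):
        decision, _ = contamination_gate(ContaminationEstimate(0.10), self.make(1, 9))
        assert decision == "all_reads"  # "above 10%" is strict

    def test_empty_after_gate_is_unprocessable(self):
        with pytest.raises(UnprocessableSampleError):
            contamination_gate(ContaminationEstimate(0.5), self.make(0, 5))


class TestCallConsensus:
    def test_three_agreeing_fragments_call_base(self):
        frags = [frag("A", start=5, rid=f"r{i}", strand=s)
                 for i, s in enumerate("++-")]
        cons = call_consensus(frags, ref_length=10, deduplicate=False)
        assert cons.calls[4] == "A"
        assert cons.calls.count("N") == 9

    def test_depth_two_gives_n(self):
        frags = [frag("A", start=5, rid=f"r{i}") for i in range(2)]
        cons = call_consensus(frags, ref_length=10, deduplicate=False)
        assert cons.calls[4] == "N"

    def test_agreement_threshold_arithmetic(self):
        frags = [frag("A", start=1, rid=f"a{i}") for i in range(6)]
        frags += [frag("G", start=1, rid=f"g{i}") for i in range(4)]
        cons = call_consensus(frags, ref_length=4, deduplicate=False)
        assert cons.calls[0] == "N"  # 0.60 < 0.65
        frags = [frag("A", start=1, rid=f"a{i}") for i in range(7)]
        frags += [frag("G", start=1, rid=f"g{i}") for i in range(3)]
        cons = call_consensus(frags, ref_length=4, deduplicate=False)
        assert cons.calls[0] == "A"  # 0.70 >= 0.65

    def test_exact_threshold_is_inclusive(self):
        frags = [frag("A", start=1, rid=f"a{i}") for i in range(13)]
        frags += [frag("G", start=1, rid=f"g{i}") for i in range(7)]
        cons = call_consensus(frags, ref_length=2, deduplicate=False)
        assert cons.calls[0] == "A"  # 13/20 == 0.65 exactly

    def test_zero_quality_bases_excluded_from_evidence(self):
        frags = [frag("A", start=1, rid=f"a{i}") for i in range(3)]
        frags.append(frag("G", start=1, quals=[0], rid="masked"))
        cons = call_consensus(frags, ref_length=2, deduplicate=False)
        assert cons.calls[0] == "A"
        assert cons.depth[0] == 3

    def test_empty_input_gives_all_n(self):
        cons = call_consensus([], ref_length=8)
        assert cons.calls == "N" * 8
        assert cons.completeness == 0.0

    def test_duplicates_counted_once(self):
        frags = [frag("A", start=3, rid=f"dup{i}") for i in range(5)]
        assert len(dedup_fragments(frags)) == 1
        cons = call_consensus(frags, ref_length=5)
        assert cons.calls[2] == "N"  # one independent fragment only

    def test_circular_wraparound_positions(self):
        frags = [frag("ACG", start=9, rid=f"r{i}", ref_length=10) for i in "xyz"]
        cons = call_consensus(frags, ref_length=10, deduplicate=False)
        assert cons.calls[8] == "A" and cons.calls[9] == "C" and cons.calls[0] == "G"

    def test_adding_supporting_fragment_never_uncalls(self, ):
        rng = np.random.default_rng(0)
        from conftest import random_pileup

        for _ in range(20):
            frags = random_pileup(rng, ref_length=40)
            cons = call_consensus(frags, ref_length=40, deduplicate=False)
            called = [i for i, b in enumerate(cons.calls) if b != "N"]
            if not called:
                continue
            i = called[0]
            extra = frag(cons.calls[i], start=i + 1, rid="extra", ref_length=40)
            cons2 = call_consensus(frags + [extra], ref_length=40, deduplicate=False)
            assert cons2.calls[i] == cons.calls[i]


class TestEndToEndRecovery:
    def test_masking_eliminates_damage_errors(self):
        genome = random_genome(3_000, seed=1)
        res = fragment_and_damage(
            genome, DamageProfile(p_ct_5p=0.3, coverage=20), seed=2
        )
        cons, qc = process_sample(
            res.fragments, ContaminationEstimate(0.0), ref_length=len(genome)
        )
        called = [(c, t) for c, t in zip(cons.calls, genome) if c != "N"]
        errors = sum(c != t for c, t in called)
        damage_errors = sum(
            (t, c) in {("C", "T"), ("G", "A")} for c, t in called if c != t
        )
        assert damage_errors == 0
        assert errors / len(called) <= 0.001
        assert qc["gate_decision"] == "all_reads"

    def test_contaminated_sample_uses_deaminated_only_path(self):
        genome = random_genome(2_000, seed=3)
        from paleomt.simulate import mutated_copy

        contam = mutated_copy(genome, 40, seed=4)
        res = fragment_and_damage(
            genome,
            DamageProfile(p_ct_5p=0.4, coverage=30, contamination_frac=0.3),
            contam,
            seed=5,
        )
        cons, qc = process_sample(
            res.fragments, ContaminationEstimate(0.30), ref_length=len(genome)
        )
        assert qc["gate_decision"] == "deaminated_only"
        called = [(c, t) for c, t in zip(cons.calls, genome) if c != "N"]
        assert sum(c != t for c, t in called) / max(len(called), 1) <= 0.002


class TestSamReader:
    def test_reads_plain_sam_and_recomputes_mismatches(self, tmp_path):
        ref = "ACGTACGTAC"
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:ref\tLN:10\n"
            "r1\t0\tref\t1\t60\t4M\t*\t0\t0\tACTT\tIIII\n"
            "r2\t16\tref\t3\t60\t4M\t*\t0\t0\tGTAC\tIIII\n"
            "r3\t4\tref\t0\t0\t*\t*\t0\t0\tAAAA\tIIII\n"
        )
        frags = read_sam(str(sam), ref)
        assert [f.read_id for f in frags] == ["r1", "r2"]
        assert frags[0].mismatches == [(3, "G", "T")]
        assert frags[1].strand == "-"
        assert frags[1].mismatches == []
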