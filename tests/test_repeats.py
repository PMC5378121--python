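"""Repeat-pair detection, significance lengths, coverage, and MUMs."""

import numpy as np
import pytest

from synterate import (
    Mum,
    RepeatPair,
    find_exact_repeats,
    find_mums,
    repeat_coverage,
    significant_repeat_length,
)

from .oracles import (
    brute_force_direct_repeats,
    brute_force_inverted_repeats,
    brute_force_mums,
    revcomp,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSignificantRepeatLength:
    def test_monotone_in_p(self):
        l_strict = significant_repeat_length(3_000_000, 0.5, 0.001)
        l_loose = significant_repeat_length(3_000_000, 0.5, 0.01)
        assert l_strict >= l_loose

    def test_monotone_in_genome_length(self):
        assert significant_repeat_length(10_000_000, 0.5) >= \
            significant_repeat_length(1_000_000, 0.5)

    def test_reference_value(self):
        # expected count (1-E)/2 n^2 E^l at n=3e6, gc=0.5 crosses 0.001
        # between l=25 and l=26
        assert significant_repeat_length(3_000_000, 0.5, 0.001) == 26

    def test_study_scale_lengths_match_meps_range(self):
        """At bacterial genome sizes and GC contents the threshold sits
        in the low-to-high 20s of bp (the MEPS scale, reported 23-29)."""
        lengths = [significant_repeat_length(n, gc)
                   for n in (2_000_000, 3_000_000, 5_000_000, 10_000_000)
                   for gc in (0.4, 0.5, 0.67)]
        assert all(23 - 3 <= l <= 29 + 3 for l in lengths)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            significant_repeat_length(100, 0.5)
        with pytest.raises(ValueError):
            significant_repeat_length(10_000, 1.5)


class TestFindExactRepeats:
    def test_random_sequence_has_no_long_repeats(self, rng):
        seq = random_seq(rng, 10_000)
        assert find_exact_repeats(seq, min_length=100) == []

    def test_tandem_example(self):
        reps = find_exact_repeats("ACGTACGT", min_length=4,
                                  include_inverted=False)
        assert reps == [RepeatPair(0, 4, 4, "direct")]

    def test_planted_inverted_repeat_exact_coordinates(self, rng):
        seq = list(random_seq(rng, 5_000))
        unit = random_seq(rng, 200)
        seq[1000:1200] = list(unit)
        seq[3000:3200] = list(revcomp(unit))
        reps = [r for r in find_exact_repeats("".join(seq), min_length=100)
                if r.orientation == "inverted"]
        assert len(reps) == 1
        rep = reps[0]
        assert rep.pos1 <= 1000 and rep.pos1 + rep.length >= 1200
        assert rep.pos2 <= 3000 and rep.pos2 + rep.length >= 3200
        assert rep.length < 220  # only chance flanking extension

    def test_every_reported_pair_verifies_by_substring_comparison(self, rng):
        seq = random_seq(rng, 1_500) + random_seq(rng, 50) * 3
        for rep in find_exact_repeats(seq, min_length=12):
            c1 = seq[rep.pos1:rep.pos1 + rep.length]
            c2 = seq[rep.pos2:rep.pos2 + rep.length]
            assert c1 == (c2 if rep.orientation == "direct" else revcomp(c2))

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        """Seed-and-extend matches exhaustive enumeration of maximal
        direct and inverted pairs on short random sequences."""
        for trial in range(30):
            base = random_seq(rng, 160)
            # guarantee some repeats by echoing a chunk
            seq = base + base[40:70] + revcomp(base[100:126])
            got = find_exact_repeats(seq, min_length=12)
            got_direct = {(r.pos1, r.pos2, r.length) for r in got
                          if r.orientation == "direct"}
            got_inv = {(r.pos1, r.pos2, r.length) for r in got
                       if r.orientation == "inverted"}
            assert got_direct == brute_force_direct_repeats(seq, 12)
            assert got_inv == brute_force_inverted_repeats(seq, 12)

    def test_p_threshold_routes_through_significance_length(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 2_000)
        with pytest.raises(ValueError):
            find_exact_repeats(seq, min_length=10, p_threshold=0.001)
        with pytest.raises(ValueError):
            find_exact_repeats(seq)


class TestRepeatCoverage:
    def test_no_repeats(self):
        assert repeat_coverage(1_000, []) == 0.0

    def test_whole_genome_tandem(self):
        rep = RepeatPair(0, 500, 500, "direct")
        assert repeat_coverage(1_000, [rep]) == 100.0

    def test_overlapping_intervals_merge(self):
        reps = [RepeatPair(0, 50, 100, "direct")]
        # copies [0,100) and [50,150) merge into [0,150) = 15%
        assert repeat_coverage(1_000, reps) == pytest.approx(15.0)

    def test_invariant_to_order_and_duplication(self, rng):
        reps = [RepeatPair(10, 300, 50, "direct"),
                RepeatPair(100, 700, 80, "inverted")]
        base = repeat_coverage(1_000, reps)
        assert repeat_coverage(1_000, reps[::-1]) == base
        assert repeat_coverage(1_000, reps + reps) == base

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            repeat_coverage(100, [RepeatPair(0, 60, 50, "direct")])


class TestFindMums:
    def test_identical_sequences_single_full_mum(self, rng):
        seq = random_seq(rng, 800)
        mums = find_mums(seq, seq, min_length=20)
        assert mums == [Mum(0, 0, 800, "forward")]

    def test_reverse_complement_query(self, rng):
        seq = random_seq(rng, 600)
        mums = find_mums(seq, revcomp(seq), min_length=20)
        assert len(mums) == 1
        m = mums[0]
        assert (m.ref_pos, m.qry_pos, m.length, m.strand) == \
            (0, 0, 600, "reverse")

    def test_planted_shared_block(self, rng):
        ref = random_seq(rng, 1_000)
        qry = random_seq(rng, 1_000)
        block = ref[200:240]
        qry = qry[:500] + block + qry[540:]
        mums = find_mums(ref, qry, min_length=40)
        assert any(m.ref_pos <= 200 and m.qry_pos <= 500 and m.length >= 40
                   for m in mums)

    def test_agrees_with_quadratic_oracle(self, rng):
        for trial in range(50):
            ref = random_seq(rng, 200)
            qry = random_seq(rng, 200)
            # plant a forward and a reverse shared block in half the trials
            if trial % 2 == 0:
                qry = qry[:60] + ref[20:45] + qry[85:]
                qry = qry[:150] + revcomp(ref[100:122]) + qry[172:]
            got = {(m.ref_pos, m.qry_pos, m.length, m.strand)
                   for m in find_mums(ref, qry, min_length=12)}
            assert got == brute_force_mums(ref, qry, 12)

    def test_symmetric_up_to_coordinate_swap(self, rng):
        ref = random_seq(rng, 300)
        qry = ref[:150] + random_seq(rng, 150)
        fwd = {(m.ref_pos, m.qry_pos, m.length) for m in
               find_mums(ref, qry, min_length=15) if m.strand == "forward"}
        rev = {(m.qry_pos, m.ref_pos, m.length) for m in
               find_mums(qry, ref, min_length=15) if m.strand == "forward"}
        assert fwd == rev

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_mums("", "ACGT", min_length=2)
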