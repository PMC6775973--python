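from collections import Counter

import numpy as np
import pytest

from cobascan import synthetic as sy
from cobascan import termini
from cobascan.records import AlignmentRecord, AnnotatedGenome, reverse_complement


def _random_seq(rng, n, gc=0.47):
    return "".join(rng.choice(list("ACGT"), n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))


class TestFindTerminalRepeat:
    def test_planted_exact_repeat(self, genome40):
        dtr = termini.find_terminal_repeat(genome40)
        assert dtr is not None
        assert (dtr.length, dtr.mismatches) == (170, 0)
        assert dtr.five_prime_interval == (0, 170)
        assert dtr.three_prime_interval == (len(genome40) - 170, len(genome40))
        assert dtr.seq == genome40.sequence[:170]

    def test_random_sequence_has_no_repeat(self):
        rng = np.random.default_rng(0)
        assert termini.find_terminal_repeat(_random_seq(rng, 10_000)) is None

    def test_repeat_with_two_substitutions_found(self):
        rng = np.random.default_rng(1)
        repeat = _random_seq(rng, 170)
        core = _random_seq(rng, 9000)
        mutated = list(repeat)
        mutated[40] = "A" if mutated[40] != "A" else "C"
        mutated[120] = "A" if mutated[120] != "A" else "C"
        seq = repeat + core + "".join(mutated)
        dtr = termini.find_terminal_repeat(seq)
        assert dtr is not None
        assert (dtr.length, dtr.mismatches) == (170, 2)

    def test_invariant_under_reverse_complement(self, genome40):
        fwd = termini.find_terminal_repeat(genome40)
        rev = termini.find_terminal_repeat(reverse_complement(genome40.sequence))
        assert rev is not None and rev.length == fwd.length

    def test_inverted_repeat_variant(self):
        rng = np.random.default_rng(2)
        repeat = _random_seq(rng, 200)
        seq = repeat + _random_seq(rng, 8000) + reverse_complement(repeat)
        assert termini.find_terminal_repeat(seq) is None
        inv = termini.find_terminal_repeat(seq, inverted=True)
        # a few random rungs beyond the plant may stay within tolerance
        assert inv is not None and inv.inverted
        assert 200 <= inv.length <= 220
        assert inv.mismatches <= 0.02 * inv.length

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            termini.find_terminal_repeat("ACGT" * 10, min_len=30)


class TestLocateDTRByReference:
    def test_exact_internal_hit(self, genome40):
        rng = np.random.default_rng(3)
        dtr = genome40.sequence[:170]
        target = _random_seq(rng, 5000) + dtr + _random_seq(rng, 5000)
        hits = termini.locate_dtr_by_reference(target, dtr)
        assert len(hits) == 1
        (interval, identity) = hits[0]
        assert interval == (5000, 5170)
        assert identity == 1.0

    def test_diverged_hit_identity(self, genome40):
        dtr = genome40.sequence[:170]
        div = sy.diverge_genome(AnnotatedGenome(id="d", sequence=dtr), 0.20, seed=4)
        hamming_identity = np.mean(
            [a == b for a, b in zip(dtr, div.sequence)]
        )
        rng = np.random.default_rng(5)
        target = _random_seq(rng, 3000) + div.sequence + _random_seq(rng, 3000)
        hits = termini.locate_dtr_by_reference(target, dtr, min_identity=0.70)
        assert len(hits) == 1
        # edlib may shave an edit or two with indels; identity tracks Hamming
        assert hits[0][1] == pytest.approx(hamming_identity, abs=0.02)
        assert hits[0][1] >= 0.70

    def test_unrelated_target_empty(self):
        rng = np.random.default_rng(6)
        assert termini.locate_dtr_by_reference(
            _random_seq(rng, 10_000), _random_seq(rng, 170)
        ) == []

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            termini.locate_dtr_by_reference("ACGT" * 100, "ACGTACGT")


def _circular_kmers(seq, k=21):
    wrapped = seq + seq[:k - 1]
    return Counter(wrapped[i:i + k] for i in range(len(seq)))


class TestReorientToDTR:
    def test_already_oriented_is_identity(self, genome40):
        out = termini.reorient_to_dtr(genome40, (0, 170))
        assert out.sequence == genome40.sequence
        assert out.provenance["rotation"] == 0

    def test_rotation_round_trip(self, genome40):
        d = 170
        circ = genome40.sequence[:-d]
        rot = circ[10_000:] + circ[:10_000]
        hits = termini.locate_dtr_by_reference(rot, genome40.sequence[:d])
        assert hits
        out = termini.reorient_to_dtr(AnnotatedGenome(id="r", sequence=rot), hits[0][0])
        assert out.sequence == genome40.sequence

    def test_rotation_splitting_the_repeat_still_recovered(self, genome40):
        # the rotation cut may fall inside the repeat; circular search wraps
        d = 170
        circ = genome40.sequence[:-d]
        cut = 80  # inside the 5' repeat copy
        rot = circ[cut:] + circ[:cut]
        assert termini.locate_dtr_by_reference(rot, genome40.sequence[:d]) == []
        hits = termini.locate_dtr_by_reference(
            rot, genome40.sequence[:d], circular=True
        )
        assert len(hits) == 1
        out = termini.reorient_to_dtr(AnnotatedGenome(id="r", sequence=rot), hits[0][0])
        assert out.sequence == genome40.sequence

    def test_circular_kmer_multiset_invariant(self, genome40):
        d = 170
        circ = genome40.sequence[:-d]
        rot = circ[5_000:] + circ[:5_000]
        out = termini.reorient_to_dtr(AnnotatedGenome(id="r", sequence=rot), (0, 100))
        stripped = out.sequence[:-100]  # drop the appended repeat copy
        assert _circular_kmers(stripped) == _circular_kmers(rot)

    def test_out_of_bounds_interval(self, genome40):
        with pytest.raises(ValueError):
            termini.reorient_to_dtr(genome40, (0, len(genome40) + 1))


class TestTerminiFromAlignments:
    @staticmethod
    def _alignments(starts, genome_id="g", m=100):
        return [
            AlignmentRecord(
                read_id=f"r{i}", genome_id=genome_id, ref_start=int(s),
                ref_end=int(s) + m, strand="+", matches=m, mismatches=0,
                insertions=0, deletions=0,
            )
            for i, s in enumerate(starts)
        ]

    def test_left_clipped_starts_pile_at_zero(self, small_genome):
        # fragments whose physical start precedes the terminus clip to 0
        rng = np.random.default_rng(0)
        raw = rng.integers(-99, len(small_genome) - 100, size=2000)
        starts = np.clip(raw, 0, None)
        ev = termini.termini_from_alignments(small_genome, self._alignments(starts))
        assert any(e.position == 0 for e in ev)
        assert max(e.zscore for e in ev if e.position == 0) >= 6

    def test_uniform_circular_starts_give_no_evidence(self, small_genome):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, len(small_genome) - 100, size=2000)
        ev = termini.termini_from_alignments(small_genome, self._alignments(starts))
        assert ev == []

    def test_too_few_alignments_error(self, small_genome):
        with pytest.raises(ValueError, match="100"):
            termini.termini_from_alignments(small_genome, self._alignments(range(50)))


class TestDtrGcProfile:
    def test_all_gc_profile_is_one(self):
        dtrs = [
            termini.DTRRecord("g", 100, "GC" * 50, 0, (0, 100), (900, 1000))
            for _ in range(3)
        ]
        profile, _ = termini.dtr_gc_profile(dtrs)
        assert np.allclose(profile, 1.0)

    def test_gc_rich_five_prime_argmax_near_start(self):
        rng = np.random.default_rng(7)
        dtrs = []
        for i in range(10):
            head = _random_seq(rng, 30, gc=0.80)
            tail = _random_seq(rng, 140, gc=0.40)
            dtrs.append(
                termini.DTRRecord(f"g{i}", 170, head + tail, 0, (0, 170), (0, 170))
            )
        _, argmax = termini.dtr_gc_profile(dtrs, window=20)
        assert 0 <= argmax <= 10

    def test_single_dtr_equals_sliding_gc(self):
        seq = "GGGGGAAAAACCCCCTTTTTGGGGG"
        dtr = termini.DTRRecord("g", len(seq), seq, 0, (0, 25), (0, 25))
        profile, _ = termini.dtr_gc_profile([dtr], window=5)
        from cobascan.records import gc_fraction

        expect = [gc_fraction(seq[i:i + 5]) for i in range(len(seq) - 4)]
        assert np.allclose(profile, expect)

    def test_window_longer_than_dtr_rejected(self):
        dtr = termini.DTRRecord("g", 10, "ACGTACGTAC", 0, (0, 10), (0, 10))
        with pytest.raises(ValueError):
            termini.dtr_gc_profile([dtr], window=20)
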