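import edlib
import numpy as np
import pytest

from cobascan import recruitment as rec
from cobascan import synthetic as sy
from cobascan.records import AlignmentRecord, SequenceRecord, reverse_complement


def _read(seq, quals):
    return SequenceRecord(id="r", sequence=seq, qualities=quals)


class TestCleanReads:
    def test_high_quality_reads_unchanged(self):
        reads = [_read("ACGT" * 20, [37] * 80)]
        out, stats = rec.clean_reads(reads)
        assert out[0].sequence == reads[0].sequence
        assert (stats.reads_in, stats.reads_out) == (1, 1)

    def test_low_quality_ends_trimmed(self):
        reads = [_read("A" * 50, [10] * 5 + [30] * 40 + [10] * 5)]
        out, stats = rec.clean_reads(reads)
        assert len(out[0]) == 40
        assert stats.bases_out == 40

    def test_short_after_trim_dropped(self):
        reads = [_read("A" * 40, [10] * 15 + [30] * 10 + [10] * 15)]
        out, _ = rec.clean_reads(reads)
        assert out == []

    def test_low_mean_quality_dropped(self):
        reads = [_read("A" * 40, [21] + [15] * 38 + [21])]
        out, _ = rec.clean_reads(reads)
        assert out == []

    def test_missing_qualities_error(self):
        with pytest.raises(ValueError, match="qualities"):
            rec.clean_reads([SequenceRecord(id="r", sequence="ACGT")])

    def test_survivors_match_independent_recount(self, small_genome):
        """Cleaning of a 3'-decay library agrees with a per-read re-application."""
        reads, _ = sy.simulate_reads(
            small_genome, depth=3, read_length=100, seed=4,
            quality_low=8, quality_tail=30,
        )
        params = rec.CleanParams()
        out, stats = rec.clean_reads(reads, params)
        survivors = 0
        for r in reads:
            q = r.qualities
            lo, hi = 0, len(q)
            while lo < hi and q[lo] < params.end_quality:
                lo += 1
            while hi > lo and q[hi - 1] < params.end_quality:
                hi -= 1
            if hi - lo >= params.min_length and sum(q[lo:hi]) / (hi - lo) >= params.min_avg_quality:
                survivors += 1
        assert stats.reads_out == survivors == len(out)


class TestAlignmentIdentity:
    @pytest.mark.parametrize(
        "m,x,i,d,expected",
        [
            (100, 0, 0, 0, 1.0),
            (90, 10, 0, 0, 0.90),
            (95, 0, 5, 5, 95 / 105),
        ],
    )
    def test_identity_formula(self, m, x, i, d, expected):
        a = AlignmentRecord("r", "g", 0, m + x + d, "+", m, x, i, d)
        assert rec.alignment_identity(a) == pytest.approx(expected)

    def test_boundary_identity_passes_inclusive_filter(self):
        a = AlignmentRecord("r", "g", 0, 100, "+", 90, 10, 0, 0)
        profiles = rec.recruit([a], {"g": 1000}, rec.RecruitParams(min_identity=0.90))
        assert profiles["g"].aligned_bases == 100

    def test_zero_columns_error(self):
        a = AlignmentRecord("r", "g", 0, 0, "+", 0, 0, 0, 0)
        with pytest.raises(ValueError):
            rec.alignment_identity(a)


class TestAlignReads:
    def test_error_free_read_found_at_planted_locus(self, small_genome):
        start = 1234
        read = SequenceRecord("r", small_genome.sequence[start:start + 150])
        (a,) = rec.align_reads([read], [small_genome])
        assert (a.ref_start, a.ref_end, a.strand) == (start, start + 150, "+")
        assert rec.alignment_identity(a) == 1.0

    def test_reverse_complement_read_same_locus(self, small_genome):
        start = 2000
        read = SequenceRecord(
            "r", reverse_complement(small_genome.sequence[start:start + 150])
        )
        (a,) = rec.align_reads([read], [small_genome])
        assert (a.ref_start, a.strand) == (start, "-")

    def test_identities_match_full_scan_oracle(self):
        """Seeded placement reproduces an exhaustive semi-global scan."""
        g = sy.simulate_genome(sy.GenomeSpec(length=2000, dtr_length=0, seed=8))
        reads, _ = sy.simulate_reads(
            g, depth=15, read_length=100, subst_rate=0.02, seed=9
        )
        alignments = {a.read_id: a for a in rec.align_reads(reads, [g])}
        assert len(alignments) == len(reads)
        for r in reads:
            a = alignments[r.id]
            dist = a.mismatches + a.insertions + a.deletions
            best = min(
                edlib.align(s, g.sequence, mode="HW")["editDistance"]
                for s in (r.sequence, reverse_complement(r.sequence))
            )
            assert dist == best


class TestRecruitAndStats:
    def test_disjoint_reads_coverage(self):
        mk = lambda i, s: AlignmentRecord(f"r{i}", "g", s, s + 150, "+", 150, 0, 0, 0)
        profiles = rec.recruit([mk(0, 0), mk(1, 500)], {"g": 4000})
        p = profiles["g"]
        assert p.aligned_bases == 300
        assert rec.breadth(p) == 300 / 4000

    def test_identity_below_cutoff_excluded(self):
        a = AlignmentRecord("r", "g", 0, 100, "+", 89, 11, 0, 0)
        profiles = rec.recruit([a], {"g": 1000})
        assert profiles["g"].aligned_bases == 0

    def test_out_of_bounds_alignment_error(self):
        a = AlignmentRecord("r", "g", 950, 1050, "+", 100, 0, 0, 0)
        with pytest.raises(ValueError, match="outside"):
            rec.recruit([a], {"g": 1000})

    def test_breadth_occupancy_formula(self):
        rng = np.random.default_rng(0)
        L, m, R = 10_000, 100, 400
        starts = rng.integers(0, L - m, size=R)
        alns = [
            AlignmentRecord(f"r{i}", "g", int(s), int(s) + m, "+", m, 0, 0, 0)
            for i, s in enumerate(starts)
        ]
        b = rec.breadth(rec.recruit(alns, {"g": L})["g"])
        expect = 1 - (1 - m / L) ** R
        assert b == pytest.approx(expect, abs=0.02)

    @pytest.mark.parametrize("b,present", [(0.75, True), (0.7499, False), (1.0, True)])
    def test_presence_boundary(self, b, present):
        L = 10_000
        covered = int(round(b * L))
        depth = np.zeros(L)
        depth[:covered] = 1
        p = rec.CoverageProfile("g", depth, covered, 1)
        assert rec.call_presence(p) is present

    def test_abundance_formula(self):
        p = rec.CoverageProfile("g", np.ones(40_000) * 20, aligned_bases=800_000)
        assert rec.relative_abundance(p, 40_000, 10**9) == 20.0
        p0 = rec.CoverageProfile("g", np.zeros(40_000), aligned_bases=0)
        assert rec.relative_abundance(p0, 40_000, 10**9) == 0.0

    def test_abundance_halves_with_doubled_library(self):
        p = rec.CoverageProfile("g", np.ones(1000), aligned_bases=1000)
        a1 = rec.relative_abundance(p, 1000, 10**8)
        a2 = rec.relative_abundance(p, 1000, 2 * 10**8)
        assert a1 == 2 * a2

    def test_abundance_invariant_under_sample_duplication(self):
        alns = [AlignmentRecord("r", "g", 0, 150, "+", 150, 0, 0, 0)]
        single = rec.reports_from_alignments(alns, {"g": 1000}, 10_000)[0]
        doubled_alns = alns + [
            AlignmentRecord("r2", "g", 0, 150, "+", 150, 0, 0, 0)
        ]
        doubled = rec.reports_from_alignments(doubled_alns, {"g": 1000}, 20_000)[0]
        assert single.abundance_per_gb == pytest.approx(doubled.abundance_per_gb)


class TestProfileSample:
    def test_diverged_genome_presence_depends_on_cutoff(self):
        ref = sy.simulate_genome(sy.GenomeSpec(length=2000, dtr_length=0, seed=10))
        distant = sy.diverge_genome(ref, 0.15, seed=11)
        reads, _ = sy.simulate_reads(distant, depth=10, read_length=150, seed=12)
        alns = rec.align_reads(reads, {ref.id: ref.sequence}, seed_stride=1)
        strict = rec.recruit(alns, {ref.id: len(ref)}, min_identity=0.90)[ref.id]
        relaxed = rec.recruit(alns, {ref.id: len(ref)}, min_identity=0.80)[ref.id]
        assert rec.breadth(strict) < 0.75
        assert rec.breadth(relaxed) >= 0.75

    def test_full_chain_reports_per_cutoff(self, small_genome):
        reads, _ = sy.simulate_reads(small_genome, depth=5, read_length=120, seed=13)
        reports = rec.profile_sample(
            reads, [small_genome],
            recruit_params=rec.RecruitParams(0.90, 0.75, (0.95, 1.0)),
        )
        assert [r.identity_cutoff for r in reports] == [0.90, 0.95, 1.0]
        assert all(r.present for r in reports)
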