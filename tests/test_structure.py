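"""Quadripartite resolution, repeat finders, GC and coverage statistics."""

import numpy as np
import pytest

from plastokit._seq import revcomp
from plastokit.models import CircularGenome
from plastokit.structure import (NoInvertedRepeatError, RegionStats,
                                 canonicalize, coverage_stats,
                                 find_direct_repeats, find_inverted_repeats,
                                 genome_summary, mean_read_length,
                                 partition_quadripartite, region_gc,
                                 weighted_overall_gc)
from plastokit.synthetic import (generate_genome, scaled_spec,
                                 simulate_genomic_reads)


def _random_seq(rng, n, forbid_homopolymer=True):
    bases = "ACGT"
    out = []
    prev = ""
    for _ in range(n):
        choices = [b for b in bases if not (forbid_homopolymer and b == prev)]
        b = choices[int(rng.integers(0, len(choices)))]
        out.append(b)
        prev = b
    return "".join(out)


def brute_force_inverted_repeats(seq: str, min_len: int):
    """O(n^2) oracle: maximal inverted matches via anti-diagonal run scan."""
    n = len(seq)
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    cenc = comp[enc]
    pairs = set()
    for A in range(2 * n - 1):
        i_lo, i_hi = max(0, A - n + 1), min(A, n - 1)
        idx = np.arange(i_lo, i_hi + 1)
        match = enc[idx] == cenc[A - idx]
        run = 0
        for off, m in enumerate(list(match) + [False]):
            if m:
                run += 1
                continue
            if run:
                end = i_lo + off  # one past last matching i
                start = end - run
                # keep the half below the midpoint; mirror is the partner
                half_end = min(end, (A + 1) // 2)
                length = half_end - start
                if length >= min_len:
                    j0 = A - half_end + 1
                    pairs.add(tuple(sorted([(start, length), (j0, length)])))
            run = 0
    return pairs


class TestInvertedRepeats:
    def test_planted_repeat_recovered_exactly(self):
        rng = np.random.default_rng(42)
        x = _random_seq(rng, 2000)
        r = _random_seq(rng, 500)
        y = _random_seq(rng, 2000)
        seq = x + r + y + revcomp(r)
        g = CircularGenome(id="t", sequence=seq, circular=False)
        pairs = [p for p in find_inverted_repeats(g, min_len=400)]
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.start1, p.length) == (2000, 500)
        assert p.start2 == 4500

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        x = _random_seq(rng, 1500)
        r = _random_seq(rng, 260)
        seq = x + r + _random_seq(rng, 800) + revcomp(r) + _random_seq(rng, 400)
        g = CircularGenome(id="t", sequence=seq, circular=False)
        got = {tuple(sorted([(p.start1, p.length), (p.start2, p.length)]))
               for p in find_inverted_repeats(g, min_len=100)}
        expected = brute_force_inverted_repeats(seq, 100)
        assert got == expected and len(expected) == 1

    def test_random_sequence_has_no_long_inverted_repeat(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 10000)
        g = CircularGenome(id="t", sequence=seq, circular=False)
        assert find_inverted_repeats(g, min_len=100) == []
        assert brute_force_inverted_repeats(seq, 100) == set()

    def test_palindrome_reported_as_single_pair(self):
        rng = np.random.default_rng(5)
        r = _random_seq(rng, 300)
        seq = _random_seq(rng, 1000) + r + revcomp(r) + _random_seq(rng, 1000)
        g = CircularGenome(id="t", sequence=seq, circular=False)
        pairs = find_inverted_repeats(g, min_len=200)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.interval1 != p.interval2
        assert p.interval1[1] <= p.interval2[0]  # no self-overlap


class TestPartition:
    def test_planted_truth_recovered_exactly(self, scaled_world):
        genome, _, truth = scaled_world
        part = partition_quadripartite(genome)
        assert part.intervals() == truth.region_coords
        assert part.canonical_offset == 0

    def test_rotation_invariance(self, scaled_world):
        genome, _, _ = scaled_world
        base, base_part = canonicalize(genome)
        rng = np.random.default_rng(17)
        for off in rng.integers(1, len(genome), size=3):
            rotated = CircularGenome(
                id="rot", sequence=genome.sequence[off:] + genome.sequence[:off])
            canon, part = canonicalize(rotated)
            assert part.region_lengths == base_part.region_lengths
            assert canon.sequence == base.sequence

    def test_strand_invariance_of_region_lengths(self, scaled_world):
        genome, _, _ = scaled_world
        part = partition_quadripartite(genome)
        part_rc = partition_quadripartite(genome.reverse_complement())
        assert part.region_lengths == part_rc.region_lengths

    def test_partition_tiles_genome(self, scaled_world):
        genome, _, _ = scaled_world
        part = partition_quadripartite(genome)
        assert part.genome_length == len(genome)

    def test_no_ir_genome_raises_structured_error(self):
        rng = np.random.default_rng(23)
        g = CircularGenome(id="noir", sequence=_random_seq(rng, 6000))
        with pytest.raises(NoInvertedRepeatError):
            partition_quadripartite(g, min_ir=1000)


class TestRegionGC:
    def test_all_at_single_copy_regions_score_zero(self):
        rng = np.random.default_rng(1)
        # AT-only single-copy fillers chosen non-self-complementary so the
        # planted IR is the only long inverted repeat
        r = _random_seq(rng, 1200)
        seq = "AAAT" * 1000 + r + "TAAA" * 700 + revcomp(r)
        g = CircularGenome(id="t", sequence=seq)
        g, part = canonicalize(g)
        stats, overall = region_gc(g, part)
        by = {s.region: s.gc for s in stats}
        assert by["lsc"] == 0.0 and by["ssc"] == 0.0

    def test_half_gc_single_copy_regions_score_fifty(self):
        rng = np.random.default_rng(2)
        r = _random_seq(rng, 1200)
        seq = "AACG" * 1000 + r + "AGGA" * 700 + revcomp(r)
        g = CircularGenome(id="t", sequence=seq)
        g, part = canonicalize(g)
        stats, _ = region_gc(g, part)
        by = {s.region: s.gc for s in stats}
        assert by["lsc"] == 50.0 and by["ssc"] == 50.0

    def test_published_region_stats_give_weighted_overall(self):
        stats = [RegionStats("lsc", 91210, 33.47),
                 RegionStats("ssc", 14058, 30.17),
                 RegionStats("ira", 31844, 40.06),
                 RegionStats("irb", 31844, 40.06)]
        assert weighted_overall_gc(stats) == 35.68


class TestDirectRepeats:
    def test_planted_tandem_45_48_recovered(self):
        rng = np.random.default_rng(31)
        s = list(_random_seq(rng, 6930))
        for off, ln in ((2599, 45), (5065, 48)):
            s[off + ln:off + 2 * ln] = s[off:off + ln]
            if s[off - 1] == s[off + ln - 1]:
                s[off - 1] = next(b for b in "ACGT" if b != s[off + ln - 1])
            if s[off + 2 * ln] == s[off + ln]:
                s[off + 2 * ln] = next(b for b in "ACGT" if b != s[off + ln])
        seq = "".join(s)
        pairs = find_direct_repeats(seq, window=200, min_len=40)
        got = {(p.start1, p.start2, p.length) for p in pairs}
        assert (2599, 2644, 45) in got
        assert (5065, 5113, 48) in got
        assert {p.length for p in pairs} == {45, 48}

    def test_repeat_free_sequence_is_empty(self):
        rng = np.random.default_rng(37)
        seq = _random_seq(rng, 2000)
        assert find_direct_repeats(seq, window=2000, min_len=25) == []

    def test_min_len_above_planted_repeat_is_empty(self):
        rng = np.random.default_rng(41)
        s = list(_random_seq(rng, 2000))
        s[1000 + 45:1000 + 90] = s[1000:1000 + 45]
        pairs = find_direct_repeats("".join(s), window=100, min_len=60)
        assert pairs == []


class TestCoverage:
    def test_single_full_length_alignment(self):
        depth, mean = coverage_stats([(0, 1000)], 1000)
        assert mean == 1.0 and (depth == 1).all()

    def test_two_half_genome_alignments(self):
        depth, mean = coverage_stats([(0, 500), (500, 1000)], 1000)
        assert mean == 1.0

    def test_origin_wrapping_interval_accrues_both_ends(self):
        depth, mean = coverage_stats([(900, 1100)], 1000)
        assert depth[950] == 1 and depth[50] == 1 and depth[500] == 0

    def test_simulated_depth_near_nominal(self, scaled_world):
        genome, _, _ = scaled_world
        n = len(genome)
        target = 20
        n_reads = target * n // 1000
        reads = simulate_genomic_reads(genome, n_reads, 1000, 0.0, seed=51)
        intervals = [(r.source_start, r.source_end) for r in reads]
        _, mean = coverage_stats(intervals, n)
        assert 19 <= mean <= 21

    def test_reference_name_mismatch_raises(self, tmp_path, scaled_world):
        genome, _, _ = scaled_world
        from plastokit.io import write_truth_sam
        reads = simulate_genomic_reads(genome, 5, 500, 0.0, seed=52)
        sam = tmp_path / "t.sam"
        write_truth_sam(reads, genome, sam)
        with pytest.raises(ValueError, match="reference"):
            coverage_stats(sam, len(genome), reference_name="other")


class TestSummary:
    def test_published_sequencing_totals_reproduce_mean_read_length(self):
        assert mean_read_length(2_579_414_638, 239_086) == 10789
        rec = genome_summary(
            CircularGenome(id="x", sequence="ACGT" * 100),
            read_stats=(239_086, 2_579_414_638))
        assert rec["mean_read_length_bp"] == 10789

    def test_empty_read_set_reports_genome_fields_only(self, scaled_world):
        genome, _, _ = scaled_world
        rec = genome_summary(genome, reads=[])
        assert rec["genome_size_bp"] == len(genome)
        assert rec["read_count"] == 0
        assert "mean_read_length_bp" not in rec

    def test_synthetic_summary_matches_truth(self, scaled_world):
        genome, annotation, truth = scaled_world
        part = partition_quadripartite(genome)
        rec = genome_summary(genome, part, annotation=annotation)
        assert rec["lsc_bp"] == truth.region_coords["lsc"][1]
        assert rec["gene_count"] == len(annotation)
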