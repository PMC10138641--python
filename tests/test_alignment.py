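"""Alignment metrics: insert size, mate overlap, duplicates, on-target, depth."""

import numpy as np
import pytest

from kiteval import (
    AlignmentRecord,
    GenomicInterval,
    IntervalSet,
    depth_profile,
    insert_size_stats,
    mark_duplicates,
    merge,
    on_target_rate,
    read_alignments,
    read_overlap,
)
from conftest import oracle_depth


def make_pair(name, chrom, start, insert, read_len=100, qual=30, mapped=True):
    """A proper pair: forward read at start, reverse mate at start+insert-len."""
    r2_start = start + insert - read_len
    r1 = AlignmentRecord(
        name=name, chrom=chrom, pos=start, strand="+", unclipped_5p=start,
        mate_chrom=chrom, mate_unclipped_5p=start + insert - 1, mate_strand="-",
        tlen=insert, aligned_blocks=((start, start + read_len),),
        mapped=mapped, proper_pair=True, is_read1=True,
        base_quality_sum=qual * read_len,
    )
    r2 = AlignmentRecord(
        name=name, chrom=chrom, pos=r2_start, strand="-",
        unclipped_5p=start + insert - 1,
        mate_chrom=chrom, mate_unclipped_5p=start, mate_strand="+",
        tlen=-insert, aligned_blocks=((r2_start, r2_start + read_len),),
        mapped=mapped, proper_pair=True, is_read1=False,
        base_quality_sum=qual * read_len,
    )
    return [r1, r2]


class TestInsertSize:
    def test_median_of_three_pairs(self):
        recs = sum((make_pair(f"p{i}", "chr1", 0, t, read_len=50)
                    for i, t in enumerate([200, 206, 210])), [])
        stats = insert_size_stats(recs)
        assert stats["median"] == 206
        assert stats["n_pairs"] == 3

    def test_outlier_template_excluded(self):
        recs = sum((make_pair(f"p{i}", "chr1", 0, t, read_len=50)
                    for i, t in enumerate([206, 206, 3000])), [])
        stats = insert_size_stats(recs)
        assert stats["median"] == 206
        assert stats["n_pairs"] == 2

    def test_no_proper_pairs_is_an_error(self):
        rec = make_pair("p", "chr1", 0, 200)[0]
        rec.proper_pair = False
        with pytest.raises(ValueError, match="proper pairs"):
            insert_size_stats([rec])

    def test_simulated_normal_insert_median_recovered(self, small_sim):
        stats = insert_size_stats(small_sim.records)
        assert abs(stats["median"] - 206) <= 2


class TestReadOverlap:
    @pytest.mark.parametrize(
        "read_len,insert,expected",
        [(150, 206, 94), (150, 215, 85), (150, 204, 96), (150, 400, 0)],
    )
    def test_mate_overlap_arithmetic(self, read_len, insert, expected):
        assert read_overlap(read_len, insert) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            read_overlap(0, 200)


class TestMarkDuplicates:
    def test_three_identical_pairs_plus_one_unique(self):
        recs = []
        for i in range(3):
            recs += make_pair(f"dup{i}", "chr1", 100, 200, qual=30 + i)
        recs += make_pair("uniq", "chr1", 5000, 200)
        rate = mark_duplicates(recs)
        assert rate == pytest.approx(0.5)
        assert sum(r.duplicate for r in recs) == 4
        # highest-quality pair retained
        kept = {r.name for r in recs if not r.duplicate}
        assert kept == {"dup2", "uniq"}

    def test_all_unique_rate_zero(self):
        recs = sum((make_pair(f"p{i}", "chr1", i * 1000, 200) for i in range(5)), [])
        assert mark_duplicates(recs) == 0.0
        assert not any(r.duplicate for r in recs)

    def test_tie_breaks_stable_first_encountered(self):
        recs = make_pair("a", "chr1", 100, 200) + make_pair("b", "chr1", 100, 200)
        mark_duplicates(recs)
        assert {r.name for r in recs if not r.duplicate} == {"a"}

    def test_single_end_reads_keyed_by_position_and_strand(self):
        se = []
        for name in ("s1", "s2"):
            se.append(AlignmentRecord(
                name=name, chrom="chr1", pos=10, strand="+", unclipped_5p=10,
                mate_chrom=None, mate_unclipped_5p=None, mate_strand=None,
                tlen=0, aligned_blocks=((10, 110),), base_quality_sum=100,
            ))
        assert mark_duplicates(se) == pytest.approx(0.5)

    def test_injected_duplicate_fraction_recovered(self, small_sim):
        rate = mark_duplicates(small_sim.records)
        assert abs(rate - small_sim.truth["expected_duplicate_rate"]) <= 0.01

    def test_duplicate_monotone_in_injected_fraction(self):
        from kiteval import SimulationConfig, simulate_experiment

        rates = []
        for frac in (0.0, 0.1, 0.25):
            sim = simulate_experiment(
                SimulationConfig(n_read_pairs=2_000, duplicate_fraction=frac, seed=4)
            )
            rates.append(mark_duplicates(sim.records))
        assert rates[0] == 0.0
        assert rates == sorted(rates)


class TestOnTarget:
    def test_half_on_half_off(self):
        target = merge([GenomicInterval("chr1", 0, 1000)])
        on = make_pair("on", "chr1", 100, 300)[0]
        off = make_pair("off", "chr1", 5000, 300)[0]
        assert on_target_rate([on, off], target) == pytest.approx(0.5)

    def test_partial_overlap_counts_bases(self):
        target = merge([GenomicInterval("chr1", 60, 1000)])
        read = make_pair("r", "chr1", 0, 300)[0]  # aligned [0,100); 40 on target
        assert on_target_rate([read], target) == pytest.approx(0.40)

    def test_fully_contained_reads_rate_one(self, small_sim):
        on = [r for r in small_sim.records
              if small_sim.design.overlap_bases(r.chrom, r.pos, r.pos + 150) == 150]
        assert on_target_rate(on, small_sim.design) == 1.0

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="empty target"):
            on_target_rate([], IntervalSet([]))

    def test_matches_boolean_array_oracle(self, small_sim):
        rng = np.random.default_rng(12)
        recs = [small_sim.records[i]
                for i in rng.choice(len(small_sim.records), 200, replace=False)]
        lengths = small_sim.config.chrom_lengths
        masks = {c: np.zeros(l, dtype=bool) for c, l in lengths.items()}
        for iv in small_sim.design:
            masks[iv.chrom][iv.start : iv.end] = True
        on = total = 0
        for r in recs:
            for s, e in r.aligned_blocks:
                total += e - s
                on += int(masks[r.chrom][s:e].sum())
        assert on_target_rate(recs, small_sim.design) == pytest.approx(on / total)


class TestDepthProfile:
    def test_one_read_exactly_covering_target(self):
        target = merge([GenomicInterval("chr1", 0, 10)])
        read = AlignmentRecord(
            name="r", chrom="chr1", pos=0, strand="+", unclipped_5p=0,
            mate_chrom=None, mate_unclipped_5p=None, mate_strand=None,
            tlen=0, aligned_blocks=((0, 10),),
        )
        prof = depth_profile([read], target)
        assert prof.depth.tolist() == [1] * 10
        assert prof.mean == 1.0

    def test_duplicate_exclusion_halves_two_pair_pileup(self):
        target = merge([GenomicInterval("chr1", 0, 300)])
        recs = make_pair("a", "chr1", 0, 300, read_len=150) + make_pair(
            "b", "chr1", 0, 300, read_len=150
        )
        mark_duplicates(recs)
        with_d = depth_profile(recs, target, include_duplicates=True)
        without = depth_profile(recs, target, include_duplicates=False)
        assert with_d.mean == pytest.approx(2 * without.mean)

    def test_simulated_profile_matches_brute_force_pileup(self, small_sim):
        rng = np.random.default_rng(2)
        recs = [small_sim.records[i]
                for i in rng.choice(len(small_sim.records), 1000, replace=False)]
        prof = depth_profile(recs, small_sim.design)
        oracle = oracle_depth(recs, small_sim.design, small_sim.config.chrom_lengths)
        assert np.array_equal(prof.depth, oracle)

    def test_depth_total_conserves_on_target_bases(self, small_sim):
        recs = small_sim.records[:400]
        prof = depth_profile(recs, small_sim.design)
        expected = sum(
            small_sim.design.overlap_bases(r.chrom, s, e)
            for r in recs for (s, e) in r.aligned_blocks
        )
        assert int(prof.depth.sum()) == expected

    def test_dedup_mean_never_exceeds_dup_inclusive_mean(self, small_sim):
        mark_duplicates(small_sim.records)
        with_d = depth_profile(small_sim.records, small_sim.design, True)
        without = depth_profile(small_sim.records, small_sim.design, False)
        assert np.all(without.depth <= with_d.depth)

    def test_pipeline_consistency_dup_rate_vs_mean_depths(self, small_sim):
        rate = mark_duplicates(small_sim.records)
        with_d = depth_profile(small_sim.records, small_sim.design, True)
        without = depth_profile(small_sim.records, small_sim.design, False)
        assert without.mean == pytest.approx(with_d.mean * (1 - rate), rel=0.05)


class TestSamIngestion:
    def test_round_trip_preserves_metric_fields(self, small_sim, sim_dir):
        back = read_alignments(sim_dir / "sample.sam")
        key = lambda r: (r.chrom, r.pos, r.name, r.is_read1)
        for a, b in zip(sorted(small_sim.records, key=key), sorted(back, key=key)):
            assert (a.chrom, a.pos, a.strand, a.unclipped_5p) == (
                b.chrom, b.pos, b.strand, b.unclipped_5p,
            )
            assert (a.mate_unclipped_5p, a.mate_strand) == (
                b.mate_unclipped_5p, b.mate_strand,
            )
            assert abs(a.tlen) == abs(b.tlen)
            assert a.aligned_blocks == b.aligned_blocks
            assert a.base_quality_sum == b.base_quality_sum

    def test_unclipped_five_prime_undoes_soft_clip(self, tmp_path):
        sam = tmp_path / "clip.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "fwd\t0\tchr1\t101\t60\t10S90M\t*\t0\t0\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
            "rev\t16\tchr1\t201\t60\t90M10S\t*\t0\t0\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
        )
        fwd, rev = sorted(read_alignments(sam), key=lambda r: r.pos)
        assert fwd.unclipped_5p == 90  # 0-based 100 minus 10 clipped
        assert rev.unclipped_5p == 289 + 10  # reference_end-1 plus trailing clip

    def test_secondary_and_supplementary_excluded(self, tmp_path):
        sam = tmp_path / "sec.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t1\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "r1\t256\tchr1\t101\t60\t50M\t*\t0\t0\t*\t*\n"
            "r1\t2048\tchr1\t201\t60\t50M\t*\t0\t0\t*\t*\n"
        )
        assert len(read_alignments(sam)) == 1
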