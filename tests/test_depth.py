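"""Depth counting: mode semantics, record filters, and the text-level oracle."""

import numpy as np
import pytest

import enrichfit as ef
from enrichfit.errors import ConfigurationError, MissingIndexError

from helpers import random_sam, sam_depth_oracle, write_sam


def seq(n):
    return "A" * n


class TestCountModes:
    def test_three_forward_reads_same_start(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [(f"r{i}", 0, 100, 60, "10M", seq(10)) for i in range(3)],
        )
        table = ef.compute_depth(sam, "start")
        assert table.counts == {ef.GenomicPosition("chr1", 100, "+"): 3}

    def test_reverse_read_start_is_rightmost_base(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r0", 16, 200, 60, "50M", seq(50))])
        table = ef.compute_depth(sam, "start")
        assert table.counts == {ef.GenomicPosition("chr1", 249, "-"): 1}
        assert ef.GenomicPosition("chr1", 200, "-") not in table.counts

    def test_all_mode_covers_every_aligned_base(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r0", 0, 10, 60, "10M", seq(10))])
        table = ef.compute_depth(sam, "all")
        expected = {ef.GenomicPosition("chr1", p, "+"): 1 for p in range(10, 20)}
        assert table.counts == expected

    def test_soft_clip_shifts_start_to_first_aligned_base(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r0", 0, 50, 60, "5S10M", seq(15))])
        table = ef.compute_depth(sam, "start")
        assert table.counts == {ef.GenomicPosition("chr1", 50, "+"): 1}

    def test_end_mode_mirrors_start(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [("f", 0, 10, 60, "10M", seq(10)), ("r", 16, 30, 60, "10M", seq(10))],
        )
        table = ef.compute_depth(sam, "end")
        assert table.counts == {
            ef.GenomicPosition("chr1", 19, "+"): 1,
            ef.GenomicPosition("chr1", 30, "-"): 1,
        }


class TestRecordFilters:
    def test_skips_unmapped_secondary_supplementary(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [
                ("keep", 0, 100, 60, "10M", seq(10)),
                ("unmapped", 4, 100, 0, "*", "*"),
                ("secondary", 256, 100, 60, "10M", seq(10)),
                ("supplementary", 2048, 100, 60, "10M", seq(10)),
            ],
        )
        table = ef.compute_depth(sam, "start")
        assert table.total_depth == 1

    def test_min_mapq_filter(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [("lo", 0, 100, 5, "10M", seq(10)), ("hi", 0, 100, 40, "10M", seq(10))],
        )
        assert ef.compute_depth(sam, "start", min_mapq=10).total_depth == 1
        assert ef.compute_depth(sam, "start", min_mapq=0).total_depth == 2

    def test_duplicate_flag_retained(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [("a", 0, 100, 60, "10M", seq(10)), ("dup", 1024, 100, 60, "10M", seq(10))],
        )
        assert ef.compute_depth(sam, "start").total_depth == 2

    def test_empty_input_gives_empty_table(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [])
        table = ef.compute_depth(sam, "start")
        assert table.counts == {} and table.total_depth == 0

    def test_unindexed_bam_raises(self, tmp_path):
        import pysam

        sam = write_sam(tmp_path / "a.sam", [("r0", 0, 100, 60, "10M", seq(10))])
        bam = tmp_path / "a.bam"
        pysam.sort("-o", str(bam), str(sam))
        with pytest.raises(MissingIndexError):
            ef.compute_depth(bam, "start")

    def test_invalid_mode_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [])
        with pytest.raises(ConfigurationError):
            ef.compute_depth(sam, "middle")


@pytest.mark.parametrize("mode", ["start", "end", "all"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_oracle_equivalence_on_random_sam(tmp_path, mode, seed):
    """compute_depth agrees with independent SAM-text/CIGAR enumeration."""
    rng = np.random.default_rng(seed)
    sam = random_sam(tmp_path / "r.sam", rng, n_reads=100)
    table = ef.compute_depth(sam, mode)
    expected = sam_depth_oracle(sam, mode)
    got = {(k.reference, k.position, k.strand): v for k, v in table.counts.items()}
    assert got == dict(expected)


def test_strand_flip_swaps_start_and_end_tables(tmp_path):
    """Reversing every read's orientation exchanges 5' and 3' depth tables."""
    rng = np.random.default_rng(3)
    reads = []
    for i in range(50):
        pos = int(rng.integers(1, 400))
        flag = int(rng.choice([0, 16]))
        n = int(rng.integers(10, 30))
        reads.append((f"r{i}", flag, pos, 60, f"{n}M", seq(n)))
    flipped = [(n_, f_ ^ 16, p, q, c, s) for n_, f_, p, q, c, s in reads]
    sam_a = write_sam(tmp_path / "a.sam", reads)
    sam_b = write_sam(tmp_path / "b.sam", flipped)
    start_flip = ef.compute_depth(sam_b, "start").counts
    end_orig = ef.compute_depth(sam_a, "end").counts
    swap = {"+": "-", "-": "+"}
    assert start_flip == {
        ef.GenomicPosition(k.reference, k.position, swap[k.strand]): v
        for k, v in end_orig.items()
    }


def test_total_depth_all_mode_equals_aligned_base_sum(tmp_path):
    rng = np.random.default_rng(4)
    sam = random_sam(tmp_path / "r.sam", rng, n_reads=80)
    table = ef.compute_depth(sam, "all")
    oracle = sam_depth_oracle(sam, "all")
    assert table.total_depth == sum(oracle.values())


class TestOverlapSummary:
    @staticmethod
    def make(positions):
        return ef.DepthTable(
            "x", "start", {ef.GenomicPosition("c", p, "+"): 1 for p in positions}
        )

    def test_identical_sets(self):
        s = ef.library_overlap_summary(self.make([1, 2, 3]), self.make([1, 2, 3]))
        assert (s.both, s.only_enriched, s.only_control) == (3, 0, 0)

    def test_disjoint_sets(self):
        s = ef.library_overlap_summary(self.make(range(4)), self.make(range(10, 16)))
        assert (s.both, s.only_enriched, s.only_control) == (0, 4, 6)

    def test_partial_overlap_and_fractions(self):
        s = ef.library_overlap_summary(self.make([1, 2, 3]), self.make([2, 3, 4]))
        assert (s.both, s.only_enriched, s.only_control) == (2, 1, 1)
        assert sum(s.fractions.values()) == pytest.approx(1.0)

    def test_mode_mismatch_rejected(self):
        a = self.make([1])
        b = ef.DepthTable("y", "end", {ef.GenomicPosition("c", 1, "+"): 1})
        with pytest.raises(ConfigurationError):
            ef.library_overlap_summary(a, b)


class TestDepthHistogram:
    def test_small_example(self):
        table = ef.DepthTable(
            "x",
            "start",
            {
                ef.GenomicPosition("c", 1, "+"): 3,
                ef.GenomicPosition("c", 2, "+"): 3,
                ef.GenomicPosition("c", 3, "+"): 1,
            },
        )
        assert ef.depth_histogram(table) == {1: 1, 3: 2}

    def test_empty(self):
        assert ef.depth_histogram(ef.DepthTable("x", "start", {})) == {}

    def test_frequencies_sum_to_position_count(self, tmp_path):
        rng = np.random.default_rng(5)
        sam = random_sam(tmp_path / "r.sam", rng, n_reads=60)
        table = ef.compute_depth(sam, "start")
        assert sum(ef.depth_histogram(table).values()) == table.n_positions


def test_tsv_round_trip(tmp_path):
    table = ef.DepthTable(
        "lib", "start",
        {ef.GenomicPosition("c", 5, "+"): 2, ef.GenomicPosition("c", 9, "-"): 7},
    )
    path = tmp_path / "d.tsv"
    table.to_tsv(path)
    back = ef.DepthTable.from_tsv(path, "lib", "start")
    assert back.counts == table.counts
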