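"""Fragment filtering, window assignment and track serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from micseq.genome import GenomeLayout, WindowGrid
from micseq.io import (
    CoverageTrack,
    FragmentRecord,
    count_windows,
    filter_fragments_frame,
    fragments_from_bam,
    insert_size_histogram,
    read_chrom_sizes,
    read_fragments,
    read_track,
    write_track,
)
from conftest import make_fragment, random_fragments


class TestGenomeLayout:
    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError, match="unique"):
            GenomeLayout(("chr1", "chr1"), {"chr1": 100})

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            GenomeLayout(("chr1",), {"chr1": 0})

    def test_chrom_sizes_round_trip(self, toy_layout, tmp_path):
        p = tmp_path / "toy.chrom.sizes"
        toy_layout.to_chrom_sizes(p)
        back = read_chrom_sizes(p)
        assert back == toy_layout

    def test_malformed_chrom_sizes_names_line(self, tmp_path):
        p = tmp_path / "bad.sizes"
        p.write_text("chr1\t100\nchr2\n")
        with pytest.raises(ValueError, match="2"):
            read_chrom_sizes(p)


class TestWindowGrid:
    def test_windows_tile_and_overlap(self, toy_layout):
        g = WindowGrid(toy_layout, 40_000, 20_000)
        starts, ends = g.starts("chr1"), g.ends("chr1")
        assert starts[0] == 0
        # consecutive interior windows overlap by exactly w - s
        overlaps = np.minimum(ends[:-1], starts[:-1] + 40_000) - starts[1:]
        assert (overlaps[:-1] == 20_000).all()
        assert ends[-1] == toy_layout.length("chr1")

    def test_step_cannot_exceed_window(self, toy_layout):
        with pytest.raises(ValueError):
            WindowGrid(toy_layout, 10_000, 20_000)

    @pytest.mark.parametrize(
        "mid,expected",
        [
            (25_000, [0, 1]),  # interior midpoint sits in two overlapping windows
            (0, [0]),  # half-open boundary: first window only
            (20_000, [0, 1]),
        ],
    )
    def test_windows_containing(self, toy_layout, mid, expected):
        g = WindowGrid(toy_layout, 40_000, 20_000)
        assert g.windows_containing("chr1", mid).tolist() == expected


class TestReadFragments:
    def test_passes_clean_fragment(self, toy_layout):
        frags = [make_fragment(start=100, end=300, mapq=25)]
        out = list(read_fragments(iter(frags), toy_layout, max_insert=1000))
        assert out == frags

    def test_mapq_filter_is_strict(self, toy_layout):
        # the retention rule is mapping quality strictly greater than 20
        out = list(read_fragments([make_fragment(mapq=20)], toy_layout))
        assert out == []
        assert list(read_fragments([make_fragment(mapq=21)], toy_layout))

    def test_mixed_fixture_counts(self, toy_layout):
        # 10 fragments: 3 duplicates, 2 low mapq, 1 over-long span -> 4 kept
        frags = (
            [make_fragment(dup=True) for _ in range(3)]
            + [make_fragment(mapq=10), make_fragment(mapq=20)]
            + [make_fragment(start=0, end=5000, mid=100)]
            + [make_fragment(start=1000 * i, end=1000 * i + 300, mid=1000 * i + 50) for i in range(4)]
        )
        rej = {}
        out = list(read_fragments(iter(frags), toy_layout, max_insert=1000, rejected=rej))
        assert len(out) == 4
        assert rej["duplicate"] == 3 and rej["mapq"] == 2 and rej["insert"] == 1

    def test_unknown_chrom_rejected_not_fatal(self, toy_layout):
        rej = {}
        out = list(
            read_fragments(
                [make_fragment(chrom="chrUn"), make_fragment()], toy_layout, rejected=rej
            )
        )
        assert len(out) == 1 and rej["unknown_chrom"] == 1

    def test_filter_idempotent(self, rng, toy_layout):
        frags = random_fragments(rng, toy_layout, 200)
        frags += [make_fragment(dup=True), make_fragment(mapq=5)]
        once = list(read_fragments(iter(frags), toy_layout, max_insert=2000))
        twice = list(read_fragments(iter(once), toy_layout, max_insert=2000))
        assert once == twice

    def test_frame_filter_matches_stream_filter(self, rng, toy_layout):
        frags = random_fragments(rng, toy_layout, 300)
        frags += [make_fragment(dup=True), make_fragment(mapq=15)]
        df = pd.DataFrame([f.__dict__ for f in frags])
        stream = list(read_fragments(iter(frags), toy_layout, max_insert=800))
        frame = filter_fragments_frame(df, toy_layout, max_insert=800)
        assert len(stream) == len(frame)


class TestInsertSizeHistogram:
    def test_constant_lengths(self):
        frags = [make_fragment(start=0, end=200, mid=50) for _ in range(5)]
        hist, mx = insert_size_histogram(frags)
        assert hist == {200: 5} and mx == 200

    def test_uniform_lengths_quantile(self):
        frags = [make_fragment(start=0, end=l, mid=0) for l in range(100, 1001)]
        _, mx = insert_size_histogram(frags, quantile=0.999)
        lengths = np.arange(100, 1001)
        expected = int(np.sort(lengths)[int(np.ceil(0.999 * lengths.size)) - 1])
        assert mx == expected

    def test_quantile_one_gives_max(self):
        frags = [make_fragment(start=0, end=l, mid=0) for l in (150, 900, 300)]
        _, mx = insert_size_histogram(frags, quantile=1.0)
        assert mx == 900

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            insert_size_histogram([])


def brute_force_counts(frags, grid, chrom):
    """O(n * windows) membership scan — the independent counting oracle."""
    starts, ends = grid.starts(chrom), grid.ends(chrom)
    counts = np.zeros(len(starts))
    for f in frags:
        if f.chrom != chrom:
            continue
        for k in range(len(starts)):
            if starts[k] <= f.left_read_mid < min(ends[k], starts[k] + grid.window_size):
                counts[k] += 1
    return counts


class TestCountWindows:
    def test_interior_midpoint_hits_two_windows(self, toy_layout):
        grid = WindowGrid(toy_layout, 40_000, 20_000)
        t = count_windows([make_fragment(start=24_900, end=25_300, mid=25_000)], grid)
        hit = np.nonzero(t.counts["chr1"])[0]
        assert hit.tolist() == [0, 1]

    def test_zero_midpoint_first_window_only(self, toy_layout):
        grid = WindowGrid(toy_layout, 40_000, 20_000)
        t = count_windows([make_fragment(start=0, end=300, mid=0)], grid)
        assert np.nonzero(t.counts["chr1"])[0].tolist() == [0]

    def test_matches_brute_force_oracle(self, rng):
        layout = GenomeLayout.from_dict({"chr1": 1_000_000})
        grid = WindowGrid(layout, 40_000, 20_000)
        frags = random_fragments(rng, layout, 1000)
        t = count_windows(iter(frags), grid)
        np.testing.assert_array_equal(t.counts["chr1"], brute_force_counts(frags, grid, "chr1"))

    def test_dataframe_path_matches_stream_path(self, rng, toy_layout, toy_grid):
        frags = random_fragments(rng, toy_layout, 500)
        a = count_windows(iter(frags), toy_grid)
        b = count_windows(pd.DataFrame([f.__dict__ for f in frags]), toy_grid)
        for c in toy_layout.chrom_names:
            np.testing.assert_array_equal(a.counts[c], b.counts[c])

    def test_order_independent(self, rng, toy_layout, toy_grid):
        frags = random_fragments(rng, toy_layout, 300)
        a = count_windows(iter(frags), toy_grid)
        b = count_windows(iter(frags[::-1]), toy_grid)
        for c in toy_layout.chrom_names:
            np.testing.assert_array_equal(a.counts[c], b.counts[c])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(mids=st.lists(st.integers(0, 999_999), min_size=1, max_size=60))
    def test_assignment_conservation(self, mids):
        """Total increments equal the number of containing windows per midpoint;
        with s = w/2 an interior midpoint lies in exactly 2 windows."""
        layout = GenomeLayout.from_dict({"chr1": 1_000_000})
        grid = WindowGrid(layout, 40_000, 20_000)
        frags = [FragmentRecord("chr1", max(m - 50, 0), min(m + 50, 10**6), m, 60) for m in mids]
        t = count_windows(iter(frags), grid)
        expected = sum(len(grid.windows_containing("chr1", m)) for m in mids)
        assert t.counts["chr1"].sum() == expected
        interior = [m for m in mids if 20_000 <= m < 980_000]
        assert all(len(grid.windows_containing("chr1", m)) == 2 for m in interior)


class TestTrackIO:
    def test_bedgraph_line_format(self, tmp_path):
        layout = GenomeLayout.from_dict({"chr1": 120_000})
        grid = WindowGrid(layout, 40_000, 40_000)
        t = CoverageTrack("MN", grid, {"chr1": np.array([7.0, 1.0, 2.0])}, 10)
        p = tmp_path / "t.bedGraph"
        write_track(t, p)
        lines = p.read_text().splitlines()
        assert lines[1] == "chr1\t0\t40000\t7"

    @pytest.mark.parametrize("fmt", ["bedGraph", "wiggle"])
    @pytest.mark.parametrize("step", [40_000, 20_000])
    def test_round_trip(self, tmp_path, fmt, step):
        layout = GenomeLayout.from_dict({"chr1": 200_000, "chr2": 90_000})
        grid = WindowGrid(layout, 40_000, step)
        rng = np.random.default_rng(0)
        counts = {c: rng.integers(0, 50, grid.n_windows(c)).astype(float) for c in layout.chrom_names}
        t = CoverageTrack("GRN", grid, counts, 123)
        p = tmp_path / f"t.{fmt}"
        write_track(t, p, fmt=fmt)
        back = read_track(p, layout, fmt=fmt)
        assert back.grid == grid and back.total_fragments == 123
        for c in layout.chrom_names:
            np.testing.assert_array_equal(back.counts[c], t.counts[c])

    def test_malformed_line_reports_number(self, tmp_path):
        layout = GenomeLayout.from_dict({"chr1": 100_000})
        p = tmp_path / "bad.bedGraph"
        p.write_text("# micseq track w=40000 s=40000\nchr1\t0\t40000\n")
        with pytest.raises(ValueError, match=":2"):
            read_track(p, layout)

    def test_tsv_round_trip(self, tmp_path, toy_layout, toy_grid, rng):
        counts = {c: rng.integers(0, 9, toy_grid.n_windows(c)).astype(float) for c in toy_layout.chrom_names}
        t = CoverageTrack("MN", toy_grid, counts, 42)
        p = tmp_path / "c.tsv"
        t.to_tsv(p)
        back = CoverageTrack.from_tsv(p, toy_layout)
        assert back.fraction == "MN" and back.total_fragments == 42
        for c in toy_layout.chrom_names:
            np.testing.assert_array_equal(back.counts[c], t.counts[c])


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:10000000\n"


def sam_pair(name, pos, mpos, tlen, mapq=60, flag1=99, flag2=147):
    cigar = "100M"
    return (
        f"{name}\t{flag1}\tchr1\t{pos + 1}\t{mapq}\t{cigar}\t=\t{mpos + 1}\t{tlen}\t*\t*\n"
        f"{name}\t{flag2}\tchr1\t{mpos + 1}\t{mapq}\t{cigar}\t=\t{pos + 1}\t{-tlen}\t*\t*\n"
    )


class TestBamInput:
    def test_fragments_from_sam(self, tmp_path):
        p = tmp_path / "in.sam"
        p.write_text(SAM_HEADER + sam_pair("r1", 1000, 1200, 300) + sam_pair("r2", 5000, 5100, 200))
        frags = list(fragments_from_bam(p))
        assert len(frags) == 2
        f = frags[0]
        assert (f.start, f.end) == (1000, 1300)
        assert f.left_read_mid == (1000 + 1100) // 2
        assert f.proper_pair and not f.duplicate

    def test_unsorted_input_fatal(self, tmp_path):
        p = tmp_path / "bad.sam"
        p.write_text(SAM_HEADER + sam_pair("r2", 5000, 5100, 200) + sam_pair("r1", 1000, 1200, 300))
        with pytest.raises(ValueError, match="sorted"):
            list(fragments_from_bam(p))
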