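"""Bin grids, read-overlap counting, filtering and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from g4dcr.bin_coverage import (
    CoverageMatrix,
    build_signal_matrix,
    count_coverage,
    filter_bins,
    make_bins,
    normalize_depth,
    signal_profile,
)
from g4dcr.io_core import ChromSizes, GenomicInterval, SampleMeta


def _meta(i):
    cond = "CT" if i % 2 == 0 else "KD"
    return SampleMeta(f"s{i}", cond, f"b{i // 2}", "chip")


class TestMakeBins:
    def test_exact_tiling(self):
        grid = make_bins(ChromSizes({"chr1": 1000}), width=200)
        assert grid.n_bins == 5
        assert [iv.length for iv in grid.intervals()] == [200] * 5

    def test_trailing_partial_bin(self):
        grid = make_bins(ChromSizes({"chr1": 950}), width=200)
        assert grid.n_bins == 5
        last = grid.bin_interval(4)
        assert (last.start, last.end) == (800, 950)

    def test_two_chromosomes_concatenate_in_order(self, two_chrom_sizes):
        grid = make_bins(two_chrom_sizes, width=200)
        ivs = grid.intervals()
        assert [iv.chrom for iv in ivs] == ["chr1"] * 5 + ["chr2"] * 3
        assert grid.row("chr2", 0) == 5

    def test_bins_tile_chromosomes_exactly(self, two_chrom_sizes):
        grid = make_bins(two_chrom_sizes, width=150)
        by_chrom = {}
        for iv in grid.intervals():
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            assert ivs[0].start == 0
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start
            assert ivs[-1].end == two_chrom_sizes[chrom]

    def test_bad_width_rejected(self, two_chrom_sizes):
        with pytest.raises(ValueError):
            make_bins(two_chrom_sizes, width=0)


class TestCountCoverage:
    def test_read_spanning_bins_counts_in_each(self):
        grid = make_bins(ChromSizes({"chr1": 30}), width=10)
        counts = count_coverage([GenomicInterval("chr1", 5, 25)], grid)
        assert counts.tolist() == [1, 1, 1]

    def test_read_equal_to_bin_counts_once(self):
        grid = make_bins(ChromSizes({"chr1": 30}), width=10)
        counts = count_coverage([GenomicInterval("chr1", 10, 20)], grid)
        assert counts.tolist() == [0, 1, 0]

    def test_matches_brute_force_on_random_reads(self, two_chrom_sizes):
        grid = make_bins(two_chrom_sizes, width=37)
        rng = np.random.default_rng(21)
        reads = []
        for _ in range(1000):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            start = int(rng.integers(0, two_chrom_sizes[chrom] - 1))
            end = int(rng.integers(start + 1, min(start + 120, two_chrom_sizes[chrom]) + 1))
            reads.append(GenomicInterval(chrom, start, end))
        counts = count_coverage(reads, grid)
        brute = np.zeros(grid.n_bins, dtype=int)
        for i, b in enumerate(grid.intervals()):
            brute[i] = sum(r.overlaps(b) for r in reads)
        assert np.array_equal(counts, brute)
        # every read contributes to at least one bin
        assert counts.sum() >= len(reads)

    def test_off_grid_reads_skipped_with_warning(self, two_chrom_sizes, caplog):
        grid = make_bins(two_chrom_sizes, width=100)
        with caplog.at_level("WARNING"):
            counts = count_coverage([GenomicInterval("chrX", 0, 50)], grid)
        assert counts.sum() == 0
        assert "skipped 1" in caplog.text


class TestFilterBins:
    def _cov(self, raw):
        raw = np.asarray(raw)
        grid = make_bins(ChromSizes({"chr1": raw.shape[0] * 100}), width=100)
        samples = [_meta(i) for i in range(raw.shape[1])]
        return CoverageMatrix(grid=grid, samples=samples, raw=raw)

    @pytest.mark.parametrize(
        "counts,kept",
        [((3, 100, 50), True), ((2, 50, 50), False), ((50, 101, 50), False)],
    )
    def test_inclusive_bounds(self, counts, kept):
        cov = self._cov(np.array([counts]))
        assert filter_bins(cov, 3, 100).tolist() == [kept]

    def test_scope_restricts_samples(self):
        cov = self._cov(np.array([[2, 50, 50]]))
        assert filter_bins(cov, 3, 100, scope=["s1", "s2"]).tolist() == [True]

    def test_min_above_max_rejected(self):
        cov = self._cov(np.array([[5]]))
        with pytest.raises(ValueError):
            filter_bins(cov, 10, 5)

    @given(st.integers(0, 3), st.integers(0, 50))
    def test_relaxing_bounds_is_monotone(self, dmin, dmax):
        rng = np.random.default_rng(77)
        cov = self._cov(rng.integers(0, 150, size=(40, 3)))
        strict = filter_bins(cov, 3, 100)
        relaxed = filter_bins(cov, 3 - dmin, 100 + dmax)
        assert np.all(relaxed[strict])


class TestNormalizeDepth:
    def _cov(self, raw, sizes=None):
        raw = np.asarray(raw)
        grid = make_bins(ChromSizes({"chr1": raw.shape[0] * 100}), width=100)
        samples = [
            SampleMeta(f"s{i}", "CT", f"b{i}", "chip",
                       library_size=None if sizes is None else sizes[i])
            for i in range(raw.shape[1])
        ]
        return CoverageMatrix(grid=grid, samples=samples, raw=raw)

    def test_counts_per_million(self):
        cov = self._cov(np.array([[10]]), sizes=[10**6])
        out = normalize_depth(cov)
        assert out.normalized[0, 0] == pytest.approx(10.0)

    def test_scale_invariance_of_doubling(self):
        raw = np.array([[4, 7], [6, 1], [2, 8]])
        a = normalize_depth(self._cov(raw))
        b = normalize_depth(self._cov(raw * 2))
        assert np.allclose(a.normalized, b.normalized)

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(3)
        cov = self._cov(rng.integers(1, 50, size=(20, 4)))
        out = normalize_depth(cov)
        assert np.allclose(out.normalized.sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        cov = self._cov(np.zeros((3, 1), dtype=int))
        with pytest.raises(ValueError, match="positive"):
            normalize_depth(cov)


class TestSignalProfile:
    def test_constant_track_profiles_flat(self):
        grid = make_bins(ChromSizes({"chr1": 100_000}), width=200)
        values = np.full(grid.n_bins, 2.5)
        prof = signal_profile(values, grid, [GenomicInterval("chr1", 50_000, 50_200)],
                              flank=5000, n_position_bins=20)
        assert prof.matrix.shape == (1, 20)
        assert prof.mean == pytest.approx(np.full(20, 2.5))

    def test_central_bin_dominates_for_point_signal(self):
        grid = make_bins(ChromSizes({"chr1": 100_000}), width=200)
        values = np.zeros(grid.n_bins)
        center = GenomicInterval("chr1", 50_000, 50_200)
        values[grid.row("chr1", 50_000)] = 100.0
        prof = signal_profile(values, grid, [center], flank=5000, n_position_bins=51)
        assert np.argmax(prof.mean) == 25

    def test_mean_matches_brute_force_average(self):
        rng = np.random.default_rng(8)
        grid = make_bins(ChromSizes({"chr1": 50_000}), width=100)
        values = rng.random(grid.n_bins)
        centers = [
            GenomicInterval("chr1", int(c), int(c) + 100)
            for c in rng.integers(5_000, 45_000, size=6)
        ]
        prof = signal_profile(values, grid, centers, flank=2000, n_position_bins=8)
        assert prof.mean == pytest.approx(prof.matrix.mean(axis=0))
        assert prof.sem == pytest.approx(
            prof.matrix.std(axis=0, ddof=1) / np.sqrt(len(centers))
        )

    def test_edge_region_dropped(self):
        grid = make_bins(ChromSizes({"chr1": 10_000}), width=100)
        prof = signal_profile(np.ones(grid.n_bins), grid,
                              [GenomicInterval("chr1", 0, 100)], flank=5000,
                              n_position_bins=4)
        assert prof.n_dropped == 1


class TestSignalMatrix:
    def _cov(self):
        rng = np.random.default_rng(13)
        grid = make_bins(ChromSizes({"chr1": 2000}), width=100)
        raw = rng.integers(0, 60, size=(grid.n_bins, 2))
        cov = CoverageMatrix(grid=grid, samples=[_meta(0), _meta(1)], raw=raw)
        return normalize_depth(cov)

    def test_row_count_equals_mask_true_count(self):
        cov = self._cov()
        mask = filter_bins(cov, 3, 50)
        table = build_signal_matrix(cov, mask)
        assert len(table) == int(mask.sum())

    def test_empty_mask_gives_empty_table_with_header(self):
        cov = self._cov()
        table = build_signal_matrix(cov, np.zeros(cov.grid.n_bins, dtype=bool))
        assert len(table) == 0
        assert list(table.columns) == ["chrom", "start", "end", "s0", "s1"]

    def test_tsv_roundtrip_to_six_decimals(self, tmp_path):
        cov = self._cov()
        table = build_signal_matrix(cov, np.ones(cov.grid.n_bins, dtype=bool))
        p = tmp_path / "signal.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.6f")
        again = pd.read_csv(p, sep="\t")
        assert np.allclose(again[["s0", "s1"]].values, table[["s0", "s1"]].values,
                           atol=1e-6)
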