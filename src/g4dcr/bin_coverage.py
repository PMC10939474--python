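"""Genome binning, bin-level read coverage and depth normalization.

The quantitative substrate for differential-capture calling: a fixed-width
:class:`BinGrid` tiling the included chromosomes (200 bp default), raw
read-overlap counts per bin per sample, the raw-count retention filter
(>=3 and <=100 in every scoped sample by default), counts-per-million depth
normalization and positional signal profiles around region centers.

A read overlapping a bin by >= 1 bp counts once in that bin; a read spanning
k bins therefore contributes 1 to each of the k bins, so the column sum of a
coverage vector can exceed the read count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import ChromSizes, GenomicInterval, SampleMeta

__all__ = [
    "BinGrid",
    "CoverageMatrix",
    "ProfileMatrix",
    "make_bins",
    "count_coverage",
    "filter_bins",
    "normalize_depth",
    "signal_profile",
    "build_signal_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling each chromosome, in sizes-file order.

    The trailing bin of a chromosome may be narrower than `width`.  Bin rows
    are globally indexed in (chromosome order, start) order; `offsets[c]` is
    the row of the first bin of chromosome c.
    """

    chrom_sizes: ChromSizes
    width: int
    chrom_names: tuple[str, ...]
    n_bins_per_chrom: tuple[int, ...]
    offsets: tuple[int, ...]

    @property
    def n_bins(self) -> int:
        return self.offsets[-1] + self.n_bins_per_chrom[-1]

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not on the grid") from None

    def row(self, chrom: str, start: int) -> int:
        """Global row of the bin starting at `start` on `chrom`."""
        c = self.chrom_index(chrom)
        if start % self.width != 0:
            raise ValueError(f"{start} is not a bin start for width {self.width}")
        b = start // self.width
        if b >= self.n_bins_per_chrom[c]:
            raise ValueError(f"bin start {start} beyond chromosome {chrom}")
        return self.offsets[c] + b

    def bin_interval(self, row: int) -> GenomicInterval:
        c = int(np.searchsorted(self.offsets, row, side="right")) - 1
        b = row - self.offsets[c]
        chrom = self.chrom_names[c]
        start = b * self.width
        end = min(start + self.width, self.chrom_sizes[chrom])
        return GenomicInterval(chrom, start, end)

    def intervals(self) -> list[GenomicInterval]:
        return [self.bin_interval(r) for r in range(self.n_bins)]

    def frame(self) -> pd.DataFrame:
        """chrom/start/end table in grid row order."""
        chroms, starts, ends = [], [], []
        for c, chrom in enumerate(self.chrom_names):
            n = self.n_bins_per_chrom[c]
            s = np.arange(n) * self.width
            e = np.minimum(s + self.width, self.chrom_sizes[chrom])
            chroms.extend([chrom] * n)
            starts.append(s)
            ends.append(e)
        return pd.DataFrame(
            {"chrom": chroms, "start": np.concatenate(starts), "end": np.concatenate(ends)}
        )


def make_bins(chrom_sizes: ChromSizes, width: int = 200) -> BinGrid:
    """Tile every chromosome with [0,w), [w,2w), ... keeping the partial tail."""
    if width < 1:
        raise ValueError("width must be >= 1")
    names = tuple(chrom_sizes.names)
    n_per = tuple(-(-chrom_sizes[n] // width) for n in names)  # ceil division
    offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(n_per)[:-1]]))
    return BinGrid(
        chrom_sizes=chrom_sizes,
        width=width,
        chrom_names=names,
        n_bins_per_chrom=n_per,
        offsets=offsets,
    )


def count_coverage(
    reads: Iterable[GenomicInterval] | Mapping[str, np.ndarray],
    grid: BinGrid,
) -> np.ndarray:
    """Per-bin read counts: a read adds 1 to every bin it overlaps by >=1 bp.

    `reads` is either an iterable of intervals or a mapping
    chrom -> (n, 2) array of [start, end) pairs.  Reads on chromosomes
    absent from the grid are skipped with a counted warning.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    diff = np.zeros(grid.n_bins + 1, dtype=np.int64)
    skipped = 0

    def _add(chrom: str, starts: np.ndarray, ends: np.ndarray) -> None:
        nonlocal skipped
        try:
            c = grid.chrom_index(chrom)
        except KeyError:
            skipped += len(starts)
            return
        n = grid.n_bins_per_chrom[c]
        off = grid.offsets[c]
        b0 = np.clip(starts // grid.width, 0, n - 1) + off
        b1 = np.clip((ends - 1) // grid.width, 0, n - 1) + off
        np.add.at(diff, b0, 1)
        np.add.at(diff, b1 + 1, -1)

    if isinstance(reads, Mapping):
        for chrom, arr in reads.items():
            arr = np.asarray(arr)
            if arr.size:
                _add(chrom, arr[:, 0], arr[:, 1])
    else:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in reads:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            arr = np.array(pairs)
            _add(chrom, arr[:, 0], arr[:, 1])

    if skipped:
        logger.warning("count_coverage: skipped %d read(s) on chromosomes absent from the grid", skipped)
    counts += np.cumsum(diff[:-1])
    return counts


@dataclass
class CoverageMatrix:
    """Synchronous bins x samples counts with sample metadata.

    `raw` holds integer overlap counts; `normalized` is filled by
    :func:`normalize_depth` as raw * scale / library_size (counts per
    million with the default scale).  All samples share one grid.
    """

    grid: BinGrid
    samples: list[SampleMeta]
    raw: np.ndarray
    normalized: np.ndarray | None = None
    library_sizes: np.ndarray | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.raw.shape != (self.grid.n_bins, len(self.samples)):
            raise ValueError(
                f"raw shape {self.raw.shape} does not match "
                f"(n_bins={self.grid.n_bins}, n_samples={len(self.samples)})"
            )
        if np.any(self.raw < 0):
            raise ValueError("raw counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def column(self, sample_id: str, normalized: bool = False) -> np.ndarray:
        j = self.sample_ids.index(sample_id)
        if normalized:
            if self.normalized is None:
                raise ValueError("matrix has not been depth-normalized yet")
            return self.normalized[:, j]
        return self.raw[:, j]

    def select(self, predicate) -> list[int]:
        return [j for j, s in enumerate(self.samples) if predicate(s)]


def filter_bins(
    cov: CoverageMatrix,
    min_count: int = 3,
    max_count: int = 100,
    scope: Sequence[str] | None = None,
) -> np.ndarray:
    """Bins retained iff min <= raw count <= max (inclusive) in every scoped sample.

    `scope` lists sample ids; default is all samples in the matrix.
    """
    if min_count > max_count:
        raise ValueError("min_count must not exceed max_count")
    if scope is None:
        cols = slice(None)
    else:
        ids = cov.sample_ids
        missing = [s for s in scope if s not in ids]
        if missing:
            raise ValueError(f"scope samples not in matrix: {missing}")
        cols = [ids.index(s) for s in scope]
    sub = cov.raw[:, cols]
    return np.all((sub >= min_count) & (sub <= max_count), axis=1)


def normalize_depth(
    cov: CoverageMatrix,
    scale: float = 1e6,
    library_sizes: Sequence[float] | None = None,
) -> CoverageMatrix:
    """Counts-per-`scale` depth normalization (CPM with the default scale).

    Library sizes default to per-sample metadata where present, else to the
    column sums of the raw counts over all bins.
    """
    if library_sizes is None:
        lib = np.array(
            [
                s.library_size if s.library_size is not None else cov.raw[:, j].sum()
                for j, s in enumerate(cov.samples)
            ],
            dtype=float,
        )
    else:
        lib = np.asarray(library_sizes, dtype=float)
        if lib.shape != (len(cov.samples),):
            raise ValueError("one library size per sample required")
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    return CoverageMatrix(
        grid=cov.grid,
        samples=cov.samples,
        raw=cov.raw,
        normalized=cov.raw * scale / lib,
        library_sizes=lib,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# positional profiles


@dataclass
class ProfileMatrix:
    """regions x position-bins signal with per-column mean and SEM."""

    matrix: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    bin_edges: np.ndarray
    n_dropped: int = 0
    order: np.ndarray | None = None  # row order by descending row sum, if sorted

    def sorted_matrix(self) -> np.ndarray:
        order = np.argsort(-self.matrix.sum(axis=1), kind="stable")
        return self.matrix[order]


def signal_profile(
    values: np.ndarray,
    grid: BinGrid,
    centers: Sequence[GenomicInterval],
    flank: int = 5000,
    n_position_bins: int = 50,
    sort_rows: bool = False,
) -> ProfileMatrix:
    """Re-grid a per-bin track onto position bins across [center-flank, center+flank).

    Each position bin takes the length-weighted mean of the grid bins it
    overlaps.  Regions whose window leaves the chromosome are dropped with a
    warning.  Row sorting (descending total signal) is presentation only.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_bins,):
        raise ValueError("values must be one number per grid bin")
    edges = np.linspace(-flank, flank, n_position_bins + 1)
    rows = []
    dropped = 0
    for region in centers:
        try:
            c = grid.chrom_index(region.chrom)
        except KeyError:
            dropped += 1
            continue
        center = region.center
        chrom_len = grid.chrom_sizes[region.chrom]
        if center - flank < 0 or center + flank > chrom_len:
            dropped += 1
            continue
        row = np.empty(n_position_bins)
        off = grid.offsets[c]
        n_chrom_bins = grid.n_bins_per_chrom[c]
        for i in range(n_position_bins):
            a = center + edges[i]
            b = center + edges[i + 1]
            b0 = int(a // grid.width)
            b1 = int(np.ceil(b / grid.width))
            total = 0.0
            for gb in range(max(b0, 0), min(b1, n_chrom_bins)):
                gs, ge = gb * grid.width, min((gb + 1) * grid.width, chrom_len)
                ov = max(0.0, min(ge, b) - max(gs, a))
                total += values[off + gb] * ov
            row[i] = total / (b - a)
        rows.append(row)
    if dropped:
        logger.warning("signal_profile: dropped %d region(s) near a chromosome edge", dropped)
    matrix = np.array(rows) if rows else np.empty((0, n_position_bins))
    order = None
    if sort_rows and len(matrix):
        order = np.argsort(-matrix.sum(axis=1), kind="stable")
        matrix = matrix[order]
    if len(matrix):
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1) if len(matrix) > 1 else np.zeros(n_position_bins)
        sem = sd / np.sqrt(len(matrix))
    else:
        mean = np.full(n_position_bins, np.nan)
        sem = np.full(n_position_bins, np.nan)
    return ProfileMatrix(matrix=matrix, mean=mean, sem=sem, bin_edges=edges,
                         n_dropped=dropped, order=order)


def build_signal_matrix(cov: CoverageMatrix, mask: np.ndarray) -> pd.DataFrame:
    """Masked per-bin normalized signal table, in grid order, ready for TSV export."""
    if cov.normalized is None:
        raise ValueError("normalize the matrix before exporting signals")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (cov.grid.n_bins,):
        raise ValueError("mask length must equal the number of bins")
    frame = cov.grid.frame().loc[mask].reset_index(drop=True)
    sig = pd.DataFrame(cov.normalized[mask], columns=cov.sample_ids)
    return pd.concat([frame, sig], axis=1)
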