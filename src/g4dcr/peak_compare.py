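"""Peak-set and region-set comparison statistics.

Interval Jaccard (total intersection length over total union length of two
merged sets, strand-blind), reciprocal >=70%-of-own-length overlap fractions,
matched-length random-region sampling for null comparisons, and the share of
a genome-wide signal track that falls inside a region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bin_coverage import BinGrid
from .io_core import ChromSizes, GenomicInterval

__all__ = [
    "OverlapSummary",
    "merge_intervals",
    "interval_jaccard",
    "reciprocal_overlap",
    "sample_random_regions",
    "region_signal_share",
]


@dataclass
class OverlapSummary:
    intersection_bp: int = 0
    union_bp: int = 0
    jaccard: float = float("nan")
    n_A: int = 0
    n_B: int = 0
    n_A_hit: int = 0
    n_B_hit: int = 0
    frac_A_hit: float = float("nan")
    frac_B_hit: float = float("nan")
    min_frac: float | None = None


def merge_intervals(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge overlapping/adjacent-overlapping intervals per chromosome.

    Returns chrom -> (n, 2) sorted arrays of disjoint [start, end) spans.
    Strand is ignored.  Touching intervals ([0,10) and [10,20)) are kept
    separate; only genuine overlap merges.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[list[int]] = []
        for s, e in spans:
            if out and s < out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out)
    return merged


def _total_length(merged: dict[str, np.ndarray]) -> int:
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in merged.values()))


def _intersection_length(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlap length between two sorted disjoint span arrays."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def _span_overlap(span: tuple[int, int], merged: np.ndarray) -> int:
    """Overlap of one [start, end) span with a sorted disjoint span array."""
    if merged is None or not len(merged):
        return 0
    s, e = span
    lo = int(np.searchsorted(merged[:, 1], s, side="right"))
    total = 0
    for k in range(lo, len(merged)):
        if merged[k, 0] >= e:
            break
        total += min(e, merged[k, 1]) - max(s, merged[k, 0])
    return total


def interval_jaccard(
    A: Sequence[GenomicInterval], B: Sequence[GenomicInterval]
) -> OverlapSummary:
    """Jaccard index of two interval sets, each merged first; strand ignored."""
    if not A and not B:
        raise ValueError("Jaccard is undefined for two empty sets")
    mA = merge_intervals(A)
    mB = merge_intervals(B)
    inter = sum(
        _intersection_length(mA[c], mB[c]) for c in set(mA) & set(mB)
    )
    union = _total_length(mA) + _total_length(mB) - inter
    return OverlapSummary(
        intersection_bp=int(inter),
        union_bp=int(union),
        jaccard=inter / union if union else float("nan"),
        n_A=len(A),
        n_B=len(B),
    )


def reciprocal_overlap(
    A: Sequence[GenomicInterval],
    B: Sequence[GenomicInterval],
    min_frac: float = 0.70,
) -> OverlapSummary:
    """Fraction of A (and of B) covered >= min_frac of their own length.

    An A interval is a hit when its total intersection with merged B reaches
    at least ``min_frac`` of its own length (inclusive); intersections with
    fragmented B pieces are summed first.  Both directions are reported.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    mA = merge_intervals(A)
    mB = merge_intervals(B)

    def _hits(queries: Sequence[GenomicInterval], target: dict[str, np.ndarray]) -> int:
        n = 0
        for iv in queries:
            ov = _span_overlap((iv.start, iv.end), target.get(iv.chrom))
            if ov >= min_frac * iv.length:
                n += 1
        return n

    n_A_hit = _hits(A, mB)
    n_B_hit = _hits(B, mA)
    return OverlapSummary(
        n_A=len(A),
        n_B=len(B),
        n_A_hit=n_A_hit,
        n_B_hit=n_B_hit,
        frac_A_hit=n_A_hit / len(A) if A else float("nan"),
        frac_B_hit=n_B_hit / len(B) if B else float("nan"),
        min_frac=min_frac,
    )


def sample_random_regions(
    chrom_sizes: ChromSizes,
    n: int,
    length_source: int | Sequence[GenomicInterval],
    seed: int,
    exclude: Sequence[GenomicInterval] | None = None,
    max_attempts: int = 1000,
) -> list[GenomicInterval]:
    """Uniformly placed random regions, optionally avoiding an exclusion set.

    Placement is proportional to chromosome length and regions lie fully
    inside chromosomes.  `length_source` is either one fixed length or a
    template peak set whose empirical lengths are resampled (matched-length
    nulls).  Overlap with `exclude` is avoided by rejection sampling; failure
    after `max_attempts` tries per region raises, reporting how many regions
    were placed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(length_source, (int, np.integer)):
        lengths = np.full(n, int(length_source))
    else:
        pool = np.array([iv.length for iv in length_source])
        if not len(pool):
            raise ValueError("empty template peak set")
        lengths = rng.choice(pool, size=n, replace=True)
    excl = merge_intervals(exclude) if exclude else {}
    names = chrom_sizes.names
    sizes = np.array([chrom_sizes[c] for c in names], dtype=float)
    weights = sizes / sizes.sum()
    out: list[GenomicInterval] = []
    for i in range(n):
        length = int(lengths[i])
        placed = False
        for _ in range(max_attempts):
            c = int(rng.choice(len(names), p=weights))
            chrom = names[c]
            hi = chrom_sizes[chrom] - length
            if hi < 0:
                continue
            start = int(rng.integers(0, hi + 1))
            if excl and _span_overlap((start, start + length), excl.get(chrom)) > 0:
                continue
            out.append(GenomicInterval(chrom, start, start + length, name=f"random_{i}"))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place region {i} after {max_attempts} attempts "
                f"({len(out)} placed so far)"
            )
    return out


def region_signal_share(
    values: np.ndarray,
    grid: BinGrid,
    regions: Sequence[GenomicInterval],
) -> float:
    """Fraction of genome-wide signal mass falling inside `regions`.

    Partial overlap of a bin is pro-rated by overlapped length fraction,
    which removes bin-phase artifacts.  The track total must be positive.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_bins,):
        raise ValueError("values must be one number per grid bin")
    total = values.sum()
    if total <= 0:
        raise ValueError("total signal must be positive")
    merged = merge_intervals(regions) if regions else {}
    inside = 0.0
    for chrom, spans in merged.items():
        try:
            c = grid.chrom_index(chrom)
        except KeyError:
            continue
        off = grid.offsets[c]
        chrom_len = grid.chrom_sizes[chrom]
        n = grid.n_bins_per_chrom[c]
        for s, e in spans:
            e = min(int(e), chrom_len)
            b0 = int(s) // grid.width
            b1 = (e - 1) // grid.width
            for gb in range(b0, min(b1 + 1, n)):
                gs = gb * grid.width
                ge = min(gs + grid.width, chrom_len)
                ov = min(ge, e) - max(gs, int(s))
                if ov > 0:
                    inside += values[off + gb] * ov / (ge - gs)
    return float(inside / total)
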