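"""Sequence-property scores for G-quadruplex biology.

Implements the canonical quadruplex signature scan ((G3-N1-7)x4 by default:
four tracts of >=3 guanines separated by 1-7 nt spacers on one strand),
per-window G/C-skew ((G-C)/(G+C)), GC-content profiles around region centers,
and the GGG/CCC weighted content score for peak sets
((overlapping GGG count + overlapping CCC count) x read coverage).

Scanner semantics
-----------------
G-tracts are *maximal* runs: a stretch of k >= run_len consecutive Gs is one
tract, never split.  A hit chains ``n_runs`` consecutive maximal tracts whose
inter-tract gaps all lie in [spacer_min, spacer_max].  Enumeration is
leftmost-greedy and hits never overlap within a strand, so the reported count
is the number of disjoint matches (this is what makes a sequence with three
unit repeats count as exactly three hits).  Reverse-strand hits are found by
matching the C-tract mirror pattern on the given sequence and reported with
strand '-' in input-sequence coordinates.  N (or any non-G) breaks a tract
and counts toward the spacer; a tetrad is never invented across unknown bases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_core import GenomicInterval

__all__ = [
    "MotifHit",
    "SkewBin",
    "WeightedContentRecord",
    "reverse_complement",
    "scan_quadruplex_signature",
    "has_quadruplex_signature",
    "compute_gc_skew",
    "gc_content_profile",
    "count_overlapping",
    "weighted_ggg_ccc_content",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One quadruplex-signature match.

    Coordinates are 0-based offsets into the scanned sequence (plus the
    optional `chrom` label).  `g_runs` lists (start, length) for each tract in
    order; `spacers` the gaps between consecutive tracts.
    """

    start: int
    end: int
    strand: str
    g_runs: tuple[tuple[int, int], ...]
    spacers: tuple[int, ...]
    chrom: str | None = None

    def to_interval(self, chrom: str | None = None) -> GenomicInterval:
        c = chrom or self.chrom
        if c is None:
            raise ValueError("no chromosome name available for this hit")
        return GenomicInterval(c, self.start, self.end, strand=self.strand)


def _maximal_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of `base` with length >= min_len."""
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(f"{base}{{{min_len},}}", seq)
    ]


def _scan_one_strand(
    seq: str, base: str, strand: str, run_len: int,
    spacer_min: int, spacer_max: int, n_runs: int,
) -> list[MotifHit]:
    runs = _maximal_runs(seq, base, run_len)
    hits: list[MotifHit] = []
    i = 0
    while i + n_runs <= len(runs):
        ok = True
        spacers = []
        for j in range(i, i + n_runs - 1):
            gap = runs[j + 1][0] - (runs[j][0] + runs[j][1])
            if not (spacer_min <= gap <= spacer_max):
                ok = False
                break
            spacers.append(gap)
        if ok:
            chain = tuple(runs[i : i + n_runs])
            hits.append(
                MotifHit(
                    start=chain[0][0],
                    end=chain[-1][0] + chain[-1][1],
                    strand=strand,
                    g_runs=chain,
                    spacers=tuple(spacers),
                )
            )
            i += n_runs  # leftmost-greedy: consume the tracts of this hit
        else:
            i += 1
    return hits


def scan_quadruplex_signature(
    sequence: str,
    run_len: int = 3,
    spacer_min: int = 1,
    spacer_max: int = 7,
    n_runs: int = 4,
    strand_mode: str = "both",
    chrom: str | None = None,
) -> list[MotifHit]:
    """Scan a sequence for the canonical quadruplex signature.

    Parameters default to the (G3-N1-7)x4 definition.  `strand_mode` is one
    of 'forward', 'reverse', 'both'; reverse-strand hits are C-tract matches
    on the given sequence, reported with strand '-'.  Hits come back sorted
    by start; an empty sequence yields an empty list.
    """
    if run_len < 2:
        raise ValueError("run_len must be >= 2")
    if not (0 <= spacer_min <= spacer_max):
        raise ValueError("require 0 <= spacer_min <= spacer_max")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if strand_mode not in ("forward", "reverse", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = sequence.upper()
    hits: list[MotifHit] = []
    if strand_mode in ("forward", "both"):
        hits.extend(_scan_one_strand(seq, "G", "+", run_len, spacer_min, spacer_max, n_runs))
    if strand_mode in ("reverse", "both"):
        hits.extend(_scan_one_strand(seq, "C", "-", run_len, spacer_min, spacer_max, n_runs))
    hits.sort(key=lambda h: (h.start, h.strand))
    if chrom is not None:
        hits = [
            MotifHit(h.start, h.end, h.strand, h.g_runs, h.spacers, chrom=chrom)
            for h in hits
        ]
    return hits


def has_quadruplex_signature(sequence: str, **kwargs) -> bool:
    """Per-sequence presence/absence flag (read-level summaries use this)."""
    return bool(scan_quadruplex_signature(sequence, **kwargs))


# ---------------------------------------------------------------------------
# G/C skew


@dataclass(frozen=True)
class SkewBin:
    """One skew window: G and C counts and (G-C)/(G+C), or excluded."""

    interval: GenomicInterval
    g_count: int
    c_count: int
    skew: float | None
    excluded: bool


def compute_gc_skew(
    sequence: str,
    bin_width: int = 100,
    chrom: str = "seq",
    offset: int = 0,
    zero_rule: str = "either",
) -> list[SkewBin]:
    """Per-window G/C-skew of a sequence.

    Windows start at `offset` and tile the sequence; a trailing partial
    window is kept at its true width.  A window is *excluded* (no skew value)
    when its G count or its C count is zero under the default
    ``zero_rule='either'``; ``zero_rule='both'`` only excludes windows with
    neither base, where the formula itself is undefined.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if zero_rule not in ("either", "both"):
        raise ValueError("zero_rule must be 'either' or 'both'")
    seq = sequence.upper()
    out: list[SkewBin] = []
    for s in range(0, len(seq), bin_width):
        window = seq[s : s + bin_width]
        g = window.count("G")
        c = window.count("C")
        excluded = (g == 0 or c == 0) if zero_rule == "either" else (g == 0 and c == 0)
        skew = None if excluded else (g - c) / (g + c)
        out.append(
            SkewBin(
                interval=GenomicInterval(chrom, offset + s, offset + s + len(window)),
                g_count=g,
                c_count=c,
                skew=skew,
                excluded=excluded,
            )
        )
    return out


# ---------------------------------------------------------------------------
# GC-content profile


@dataclass
class ProfileResult:
    """regions x position-bins matrix with per-column mean and SEM."""

    matrix: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    bin_edges: np.ndarray  # offsets relative to region center, len = n_bins + 1
    n_dropped: int = 0


def gc_content_profile(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    flank: int = 2000,
    n_position_bins: int = 40,
) -> ProfileResult:
    """GC fraction (G+C)/(A+C+G+T) per position bin around region centers.

    The window [center - flank, center + flank) is cut into equal position
    bins.  Regions whose window would run off a chromosome end are dropped
    with a logged warning.  N bases count in neither numerator nor
    denominator; an all-N position bin contributes NaN.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if n_position_bins < 1:
        raise ValueError("n_position_bins must be >= 1")
    edges = np.linspace(-flank, flank, n_position_bins + 1).astype(int)
    rows: list[np.ndarray] = []
    dropped = 0
    for region in regions:
        seq = genome.get(region.chrom)
        if seq is None:
            raise KeyError(f"chromosome {region.chrom!r} not in genome")
        center = region.center
        if center - flank < 0 or center + flank > len(seq):
            dropped += 1
            continue
        row = np.empty(n_position_bins)
        for i in range(n_position_bins):
            window = seq[center + edges[i] : center + edges[i + 1]].upper()
            gc = window.count("G") + window.count("C")
            acgt = gc + window.count("A") + window.count("T")
            row[i] = gc / acgt if acgt else np.nan
        rows.append(row)
    if dropped:
        logger.warning("gc_content_profile: dropped %d region(s) too close to a chromosome end", dropped)
    matrix = np.array(rows) if rows else np.empty((0, n_position_bins))
    if len(matrix):
        mean = np.nanmean(matrix, axis=0)
        n = np.sum(~np.isnan(matrix), axis=0)
        sd = np.nanstd(matrix, axis=0, ddof=1) if len(matrix) > 1 else np.zeros(n_position_bins)
        sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    else:
        mean = np.full(n_position_bins, np.nan)
        sem = np.full(n_position_bins, np.nan)
    return ProfileResult(matrix=matrix, mean=mean, sem=sem, bin_edges=edges, n_dropped=dropped)


# ---------------------------------------------------------------------------
# GGG/CCC weighted content


def count_overlapping(seq: str, pattern: str) -> int:
    """Occurrences of `pattern` sliding one base at a time ('GGGG' has 2 GGG)."""
    count = 0
    pos = seq.find(pattern)
    while pos != -1:
        count += 1
        pos = seq.find(pattern, pos + 1)
    return count


@dataclass(frozen=True)
class WeightedContentRecord:
    """GGG/CCC weighted content of one peak.

    weighted_content = (ggg_count + ccc_count) * coverage; peaks lacking
    either pattern entirely are flagged `discarded` and excluded from score
    distributions.
    """

    peak: GenomicInterval
    ggg_count: int
    ccc_count: int
    coverage: float
    weighted_content: float
    discarded: bool


def weighted_ggg_ccc_content(
    peaks: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    coverage_per_peak: Sequence[float],
) -> list[WeightedContentRecord]:
    """Score every peak; records with zero GGG or zero CCC are discarded."""
    if len(peaks) != len(coverage_per_peak):
        raise ValueError("coverage must be provided for every peak")
    out: list[WeightedContentRecord] = []
    for peak, cov in zip(peaks, coverage_per_peak):
        seq = genome.get(peak.chrom)
        if seq is None or peak.end > len(seq):
            raise ValueError(
                f"sequence unavailable for peak {peak.chrom}:{peak.start}-{peak.end}"
            )
        sub = seq[peak.start : peak.end].upper()
        ggg = count_overlapping(sub, "GGG")
        ccc = count_overlapping(sub, "CCC")
        discarded = ggg == 0 or ccc == 0
        out.append(
            WeightedContentRecord(
                peak=peak,
                ggg_count=ggg,
                ccc_count=ccc,
                coverage=float(cov),
                weighted_content=(ggg + ccc) * float(cov),
                discarded=discarded,
            )
        )
    return out
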