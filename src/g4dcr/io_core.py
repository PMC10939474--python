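"""Genomic interval / sequence data model and plain-text format I/O.

Everything downstream works on three small value types: :class:`GenomicInterval`
(0-based half-open, BED convention), :class:`ChromSizes` (ordered chromosome
name -> length map with an optional inclusion list) and :class:`SampleMeta`
(condition / replicate-batch / role bookkeeping for ChIP-style designs).

Formats handled here are the uncompressed text exchange forms: BED3-BED6,
FASTA, bedGraph, two-column chrom.sizes and a tab-separated sample sheet.
BAM/bigWig are deliberately out of scope; reads arrive as interval lists.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "SampleMeta",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_sample_sheet",
]

VALID_STRANDS = ("+", "-", ".")

# Full nucleotide alphabet accepted on FASTA read (soft-masked input is
# uppercased, not rejected: masking is ignored).
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


class BedParseError(ValueError):
    """Malformed record in a BED-like file; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class ChromSizes(Mapping[str, int]):
    """Ordered chromosome name -> length map.

    An inclusion list mirrors the common practice of dropping unannotated,
    mitochondrial or sex chromosomes from an analysis without editing the
    sizes file itself.
    """

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        self._sizes: "OrderedDict[str, int]" = OrderedDict()
        items = sizes.items() if isinstance(sizes, Mapping) else sizes
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._sizes[name] = length
        if not self._sizes:
            raise ValueError("ChromSizes is empty")

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def restrict(self, include: Sequence[str]) -> "ChromSizes":
        keep = [(n, l) for n, l in self._sizes.items() if n in set(include)]
        if not keep:
            raise ValueError("no chromosomes left after applying the inclusion list")
        return ChromSizes(keep)

    def validate(self, interval: GenomicInterval) -> None:
        """Raise if the interval is off this genome."""
        if interval.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self._sizes[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {self._sizes[interval.chrom]}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: condition (CT/KD), replicate batch, role."""

    sample_id: str
    condition: str
    replicate: str
    role: str
    library_size: int | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("chip", "input"):
            raise ValueError(f"role must be 'chip' or 'input', got {self.role!r}")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library size must be positive when given")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-BED6 into intervals, preserving file order.

    Columns 4-6 map to name/score/strand when present.  Malformed lines and
    empty intervals raise :class:`BedParseError` naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def _format_score(score: float) -> str:
    return f"{score:g}"


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, emitting only the columns actually populated."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                fields.append(_format_score(iv.score) if iv.score is not None else ".")
            if iv.strand != ".":
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> "OrderedDict[str, str]":
    """Read a (multi-)FASTA into an ordered name -> uppercased sequence map.

    Lowercase (soft-masked) input is accepted and uppercased.  Duplicate
    record names, empty files and non-IUPAC characters are errors.
    """
    records: "OrderedDict[str, str]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path, include: Sequence[str] | None = None) -> ChromSizes:
    """Read a two-column name/length file, optionally keeping only `include`."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length") from exc
    sizes = ChromSizes(pairs)
    if include is not None:
        sizes = sizes.restrict(include)
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    bins: Sequence[GenomicInterval],
    values: Sequence[float],
    path: str | Path,
    mask: Sequence[bool] | None = None,
) -> None:
    """Write a four-column bedGraph; masked-out bins are omitted, not zeroed.

    `mask[i]` True means "write bin i".  Bins must be sorted and
    non-overlapping within each chromosome.
    """
    if len(bins) != len(values):
        raise ValueError("bins and values differ in length")
    if mask is not None and len(mask) != len(bins):
        raise ValueError("mask length does not match bins")
    last: dict[str, int] = {}
    for iv in bins:
        if iv.start < last.get(iv.chrom, 0) and iv.chrom in last:
            raise ValueError(f"overlapping or unsorted bins at {iv.chrom}:{iv.start}")
        last[iv.chrom] = iv.end
    with open(path, "w") as fh:
        for i, iv in enumerate(bins):
            if mask is not None and not mask[i]:
                continue
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{values[i]:.6g}\n")


def read_bedgraph(path: str | Path) -> tuple[list[GenomicInterval], list[float]]:
    bins: list[GenomicInterval] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            bins.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            values.append(float(fields[3]))
    return bins, values


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a tab-separated sample sheet: id, condition, replicate, role[, path].

    A header line starting with 'sample' or '#' is skipped.  The
    (condition, replicate, role) triple must be unique.
    """
    samples: list[SampleMeta] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("sample", "sample_id", "id"):
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            sid, condition, replicate, role = fields[:4]
            key = (condition, replicate, role)
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate (condition, replicate, role) {key}")
            seen.add(key)
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    condition=condition,
                    replicate=replicate,
                    role=role,
                    path=fields[4] if len(fields) > 4 else None,
                )
            )
    if not samples:
        raise ValueError(f"sample sheet {path} is empty")
    return samples
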