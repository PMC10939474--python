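"""Desk-scale synthetic inputs for the whole pipeline.

Three generators live here:

* :func:`packaged_fixtures` — the published control/carrier constructs and
  oligonucleotides, byte-for-byte as printed: a 272 nt Control DNA carrying
  three repeats of the canonical (G3-N5)x3-G3 signature unit between T7 and
  SP6 ends, a same-length carrier DNA in which every tetrad-forming GGG is
  replaced by ATG, the 27 nt signature oligo and its reverse complement, and
  the primer sequences.

* :func:`make_toy_genome` — a small multi-chromosome genome of i.i.d.
  nucleotides at a configurable GC fraction with planted signature regions
  (the Control-DNA unit design), planted G-skewed regions, and a truth record
  of every placement.

* :func:`simulate_experiment` — CT/KD ChIP plus matched input replicate
  libraries in paired batches.  Per bin, batch and condition the expected
  chip count is depth x batch factor x (1 + enrichment at planted G4
  regions), multiplied (gain) or divided (loss) by the effect multiplier in
  KD at planted differential bins; inputs share the batch factor but carry
  neither enrichment nor effect — that shared factor is exactly what makes
  the paired chip-minus-input analysis the right test.  Counts are negative
  binomial (overdispersed, the realistic default) or Poisson, realized as
  fixed-length reads laid flush within their bin so per-bin read counts
  equal the drawn counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bin_coverage import BinGrid, CoverageMatrix, count_coverage, make_bins
from .io_core import ChromSizes, GenomicInterval, SampleMeta

__all__ = [
    "CONTROL_DNA",
    "CARRIER_DNA",
    "OLIGO1",
    "OLIGO2",
    "T7_PRIMER",
    "SP6_PRIMER",
    "QPCR_PRIMER_F",
    "QPCR_PRIMER_R",
    "packaged_fixtures",
    "SimConfig",
    "SyntheticTruth",
    "make_toy_genome",
    "simulate_experiment",
    "SimulatedExperiment",
]

# Published construct and oligo sequences, verbatim.
CONTROL_DNA = (
    "TAATACGACTCACTATAGGGCACCCCTACATCGCAGCGGTCTTTCGGGCTAACGGGATCATGGGACTCAGGG"
    "GACAGCCTCAAGCAACATGCCCAGTCCTGACCTTCAATAAGGAAGCAAACTGGGAAGGAGGGTGTCAGGGAT"
    "AAAGGGGAGTCCTAGTCAAGGTGTCGGATGTCCTAAGACTTATGATCATTTTCTTAGGGTCTAAGGGCTCGA"
    "GGGTCTGCGGGTCGGTTTCCTTCTAGAATTAGTATCTTCTATAGTGTCACCTAAAT"
)
CARRIER_DNA = (
    "TAATACGACTCACTATAGGGCACCCCTACATCGCAGCGGTCTTTCATGCTAACATGATCATATGACTCAATG"
    "GACAGCCTCAAGCAACATGCCCAGTCCTGACCTTCAATAAGGAAGCAAACTATGAAGGAATGTGTCAATGAT"
    "AAAATGGAGTCCTAGTCAAGGTGTCGGATGTCCTAAGACTTATGATCATTTTCTTAATGTCTAAATGCTCGA"
    "ATGTCTGCATGTCGGTTTCCTTCTAGAATTAGTATCTTCTATAGTGTCACCTAAAT"
)
OLIGO1 = "GGGTCTAAGGGCTCGAGGGTCTGCGGG"
OLIGO2 = "CCCGCAGACCCTCGAGCCCTTAGACCC"
T7_PRIMER = "TAATACGACTCACTATAGGG"
SP6_PRIMER = "ATTTAGGTGACACTATAGAA"
QPCR_PRIMER_F = "CAGCCTCAAGCAACATGCCCAGTC"
QPCR_PRIMER_R = "AGTTTGCTTCCTTATTGAAGG"


def packaged_fixtures() -> dict[str, str]:
    """Named published sequences, byte-for-byte as printed."""
    return {
        "control": CONTROL_DNA,
        "carrier": CARRIER_DNA,
        "oligo1": OLIGO1,
        "oligo2": OLIGO2,
        "t7_primer": T7_PRIMER,
        "sp6_primer": SP6_PRIMER,
        "qpcr_primer_f": QPCR_PRIMER_F,
        "qpcr_primer_r": QPCR_PRIMER_R,
    }


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the published design where it states one (200 bp bins,
    three paired CT/KD batches with matched inputs, effect multiplier 3,
    background bin depth 20, the G3-N5 unit signature) and realistic choices
    elsewhere (human-like 41% GC background, negative-binomial counts with
    size 10, log-normal batch factors with sigma 0.2).
    """

    chrom_lengths: tuple[int, ...] = (150_000, 120_000, 100_000)
    bin_width: int = 200
    gc_fraction: float = 0.41
    # planted quadruplex-signature regions
    n_g4_regions: int = 220
    g4_region_length: int = 200
    signature_run_len: int = 3
    signature_spacer: int = 5
    signature_n_runs: int = 4
    # planted skewed regions (G-biased forward strand)
    n_skew_regions: int = 10
    skew_region_length: int = 1000
    skew_g_fraction: float = 0.4  # per-base G probability inside skew regions
    # planted differential bins
    n_dcr_bins: int = 200
    gain_fraction: float = 1.0
    effect_multiplier: float = 3.0
    # depth / noise
    depth: float = 20.0
    input_depth: float = 20.0
    base_enrichment: float = 0.25
    n_batches: int = 3
    dispersion: str = "nb"  # 'nb' | 'poisson'
    nb_size: float = 10.0
    batch_sd: float = 0.2
    read_length: int | None = None  # defaults to bin_width

    def __post_init__(self) -> None:
        if self.effect_multiplier <= 0:
            raise ValueError("effect multiplier must be positive")
        if not (0 <= self.gain_fraction <= 1):
            raise ValueError("gain_fraction must be in [0, 1]")
        if self.dispersion not in ("nb", "poisson"):
            raise ValueError("dispersion must be 'nb' or 'poisson'")
        if self.n_dcr_bins > self.n_g4_regions:
            raise ValueError(
                "planted differential bins sit inside planted G4 regions; "
                "n_dcr_bins must not exceed n_g4_regions"
            )

    @property
    def batch_labels(self) -> list[str]:
        base = ["nuc", "tr", "ut"]
        if self.n_batches <= 3:
            return base[: self.n_batches]
        return base + [f"b{i}" for i in range(4, self.n_batches + 1)]


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic genome: every planted placement."""

    chrom_sizes: ChromSizes
    g4_regions: list[GenomicInterval]
    skew_regions: list[GenomicInterval]
    dcr_bins: list[GenomicInterval]  # name = direction, score = multiplier
    grid: BinGrid

    def dcr_rows(self) -> np.ndarray:
        return np.array([self.grid.row(iv.chrom, iv.start) for iv in self.dcr_bins])

    def g4_region_rows(self) -> np.ndarray:
        # regions are bin-aligned, possibly spanning several bins
        rows = []
        for iv in self.g4_regions:
            first = self.grid.row(iv.chrom, iv.start)
            nbins = -(-(iv.end - iv.start) // self.grid.width)
            rows.extend(range(first, first + nbins))
        return np.array(sorted(set(rows)))


def _signature_unit(rng: np.random.Generator, run_len: int, spacer: int, n_runs: int) -> str:
    """One canonical unit, e.g. GGG-N5-GGG-N5-GGG-N5-GGG with non-G spacers."""
    parts = []
    for i in range(n_runs):
        parts.append("G" * run_len)
        if i < n_runs - 1:
            parts.append("".join(rng.choice(list("ACT"), size=spacer)))
    return "".join(parts)


def make_toy_genome(
    config: SimConfig, seed: int
) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate the toy genome and its truth record; deterministic per seed."""
    rng = np.random.default_rng(seed)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))

    names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    sizes = ChromSizes(zip(names, config.chrom_lengths))
    grid = make_bins(sizes, config.bin_width)

    genome: dict[str, list[str]] = {}
    for name, length in sizes.items():
        genome[name] = list(rng.choice(alphabet, size=length, p=probs))

    # choose non-overlapping bin-aligned slots for G4 and skew regions
    w = config.bin_width
    g4_bins_per_region = -(-config.g4_region_length // w)
    skew_bins_per_region = -(-config.skew_region_length // w)
    slot_rows = np.arange(grid.n_bins)
    rng.shuffle(slot_rows)
    taken = np.zeros(grid.n_bins, dtype=bool)

    def _claim(n_regions: int, span: int) -> list[int]:
        rows: list[int] = []
        for r in slot_rows:
            if len(rows) == n_regions:
                break
            r = int(r)
            iv = grid.bin_interval(r)
            c = grid.chrom_index(iv.chrom)
            last = grid.offsets[c] + grid.n_bins_per_chrom[c]
            if r + span > last:
                continue
            if taken[r : r + span].any():
                continue
            # region must lie fully inside the chromosome at full bin width
            if grid.bin_interval(r + span - 1).length < w:
                continue
            taken[r : r + span] = True
            rows.append(r)
        if len(rows) < n_regions:
            raise RuntimeError(
                f"could not place {n_regions} non-overlapping regions "
                f"(placed {len(rows)})"
            )
        return rows

    g4_rows = _claim(config.n_g4_regions, g4_bins_per_region)
    skew_rows = _claim(config.n_skew_regions, skew_bins_per_region)

    g4_regions: list[GenomicInterval] = []
    for r in sorted(g4_rows):
        iv0 = grid.bin_interval(r)
        start, end = iv0.start, iv0.start + config.g4_region_length
        region = GenomicInterval(iv0.chrom, start, end, name="g4_region")
        unit = _signature_unit(
            rng, config.signature_run_len, config.signature_spacer, config.signature_n_runs
        )
        mid = start + (region.length - len(unit)) // 2
        seq = genome[iv0.chrom]
        seq[mid : mid + len(unit)] = list(unit)
        # guard bases so flanking genomic Gs cannot extend the outer tracts
        if mid > start:
            seq[mid - 1] = "T"
        if mid + len(unit) < end:
            seq[mid + len(unit)] = "T"
        g4_regions.append(region)

    skew_probs = np.array(
        [
            (1 - gc) / 2,
            gc - config.skew_g_fraction if gc > config.skew_g_fraction else gc * 0.2,
            0.0,
            (1 - gc) / 2,
        ]
    )
    skew_probs[2] = config.skew_g_fraction if gc > config.skew_g_fraction else gc * 0.8
    skew_probs = skew_probs / skew_probs.sum()
    # order: A, C, G, T -> G-biased forward strand
    skew_alphabet = np.array(list("ACGT"))
    skew_regions: list[GenomicInterval] = []
    for r in sorted(skew_rows):
        iv0 = grid.bin_interval(r)
        start, end = iv0.start, iv0.start + config.skew_region_length
        genome[iv0.chrom][start:end] = list(
            rng.choice(skew_alphabet, size=end - start, p=skew_probs[[0, 1, 2, 3]])
        )
        skew_regions.append(GenomicInterval(iv0.chrom, start, end, name="skew_region"))

    # planted differential bins: first bin of a subset of G4 regions
    chosen = sorted(rng.choice(len(g4_regions), size=config.n_dcr_bins, replace=False))
    n_gain = int(round(config.gain_fraction * config.n_dcr_bins))
    directions = ["gain-in-KD"] * n_gain + ["loss-in-KD"] * (config.n_dcr_bins - n_gain)
    rng.shuffle(directions)
    dcr_bins = []
    for k, idx in enumerate(chosen):
        region = g4_regions[idx]
        iv = grid.bin_interval(grid.row(region.chrom, region.start))
        dcr_bins.append(
            GenomicInterval(
                iv.chrom, iv.start, iv.end,
                name=directions[k], score=config.effect_multiplier,
            )
        )

    genome_str = {name: "".join(seq) for name, seq in genome.items()}
    truth = SyntheticTruth(
        chrom_sizes=sizes,
        g4_regions=g4_regions,
        skew_regions=skew_regions,
        dcr_bins=dcr_bins,
        grid=grid,
    )
    return genome_str, truth


@dataclass
class SimulatedExperiment:
    """Reads, drawn counts and metadata of one simulated run."""

    samples: list[SampleMeta]
    reads: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> (n, 2) spans
    counts: dict[str, np.ndarray]  # sample -> per-bin drawn counts
    grid: BinGrid

    def coverage_matrices(self) -> tuple[CoverageMatrix, CoverageMatrix]:
        """(chip, input) coverage matrices built from the simulated reads."""

        def _matrix(role: str) -> CoverageMatrix:
            sel = [s for s in self.samples if s.role == role]
            raw = np.column_stack(
                [count_coverage(self.reads[s.sample_id], self.grid) for s in sel]
            )
            return CoverageMatrix(grid=self.grid, samples=sel, raw=raw)

        return _matrix("chip"), _matrix("input")

    def read_intervals(self, sample_id: str) -> list[GenomicInterval]:
        out = []
        for chrom, spans in self.reads[sample_id].items():
            out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in spans)
        return out


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.dispersion == "poisson":
        return rng.poisson(lam)
    size = config.nb_size
    p = size / (size + lam)
    return rng.negative_binomial(size, p)


def simulate_experiment(
    truth: SyntheticTruth, config: SimConfig, seed: int
) -> SimulatedExperiment:
    """Simulate CT/KD chip + matched input replicate libraries.

    Batch factors (log-normal, sigma = `batch_sd`) are drawn per (batch,
    condition) and shared between a chip library and its matched input.
    Reads are `read_length` long (default one bin) and laid flush with the
    bin start, so bin counts equal drawn counts exactly.
    """
    if config.depth <= 0 or config.input_depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    n = grid.n_bins
    read_len = config.read_length or config.bin_width

    enrich = np.ones(n)
    enrich[truth.g4_region_rows()] += config.base_enrichment
    effect_kd = np.ones(n)
    for iv in truth.dcr_bins:
        r = grid.row(iv.chrom, iv.start)
        m = iv.score or config.effect_multiplier
        effect_kd[r] = m if iv.name == "gain-in-KD" else 1.0 / m

    samples: list[SampleMeta] = []
    reads: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[str, np.ndarray] = {}

    for batch in config.batch_labels:
        for cond in ("CT", "KD"):
            factor = float(np.exp(rng.normal(0.0, config.batch_sd)))
            lam_chip = config.depth * factor * enrich
            if cond == "KD":
                lam_chip = lam_chip * effect_kd
            lam_input = config.input_depth * factor * np.ones(n)
            for role, lam in (("chip", lam_chip), ("input", lam_input)):
                sid = f"{cond}_{batch}_{role}"
                c = _draw_counts(rng, lam, config)
                counts[sid] = c
                by_chrom: dict[str, np.ndarray] = {}
                for ci, chrom in enumerate(grid.chrom_names):
                    off = grid.offsets[ci]
                    nb = grid.n_bins_per_chrom[ci]
                    cc = c[off : off + nb]
                    bins = np.nonzero(cc)[0]
                    starts = np.repeat(bins * grid.width, cc[bins])
                    chrom_len = grid.chrom_sizes[chrom]
                    if read_len < grid.width and len(starts):
                        # uniform placement inside the bin, read fully contained
                        starts = starts + rng.integers(
                            0, grid.width - read_len + 1, size=len(starts)
                        )
                    ends = np.minimum(starts + read_len, chrom_len)
                    starts = np.minimum(starts, np.maximum(ends - 1, 0))
                    by_chrom[chrom] = np.column_stack([starts, ends])
                reads[sid] = by_chrom
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        condition=cond,
                        replicate=batch,
                        role=role,
                        library_size=int(c.sum()) or None,
                    )
                )
    return SimulatedExperiment(samples=samples, reads=reads, counts=counts, grid=grid)
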