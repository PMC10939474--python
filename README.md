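# g4dcr

Bin-level differential G-quadruplex (G4) capture analysis for ChIP-style
experiments, plus the G4 sequence-property scores used to characterize the
resulting regions.

## The problem

Antibody-based G4 capture (G4-ChIP and its artifact-suppressed variants)
yields genome-wide read landscapes of folded quadruplexes.  Comparing two
conditions — a control (CT) and, say, a knockdown of a candidate
G4-suppressing protein (KD) — asks which genomic regions gain or lose G4
capture.  `g4dcr` implements that comparison at the level of fixed-width
genomic bins (200 bp by default), together with the sequence features that
G4 biology cares about:

* **Quadruplex signature scanning** — the canonical (G₃-N₁₋₇)×4 pattern:
  four tracts of ≥3 guanines separated by 1–7 nt spacers on one strand.
  Tracts are maximal runs, enumeration is leftmost-greedy and hits never
  overlap within a strand; reverse-strand hits are C-tract matches reported
  in input coordinates.
* **Differentially captured regions (DCRs)** — per retained bin the
  diff/sum ratio (KD − CT)/(KD + CT) is computed on depth-normalized counts
  for each replicate batch, for the ChIP libraries and their matched inputs.
  A one-tailed paired *t*-test on the per-batch differences
  d_b = chip_ratio_b − input_ratio_b (n − 1 degrees of freedom) tests each
  direction; p-values are pooled per direction and corrected with the
  two-stage linear step-up FDR procedure of Benjamini, Krieger and
  Yekutieli.  A bin is a DCR when p < 0.01 and it survives the two-stage cut
  at q < 0.01, labeled gain-in-KD or loss-in-KD by the sign of the mean
  difference.
* **G/C-skew** ((G − C)/(G + C) per 100 bp window, windows missing either
  base excluded), **GC-content profiles** around region centers, and
  **GGG/CCC weighted content** ((overlapping GGG + CCC counts) × read
  coverage per peak).
* **Region-set statistics** — merged-interval Jaccard, reciprocal
  ≥70%-of-own-length overlap, matched-length random-region nulls, and the
  share of total signal inside a region set.
* **A synthetic-data generator** — toy genomes with planted signature
  regions and skewed regions, and simulated CT/KD ChIP + input replicate
  libraries with planted differential bins, for end-to-end validation with
  known truth.

Raw counts per bin are filtered to the inclusive range [3, 100] in every
ChIP library (no bounds on inputs) before testing; normalization is counts
per million.

## Worked example

The published 272 nt Control DNA construct carries three repeats of the
canonical signature unit; the same-length carrier construct (every
tetrad-forming GGG replaced by ATG) carries none:

```python
>>> from g4dcr import scan_quadruplex_signature
>>> from g4dcr.synthetic import CONTROL_DNA, CARRIER_DNA
>>> for h in scan_quadruplex_signature(CONTROL_DNA, strand_mode="forward"):
...     print(h.start, h.end, h.spacers)
45 73 (5, 5, 5)
123 151 (5, 5, 5)
200 227 (5, 5, 5)
>>> scan_quadruplex_signature(CARRIER_DNA)
[]
```

A full simulated experiment (3 chromosomes, 1850 bins, three paired CT/KD
batches with matched inputs, 200 planted gain bins at effect multiplier 3):

```python
>>> from g4dcr.synthetic import SimConfig, make_toy_genome, simulate_experiment
>>> from g4dcr.dcr import call_dcrs
>>> cfg = SimConfig()
>>> genome, truth = make_toy_genome(cfg, seed=7)
>>> sim = simulate_experiment(truth, cfg, seed=8)
>>> chip, inp = sim.coverage_matrices()
>>> res = call_dcrs(chip, inp)
>>> res.n_bins_tested, len(res.dcrs)
(1778, 0)
>>> print(res.table[["chrom", "start", "end", "dbar", "t", "p", "q", "direction"]]
...       .sort_values("p").head(3).to_string(index=False))
chrom  start   end      dbar          t        p        q  direction
 chr1  32000 32200  0.179272  38.490041 0.000337 1.000000 gain-in-KD
 chr3  59400 59600 -0.290000 -33.092991 0.000456 0.485548 loss-in-KD
 chr1  61200 61400 -0.357010 -27.432550 0.000663 0.485548 loss-in-KD
```

1778 of 1850 bins pass the [3, 100] coverage filter.  Even the best bins
reach only p ≈ 3×10⁻⁴: with three replicate pairs the *t*-test has two
degrees of freedom, so single-bin p-values rarely get small enough for the
two-stage q < 0.01 cut over ~1800 simultaneous tests — a property of the
published design that the simulation makes visible (see
`docs/methods.md`).

The same pipeline is available from the shell:

```
g4dcr simulate --seed 7 --outdir sim/
g4dcr dcr --sample-sheet sim/samples.tsv --sizes sim/genome.chrom.sizes --out-prefix dcr
g4dcr scan --fasta sim/genome.fasta --out hits.bed
g4dcr compare --a dcr.bed --b sim/truth_dcr_bins.bed
```

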