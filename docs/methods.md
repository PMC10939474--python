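# Methods

This note documents the models and procedures implemented in `g4dcr`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Quadruplex signature scan

The canonical signature is (G₃-N₁₋₇)×4: `n_runs` (default 4) tracts of at
least `run_len` (default 3) guanines, consecutive tracts separated by
spacers of `spacer_min`–`spacer_max` (default 1–7) nucleotides, all on one
strand.  Three semantic choices close the gaps that the pattern notation
leaves open:

* **Maximal tracts.** A stretch of k ≥ run_len consecutive Gs is one tract;
  it is never split into overlapping sub-tracts.  This avoids combinatorial
  double counting on long runs (`GGGGGG` is one tract, and alone matches
  nothing).
* **Leftmost-greedy, non-overlapping enumeration.** Hits chain consecutive
  maximal tracts whose gaps all lie in the spacer bounds; once a hit is
  emitted its tracts are consumed.  The reported count is therefore the
  number of disjoint matches — the reading under which the published
  control construct, three tandem copies of the 27 nt unit
  `GGG-N₅-GGG-N₅-GGG-N₅-GGG`, counts as exactly 3.
* **N breaks tracts.** Any non-G (including N) ends a tract and counts
  toward the spacer; a tetrad is never assumed across unknown sequence.

Reverse-strand hits are found by matching the mirror C-tract pattern on the
given sequence and reported with strand `-` in input coordinates; a
brute-force enumeration oracle checks both the counts and the exact tract
structure in the tests.  Both a hit list and a per-sequence boolean are
exposed, so either per-region hit counts or read-level presence/absence
fractions can be formed.

## G/C-skew and GC-content scores

Skew is (G − C)/(G + C) per `bin_width` window (default 100 bp), windows
tiling the sequence from offset 0, trailing partial window kept at its true
width.  A window with **either** count zero is excluded rather than scored — the
stricter of the two defensible zero-count elimination rules — and
`zero_rule="both"` relaxes this to the cases where the formula itself is
undefined.  Skew is antisymmetric under per-base
complementation, which the tests exercise on random sequence.

GC-content profiles average (G+C)/(A+C+G+T) in equal position bins across
[center − flank, center + flank); regions whose window would cross a
chromosome end are dropped with a logged warning rather than padded.

GGG/CCC weighted content counts pattern occurrences with single-base
sliding (so `G×k` contains k − 2 `GGG`), discards peaks lacking either
pattern entirely, and multiplies the summed counts by the peak's read
coverage.

## Binning, coverage and normalization

Bins are fixed-width (default 200 bp, the published resolution), tiling
each included chromosome from 0 with the partial tail kept.  A read
overlapping a bin by ≥1 bp counts once in that bin; a read spanning k bins
contributes to all k.  The retention filter keeps bins whose **raw** count
lies in the inclusive range [3, 100] in *every* ChIP library (the published
rule: <3 removes no-signal bins, >100 removes PCR artifacts); inputs carry
no bounds.  Depth normalization is counts per million; the scale is
recorded in the matrix metadata.  Library size defaults to the per-sample
total counted reads (all aligned reads, not just filter-surviving ones),
overridable per sample — the diff/sum ratio is scale-invariant within a
sample pair as long as both libraries use the same scale, which CPM
guarantees.

## Differential capture model

Per retained bin and replicate batch b, the condition contrast is the
diff/sum ratio r = (KD − CT)/(KD + CT) on normalized counts, bounded in
[−1, 1] and exactly sign-flipping under a label swap.  For inputs (which
may have empty bins) the 0/0 case is defined as ratio 0 — "no evidence of
input bias" — configurable to dropping the bin.

The test statistic pairs each ChIP contrast with its matched input
contrast: d_b = chip_ratio_b − input_ratio_b, and a one-tailed paired *t*
on (d_1 … d_n) with n − 1 degrees of freedom is evaluated in both
directions.  Pairing is how input correction enters: each ChIP contrast is
corrected by the input contrast measured on the same regions in the same
batch.  Two defensible alternative formulations are available behind
`DcrParams.method`: `unpaired` (two-sample pooled-variance *t* of chip
ratios vs input ratios, 2n − 2 df) and `one-sample` (chip ratio minus the
mean input ratio, tested against zero).

Degenerate bins — zero spread with a nonzero mean difference — receive the
smallest positive representable p-value and an explicit flag, never a
silent NaN.

P-values are pooled per direction across all tested bins and corrected
with the two-stage linear step-up procedure (Benjamini–Krieger–Yekutieli):
stage 1 runs the linear step-up at q′ = q/(1 + q); its rejection count r₁
gives the null estimate m̂₀ = m − r₁; stage 2 reruns the step-up at
q′·m/m̂₀ (nothing rejected if r₁ = 0, everything if r₁ = m).  Adjusted
q-values are defined by monotone inversion — the smallest nominal q at
which the bin would be rejected — computed on a geometric grid of 256
candidate levels that always includes the nominal q, so the rejection set
equals `qvalues <= q` exactly at the requested level.  A bin is a DCR when
p < 0.01 and it is rejected by the two-stage procedure at q = 0.01 in its
direction; the default reports the union of both directions with per-bin
labels, configurable to a single pre-declared tail.

## Region-set statistics

Jaccard merges each set first, then divides total intersection length by
total union length, strand-blind.  Reciprocal overlap is computed against
the merged other set, summing fragmented intersections before comparing to
`min_frac` (default 0.70) of the query's **own** length, boundary
inclusive; both directions are reported.  Random-region sampling places
regions uniformly with probability proportional to chromosome length,
fully inside chromosomes, rejection-sampling against an optional exclusion
set (up to 1000 attempts per region) and drawing lengths from a template
set's empirical distribution for matched-length nulls.  Signal share
pro-rates partially overlapped bins by overlapped length fraction, which
removes bin-phase artifacts.

## Synthetic experiments

`make_toy_genome` plants the published construct's unit signature
(G₃-N₅ ×4, spacers drawn from A/C/T, guard bases so background Gs cannot
extend the outer tracts) centered in bin-aligned regions of an i.i.d.
background at 41% GC (human-like), plus G-biased skew regions, on three
chromosomes of 150/120/100 kb.  `simulate_experiment` draws, per bin,
batch and condition, counts with mean depth × batch factor ×
(1 + enrichment inside signature regions), the KD mean multiplied (gain)
or divided (loss) by the effect multiplier at planted differential bins.
Batch factors are log-normal (σ = 0.2) and shared between a ChIP library
and its matched input — exactly the correlation structure that motivates
the paired analysis.  Counts are negative binomial (size 10; ChIP counts
are overdispersed in practice) with a Poisson option for oracle-friendly
tests, realized as one-bin-length reads laid flush with their bin so
per-bin read counts equal the drawn counts exactly.

Defaults are the study conditions: three paired batches, background bin
depth 20, input depth 20, signature-region enrichment 0.25 (keeping
KD-side planted means near 75, inside the ≤100 raw-count filter), 220
signature regions, 200 planted differential bins (all gains by default,
mirroring the published predominance of capture gains), effect
multiplier 3.

What the generator does **not** emulate: fragment-size and sequencing-error
processes, mappability and repeat structure, GC-dependent amplification
bias, and long-read multi-bin alignments.  Passing tests therefore show
correctness of the statistical machinery on its own model, not performance
on real libraries.

### Power at the published thresholds

With n = 3 pairs the *t* statistic has 2 degrees of freedom, so a single
bin's p-value is heavy-tailed: even t ≈ 38 gives p ≈ 3×10⁻⁴.  A two-stage
cut at q = 0.01 over ~1.8×10³ simultaneous tests needs p of order 10⁻⁵ or
an adaptive threshold raised by many strong effects.  At effect
multiplier 3 the planted ratio is 0.5 while its per-batch sampling noise at
depth ≤100 (the filter cap) is ≈0.1–0.2, a noncentrality far below what
two degrees of freedom require.  Consequently the pipeline recovers
essentially no planted bins at these settings — sensitivity ≈ 0 over 20
seeds — while null calibration (no-effect and self-vs-self simulations)
holds comfortably and the CT/KD label swap flips every direction exactly.
This is a property of the design (three pairs, df = 2, bin-level q < 0.01,
counts capped at 100), not of the implementation; larger effect sizes,
more batches, or relaxed q make recovery climb steeply.  The desk-scale
problem sizes used throughout (≈370 kb genomes, 50 null and 20 recovery
replicates) were chosen to characterize these operating properties
precisely and reproducibly.

## Determinism and degenerate inputs

Every stochastic operation takes an explicit seed; identical seeds give
byte-identical outputs (genomes, reads, region samples, pipeline files).
Empty interval lists, empty bins, all-filtered matrices, zero-signal
tracks and regions off chromosome ends all follow documented paths —
empty results or named errors, never silent propagation of NaNs.
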