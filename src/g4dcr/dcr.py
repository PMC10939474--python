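"""Differential G4-capture inference: diff/sum ratios, paired one-tailed
t-tests and two-stage adaptive FDR.

Per retained 200 bp bin, a condition-contrast ratio (KD - CT)/(KD + CT) is
computed on depth-normalized counts for each of the three replicate batches,
once for the ChIP libraries and once for the matched inputs.  The paired
differences d_b = chip_ratio_b - input_ratio_b correct the capture contrast
for regional representation bias in the inputs, and a one-tailed paired t
with n - 1 degrees of freedom tests each direction.  P-values are pooled
per direction across bins and passed through the two-stage linear step-up
procedure of Benjamini, Krieger and Yekutieli (BKY).  A bin is a
differentially captured region (DCR) when p < 0.01 and BKY q < 0.01 in its
direction (gain-in-KD for positive mean difference, loss-in-KD otherwise).

The diff/sum ratio is bounded in [-1, 1], scale-invariant, and flips sign
exactly under a CT/KD label swap, which swaps the two direction-specific
DCR sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bin_coverage import CoverageMatrix, filter_bins, normalize_depth
from .io_core import GenomicInterval

__all__ = [
    "DcrParams",
    "DcrRecord",
    "DcrResult",
    "diff_sum_ratio",
    "paired_one_tailed_t",
    "bky_two_stage",
    "BkyResult",
    "call_dcrs",
]

logger = logging.getLogger(__name__)

TINY_P = float(np.nextafter(0, 1))


def diff_sum_ratio(kd, ct):
    """(kd - ct)/(kd + ct) on non-negative counts; defined 0 when both are 0.

    Accepts scalars or arrays.  The both-zero case arises only for inputs,
    which carry no coverage bounds; it reads as "no evidence of input bias".
    """
    kd = np.asarray(kd, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if np.any(kd < 0) or np.any(ct < 0):
        raise ValueError("counts must be non-negative")
    total = kd + ct
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, (kd - ct) / np.where(total > 0, total, 1.0), 0.0)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def _paired_t_core(d: np.ndarray):
    """t, mean difference and degeneracy flag for paired differences.

    `d` has batches on the last axis.  Zero spread with a nonzero mean gives
    an infinite t (flagged degenerate, never a silent NaN); zero spread with
    zero mean gives t = 0.
    """
    n = d.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    dbar = d.mean(axis=-1)
    sd = d.std(axis=-1, ddof=1)
    degenerate = (sd == 0) & (dbar != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            sd > 0,
            dbar / np.where(sd > 0, sd, 1.0) * np.sqrt(n),
            np.where(dbar > 0, np.inf, np.where(dbar < 0, -np.inf, 0.0)),
        )
    return t, dbar, degenerate, n - 1


def _tail_p(t, df: int, tail: str):
    if tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    # +/- inf t gives p = 0 from the distribution; report the smallest
    # positive representable value instead so downstream -log10 is finite.
    return np.maximum(p, TINY_P)


def paired_one_tailed_t(
    chip_ratios: Sequence[float] | np.ndarray,
    input_ratios: Sequence[float] | np.ndarray,
    tail: str = "greater",
):
    """One-tailed paired t on d_b = chip_ratio_b - input_ratio_b.

    Returns ``(t, p, dbar, degenerate)``.  Inputs may be 1-D (one bin,
    batches along the axis) or 2-D (bins x batches); shapes must match.
    """
    chip = np.asarray(chip_ratios, dtype=float)
    inp = np.asarray(input_ratios, dtype=float)
    if chip.shape != inp.shape:
        raise ValueError("chip and input ratio vectors must have equal shape")
    d = chip - inp
    t, dbar, degenerate, df = _paired_t_core(d)
    p = _tail_p(t, df, tail)
    if d.ndim == 1:
        return float(t), float(p), float(dbar), bool(degenerate)
    return t, p, dbar, degenerate


# ---------------------------------------------------------------------------
# two-stage adaptive FDR


@dataclass
class BkyResult:
    reject: np.ndarray
    qvalues: np.ndarray | None
    m0_hat: int
    stage1_rejections: int


def _stepup_count(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear step-up (BH) procedure at `level`."""
    m = len(p_sorted)
    crit = level * np.arange(1, m + 1) / m
    below = np.nonzero(p_sorted <= crit)[0]
    return int(below[-1]) + 1 if len(below) else 0


def _two_stage_cutoff(p_sorted: np.ndarray, q: float) -> float:
    """Largest p-value rejected by the two-stage procedure at level q (-inf if none)."""
    m = len(p_sorted)
    q1 = q / (1.0 + q)
    r1 = _stepup_count(p_sorted, q1)
    if r1 == 0:
        return -np.inf
    if r1 == m:
        return p_sorted[-1]
    m0 = m - r1
    r2 = _stepup_count(p_sorted, q1 * m / m0)
    return p_sorted[r2 - 1] if r2 else -np.inf


def bky_two_stage(
    pvalues: Sequence[float] | np.ndarray,
    q: float = 0.01,
    return_qvalues: bool = True,
    grid_size: int = 256,
) -> BkyResult:
    """Two-stage linear step-up FDR procedure (Benjamini-Krieger-Yekutieli).

    Stage 1 runs the linear step-up at q' = q/(1+q); its rejection count r1
    estimates the number of true nulls as m0 = m - r1, and stage 2 reruns the
    step-up at level q' * m / m0.  With r1 = 0 nothing is rejected; with
    r1 = m everything is.

    Adjusted q-values are the smallest nominal q at which a p-value would be
    rejected by the full two-stage procedure, obtained by monotone inversion
    over a geometric grid of candidate levels (the nominal q is always on the
    grid, so ``reject`` equals ``qvalues <= q`` exactly).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    m = len(p)

    q1 = q / (1.0 + q)
    r1 = _stepup_count(p_sorted, q1)
    cutoff = _two_stage_cutoff(p_sorted, q)
    reject = p <= cutoff
    m0_hat = m - r1 if 0 < r1 < m else m

    qvalues = None
    if return_qvalues:
        grid = np.unique(
            np.concatenate([np.geomspace(1e-10, 0.9999, grid_size), [q]])
        )
        cutoffs = np.array([_two_stage_cutoff(p_sorted, g) for g in grid])
        cutoffs = np.maximum.accumulate(cutoffs)  # rejection is monotone in q
        idx = np.searchsorted(cutoffs, p, side="left")
        qvalues = np.where(idx < len(grid), grid[np.minimum(idx, len(grid) - 1)], 1.0)
    return BkyResult(reject=reject, qvalues=qvalues, m0_hat=m0_hat, stage1_rejections=r1)


# ---------------------------------------------------------------------------
# DCR calling


@dataclass
class DcrParams:
    """Thresholds of the differential-capture pipeline (defaults as published)."""

    bin_min_count: int = 3
    bin_max_count: int = 100
    p_threshold: float = 0.01
    q_threshold: float = 0.01
    tails: str = "both"  # 'both' | 'greater' | 'less'
    method: str = "paired"  # 'paired' | 'unpaired' | 'one-sample'
    scale: float = 1e6


@dataclass(frozen=True)
class DcrRecord:
    bin: GenomicInterval
    dbar: float
    t: float
    p: float
    q: float
    direction: str  # 'gain-in-KD' | 'loss-in-KD'
    is_dcr: bool
    degenerate: bool = False


@dataclass
class DcrResult:
    """Per-tested-bin statistics plus the called DCR subset."""

    table: pd.DataFrame
    params: DcrParams
    n_bins_total: int
    n_bins_tested: int
    batches: list[str]

    @property
    def dcrs(self) -> pd.DataFrame:
        return self.table[self.table["is_dcr"]]

    def records(self) -> list[DcrRecord]:
        out = []
        for row in self.table.itertuples(index=False):
            out.append(
                DcrRecord(
                    bin=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    dbar=row.dbar,
                    t=row.t,
                    p=row.p,
                    q=row.q,
                    direction=row.direction,
                    is_dcr=bool(row.is_dcr),
                    degenerate=bool(row.degenerate),
                )
            )
        return out

    def dcr_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(
                r.chrom, int(r.start), int(r.end),
                name=r.direction, score=float(-np.log10(max(r.p, TINY_P))),
            )
            for r in self.dcrs.itertuples(index=False)
        ]


def _pair_columns(cov: CoverageMatrix, role: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Column indices of (CT, KD) per replicate batch, batches sorted by label."""
    by_key = {(s.condition, s.replicate): j for j, s in enumerate(cov.samples) if s.role == role}
    batches = sorted({s.replicate for s in cov.samples if s.role == role})
    missing = [
        (cond, b) for b in batches for cond in ("CT", "KD") if (cond, b) not in by_key
    ]
    if missing:
        raise ValueError(f"unpairable {role} batches; missing samples: {missing}")
    ct = np.array([by_key[("CT", b)] for b in batches])
    kd = np.array([by_key[("KD", b)] for b in batches])
    return batches, ct, kd


def call_dcrs(
    cov_chip: CoverageMatrix,
    cov_input: CoverageMatrix,
    params: DcrParams | None = None,
) -> DcrResult:
    """Run the full differential-capture pipeline on paired coverage matrices.

    Pipeline: retain bins whose raw count lies in [min, max] in *every* ChIP
    sample (inputs carry no coverage bounds) -> depth-normalize both matrices
    -> per-batch diff/sum ratios for ChIP and inputs -> paired one-tailed t
    per bin and direction -> per-direction BKY FDR -> DCR = p and q below
    threshold, labeled with its direction.
    """
    params = params or DcrParams()
    if cov_chip.grid is not cov_input.grid and (
        cov_chip.grid.chrom_names != cov_input.grid.chrom_names
        or cov_chip.grid.width != cov_input.grid.width
    ):
        raise ValueError("chip and input matrices must share one bin grid")

    batches, chip_ct, chip_kd = _pair_columns(cov_chip, "chip")
    ibatches, in_ct, in_kd = _pair_columns(cov_input, "input")
    if batches != ibatches:
        raise ValueError(
            f"chip batches {batches} do not match input batches {ibatches}"
        )

    mask = filter_bins(cov_chip, params.bin_min_count, params.bin_max_count)
    n_tested = int(mask.sum())
    columns = [
        "chrom", "start", "end", "dbar", "t", "p", "q",
        "p_greater", "p_less", "q_greater", "q_less",
        "direction", "is_dcr", "degenerate",
    ] + [f"chip_ratio_{b}" for b in batches] + [f"input_ratio_{b}" for b in batches]
    if n_tested == 0:
        logger.info("call_dcrs: no bins pass the coverage filter; empty DCR set")
        empty = pd.DataFrame({c: [] for c in columns})
        return DcrResult(empty, params, cov_chip.grid.n_bins, 0, batches)

    chip = normalize_depth(cov_chip, scale=params.scale)
    inp = normalize_depth(cov_input, scale=params.scale)

    chip_ratio = diff_sum_ratio(
        chip.normalized[mask][:, chip_kd], chip.normalized[mask][:, chip_ct]
    )
    input_ratio = diff_sum_ratio(
        inp.normalized[mask][:, in_kd], inp.normalized[mask][:, in_ct]
    )

    if params.method == "paired":
        d = chip_ratio - input_ratio
        t, dbar, degenerate, df = _paired_t_core(d)
    elif params.method == "one-sample":
        d = chip_ratio - input_ratio.mean(axis=1, keepdims=True)
        t, dbar, degenerate, df = _paired_t_core(d)
    elif params.method == "unpaired":
        n1 = chip_ratio.shape[1]
        n2 = input_ratio.shape[1]
        m1, m2 = chip_ratio.mean(axis=1), input_ratio.mean(axis=1)
        v1 = chip_ratio.var(axis=1, ddof=1)
        v2 = input_ratio.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        dbar = m1 - m2
        degenerate = (se == 0) & (dbar != 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                se > 0,
                dbar / np.where(se > 0, se, 1.0),
                np.where(dbar > 0, np.inf, np.where(dbar < 0, -np.inf, 0.0)),
            )
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown test method {params.method!r}")

    p_greater = _tail_p(t, df, "greater")
    p_less = _tail_p(t, df, "less")

    q_greater = np.full(n_tested, 1.0)
    q_less = np.full(n_tested, 1.0)
    rej_greater = np.zeros(n_tested, dtype=bool)
    rej_less = np.zeros(n_tested, dtype=bool)
    if params.tails in ("both", "greater"):
        res = bky_two_stage(p_greater, q=params.q_threshold)
        q_greater, rej_greater = res.qvalues, res.reject
    if params.tails in ("both", "less"):
        res = bky_two_stage(p_less, q=params.q_threshold)
        q_less, rej_less = res.qvalues, res.reject

    gain = dbar >= 0
    direction = np.where(gain, "gain-in-KD", "loss-in-KD")
    p = np.where(gain, p_greater, p_less)
    q = np.where(gain, q_greater, q_less)
    sig_gain = (p_greater < params.p_threshold) & rej_greater
    sig_loss = (p_less < params.p_threshold) & rej_less
    if params.tails == "greater":
        is_dcr = sig_gain
        direction = np.where(sig_gain, "gain-in-KD", direction)
    elif params.tails == "less":
        is_dcr = sig_loss
        direction = np.where(sig_loss, "loss-in-KD", direction)
    else:
        is_dcr = np.where(gain, sig_gain, sig_loss)

    frame = cov_chip.grid.frame().loc[mask].reset_index(drop=True)
    table = frame.assign(
        dbar=dbar, t=t, p=p, q=q,
        p_greater=p_greater, p_less=p_less,
        q_greater=q_greater, q_less=q_less,
        direction=direction, is_dcr=is_dcr, degenerate=degenerate,
    )
    for k, b in enumerate(batches):
        table[f"chip_ratio_{b}"] = chip_ratio[:, k]
        table[f"input_ratio_{b}"] = input_ratio[:, k]
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("call_dcrs: %d bin(s) had zero spread with nonzero mean (degenerate)", n_deg)
    logger.info(
        "call_dcrs: tested %d/%d bins, %d DCRs (%d gain, %d loss)",
        n_tested, cov_chip.grid.n_bins, int(is_dcr.sum()),
        int((is_dcr & gain).sum()), int((is_dcr & ~gain).sum()),
    )
    return DcrResult(table, params, cov_chip.grid.n_bins, n_tested, batches)
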