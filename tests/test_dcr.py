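"""diff/sum ratios, paired one-tailed t, BKY two-stage FDR and DCR calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from g4dcr.bin_coverage import CoverageMatrix, make_bins
from g4dcr.dcr import (
    bky_two_stage,
    call_dcrs,
    diff_sum_ratio,
    paired_one_tailed_t,
)
from g4dcr.io_core import ChromSizes, SampleMeta
from g4dcr.synthetic import simulate_experiment


class TestDiffSumRatio:
    def test_published_control_dna_read_counts(self):
        # six reads in control, 390 after knockdown
        assert diff_sum_ratio(390, 6) == pytest.approx(0.9697, abs=1e-4)

    def test_symmetry(self):
        assert diff_sum_ratio(5, 5) == 0.0

    def test_defined_zero_for_empty_bins(self):
        assert diff_sum_ratio(0, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            diff_sum_ratio(-1, 5)

    @given(
        st.floats(0.01, 1e6), st.floats(0.01, 1e6), st.floats(0.01, 1e3)
    )
    def test_scale_invariance_and_bounds(self, kd, ct, c):
        r = diff_sum_ratio(kd, ct)
        assert -1 <= r <= 1
        assert diff_sum_ratio(kd * c, ct * c) == pytest.approx(r, abs=1e-9)

    def test_label_swap_negates(self):
        kd = np.array([3.0, 0.0, 17.5])
        ct = np.array([1.0, 0.0, 20.0])
        assert np.allclose(diff_sum_ratio(kd, ct), -diff_sum_ratio(ct, kd))


class TestPairedT:
    def test_identical_vectors_give_midpoint_p(self):
        t, p, dbar, deg = paired_one_tailed_t([0.2, 0.4, 0.3], [0.2, 0.4, 0.3])
        assert t == 0.0 and p == 0.5 and dbar == 0.0 and not deg

    @pytest.mark.parametrize("tail", ["greater", "less"])
    def test_matches_scipy_reference(self, tail):
        chip = np.array([0.5, 0.6, 0.55])
        inp = np.array([0.0, 0.05, -0.02])
        t, p, dbar, _ = paired_one_tailed_t(chip, inp, tail=tail)
        ref = stats.ttest_rel(chip, inp, alternative=tail)
        assert t == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)
        assert dbar == pytest.approx(np.mean(chip - inp))

    def test_constant_nonzero_difference_is_degenerate(self):
        t, p, dbar, deg = paired_one_tailed_t([0.3, 0.3, 0.3], [0.0, 0.0, 0.0])
        assert deg
        assert p < 1e-300
        assert dbar == pytest.approx(0.3)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        chip = rng.normal(0.2, 0.1, size=(50, 3))
        inp = rng.normal(0.0, 0.1, size=(50, 3))
        t, p, dbar, deg = paired_one_tailed_t(chip, inp, tail="greater")
        for i in range(50):
            ti, pi, di, _ = paired_one_tailed_t(chip[i], inp[i], tail="greater")
            assert t[i] == pytest.approx(ti)
            assert p[i] == pytest.approx(pi)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_one_tailed_t([0.1, 0.2], [0.1, 0.2, 0.3])


class TestBky:
    def test_flat_pvalues_reject_nothing(self):
        res = bky_two_stage(np.full(100, 0.5), q=0.01)
        assert res.reject.sum() == 0

    def test_single_small_pvalue_rejected(self):
        res = bky_two_stage(np.array([0.001]), q=0.01)
        assert res.reject.tolist() == [True]

    def test_small_example_matches_reference(self):
        p = np.array([0.0001, 0.0002, 0.2, 0.8, 0.9])
        res = bky_two_stage(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        assert np.array_equal(res.reject, ref)
        assert res.reject.tolist() == [True, True, False, False, False]

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(20)
        for _ in range(100):
            m = int(rng.integers(1, 500))
            k = int(rng.uniform(0, 0.4) * m)
            p = np.concatenate(
                [rng.uniform(0, 0.02, size=k) ** 2, rng.uniform(size=m - k)]
            )
            rng.shuffle(p)
            q = float(rng.choice([0.01, 0.05, 0.1]))
            res = bky_two_stage(p, q=q, return_qvalues=False)
            ref = multipletests(p, alpha=q, method="fdr_tsbky")[0]
            assert np.array_equal(res.reject, ref)

    def test_qvalues_consistent_with_rejections(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(0, 1e-4, 20), rng.uniform(size=200)])
        for q in (0.01, 0.05):
            res = bky_two_stage(p, q=q)
            assert np.array_equal(res.reject, res.qvalues <= q)

    def test_stage_two_never_shrinks_stage_one(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            m = int(rng.integers(5, 300))
            p = rng.uniform(size=m) ** rng.uniform(1, 4)
            q = 0.05
            res = bky_two_stage(p, q=q, return_qvalues=False)
            bh = multipletests(p, alpha=q / (1 + q), method="fdr_bh")[0]
            assert res.reject.sum() >= bh.sum()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bky_two_stage(np.array([0.5, 1.2]), q=0.05)

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(40)
        fdp = []
        for _ in range(50):
            p = rng.uniform(size=2000)
            res = bky_two_stage(p, q=0.05, return_qvalues=False)
            r = res.reject.sum()
            fdp.append(1.0 if r else 0.0)  # all rejections are false under the null
        assert np.mean(fdp) <= 0.05 + 2 * np.sqrt(0.05 / 50)


def _experiment(small_config, toy_world, seed, swap=False):
    _, truth = toy_world
    sim = simulate_experiment(truth, small_config, seed)
    chip, inp = sim.coverage_matrices()
    if swap:
        def _swap(cov):
            samples = [
                SampleMeta(s.sample_id, {"CT": "KD", "KD": "CT"}[s.condition],
                           s.replicate, s.role, s.library_size)
                for s in cov.samples
            ]
            return CoverageMatrix(grid=cov.grid, samples=samples, raw=cov.raw)
        chip, inp = _swap(chip), _swap(inp)
    return truth, chip, inp


class TestCallDcrs:
    def test_label_swap_negates_statistics_and_flips_directions(
        self, small_config, toy_world
    ):
        _, chip, inp = _experiment(small_config, toy_world, seed=50)
        _, chip_s, inp_s = _experiment(small_config, toy_world, seed=50, swap=True)
        a = call_dcrs(chip, inp)
        b = call_dcrs(chip_s, inp_s)
        assert np.allclose(a.table["dbar"], -b.table["dbar"])
        assert np.allclose(a.table["t"], -b.table["t"])
        assert np.allclose(a.table["p_greater"], b.table["p_less"])
        nz = a.table["dbar"] != 0
        flip = {"gain-in-KD": "loss-in-KD", "loss-in-KD": "gain-in-KD"}
        assert (
            a.table.loc[nz, "direction"].map(flip).tolist()
            == b.table.loc[nz, "direction"].tolist()
        )
        # the two direction-specific DCR sets swap exactly
        assert np.array_equal(
            (a.table["is_dcr"] & (a.table["direction"] == "gain-in-KD")).values,
            (b.table["is_dcr"] & (b.table["direction"] == "loss-in-KD")).values,
        )

    def test_all_bins_below_minimum_coverage_gives_empty_result(self, caplog):
        grid = make_bins(ChromSizes({"chr1": 1000}), width=200)
        samples_chip = [
            SampleMeta(f"{c}_{b}_chip", c, b, "chip")
            for b in ("nuc", "tr", "ut") for c in ("CT", "KD")
        ]
        samples_input = [
            SampleMeta(f"{c}_{b}_input", c, b, "input")
            for b in ("nuc", "tr", "ut") for c in ("CT", "KD")
        ]
        chip = CoverageMatrix(grid=grid, samples=samples_chip,
                              raw=np.ones((5, 6), dtype=int))
        inp = CoverageMatrix(grid=grid, samples=samples_input,
                             raw=np.full((5, 6), 10, dtype=int))
        with caplog.at_level("INFO"):
            res = call_dcrs(chip, inp)
        assert res.n_bins_tested == 0
        assert len(res.table) == 0
        assert "no bins pass" in caplog.text

    def test_missing_pair_reported(self):
        grid = make_bins(ChromSizes({"chr1": 1000}), width=200)
        samples = [
            SampleMeta("CT_nuc_chip", "CT", "nuc", "chip"),
            SampleMeta("KD_tr_chip", "KD", "tr", "chip"),
        ]
        chip = CoverageMatrix(grid=grid, samples=samples,
                              raw=np.full((5, 2), 10, dtype=int))
        with pytest.raises(ValueError, match="missing"):
            call_dcrs(chip, chip)

    def test_self_vs_self_input_null_calls_almost_nothing(self, small_config, toy_world):
        _, truth = toy_world
        # two independent draws of effect-free input libraries: a pure null
        _, inp_a = simulate_experiment(truth, small_config, seed=60).coverage_matrices()
        _, inp_b = simulate_experiment(truth, small_config, seed=61).coverage_matrices()
        chip_like = CoverageMatrix(
            grid=inp_a.grid,
            samples=[SampleMeta(s.sample_id, s.condition, s.replicate, "chip",
                                s.library_size) for s in inp_a.samples],
            raw=inp_a.raw,
        )
        res = call_dcrs(chip_like, inp_b)
        assert res.n_bins_tested > 0
        assert len(res.dcrs) <= 0.01 * res.n_bins_tested
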