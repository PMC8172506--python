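import math

import numpy as np
import pytest
from scipy import stats

from proirm.decision import (
    DecisionInputs,
    DecisionTable,
    MethodSummary,
    Z975,
    ci_width,
    decision_table_analytic,
    decision_table_mc,
    npv,
    p_go,
    p_stop,
    power_curve,
    power_threshold,
    ppv,
    roc_and_auc,
    sample_size_ratio,
    sd_from_ci,
)

# printed comparator values used throughout: reference-method CI bounds for
# the respiratory subscore and the two decision SDs
MMRM_CI = (-4.77, 2.04)
IRM_CI = (-3.16, 0.48)


class TestCiAndSampleSize:
    def test_printed_widths(self):
        assert ci_width(*MMRM_CI) == pytest.approx(6.81)
        assert ci_width(*IRM_CI) == pytest.approx(3.64)

    def test_printed_ratio(self):
        ratio = sample_size_ratio(ci_width(*MMRM_CI), ci_width(*IRM_CI))
        assert round(ratio, 1) == 3.5

    def test_equal_widths(self):
        assert sample_size_ratio(2.5, 2.5) == 1.0

    def test_square_law(self):
        assert sample_size_ratio(2.0, 1.0) == 4.0

    def test_sd_from_ci(self):
        assert sd_from_ci(*IRM_CI) == pytest.approx(3.64 / (2 * 1.959964), abs=1e-4)
        assert sd_from_ci(-1, 1) == pytest.approx(2 / 3.91993, abs=1e-4)

    def test_reversed_bounds(self):
        with pytest.raises(ValueError):
            ci_width(2.0, -2.0)

    def test_nonpositive_width(self):
        with pytest.raises(ValueError):
            sample_size_ratio(0.0, 1.0)


class TestPGo:
    def test_printed_87(self):
        assert round(100 * p_go(-5.0, 2.70, -2.0)) == 87

    def test_printed_96(self):
        assert round(100 * p_go(-5.0, 1.74, -2.0)) == 96

    def test_median_at_threshold(self):
        assert p_go(-2.0, 1.0, -2.0) == pytest.approx(0.5)

    def test_complement(self):
        for d in (-6.0, -2.0, 1.0):
            assert p_go(d, 1.5, -2.0) + p_stop(d, 1.5, -2.0) == pytest.approx(1.0)


class TestAnalyticTable:
    def test_printed_mmrm_exact_column(self):
        t = decision_table_analytic(DecisionInputs(tv=-2.0, sigma_delta=2.70))
        assert t.p_correct_stop == pytest.approx(0.68, abs=0.005)
        assert t.p_incorrect_go == pytest.approx(0.22, abs=0.005)
        assert t.p_incorrect_stop == pytest.approx(0.04, abs=0.005)
        assert t.p_correct_go == pytest.approx(0.06, abs=0.005)
        assert ppv(t) == pytest.approx(0.22, abs=0.005)
        assert npv(t) == pytest.approx(0.95, abs=0.005)

    def test_printed_mmrm_ers_correct_go(self):
        t = decision_table_analytic(DecisionInputs(tv=-2.0, sigma_delta=1.74))
        assert t.p_correct_go == pytest.approx(0.067, abs=0.003)

    def test_irm_ers_npv(self):
        sigma = sd_from_ci(*IRM_CI)
        t = decision_table_analytic(DecisionInputs(tv=-2.0, sigma_delta=sigma))
        assert npv(t) == pytest.approx(0.97, abs=0.005)

    def test_cells_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = decision_table_analytic(
                DecisionInputs(
                    tv=float(rng.uniform(-4, -0.5)),
                    sigma_delta=float(rng.uniform(0.3, 4)),
                    w0=float(rng.uniform(0.2, 0.95)),
                )
            )
            total = t.p_correct_go + t.p_incorrect_go + t.p_correct_stop + t.p_incorrect_stop
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_prior_margins(self):
        # point mass at 0 with tv < 0 plus a symmetric normal at tv:
        # P(true effect > tv) = w0 + w1/2
        t = decision_table_analytic(DecisionInputs(tv=-2.0, sigma_delta=1.0))
        assert t.p_incorrect_go + t.p_correct_stop == pytest.approx(0.9, abs=1e-12)
        assert t.p_correct_go + t.p_incorrect_stop == pytest.approx(0.1, abs=1e-12)

    def test_noiseless_limit(self):
        t = decision_table_analytic(DecisionInputs(tv=-2.0, sigma_delta=1e-8))
        assert t.p_incorrect_go == pytest.approx(0.0, abs=1e-9)
        assert t.p_incorrect_stop == pytest.approx(0.0, abs=1e-9)
        assert ppv(t) == pytest.approx(1.0, abs=1e-6)
        assert npv(t) == pytest.approx(1.0, abs=1e-6)


class TestMcTable:
    def test_within_binomial_error_of_analytic(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            inputs = DecisionInputs(
                tv=float(rng.uniform(-4, -0.5)),
                sigma_delta=float(rng.uniform(0.3, 4)),
                n_samples=40_000,
                seed=trial,
            )
            mc = decision_table_mc(inputs)
            an = decision_table_analytic(inputs)
            for name in ("p_correct_go", "p_incorrect_go", "p_correct_stop", "p_incorrect_stop"):
                p = getattr(an, name)
                se = math.sqrt(max(p * (1 - p), 1e-12) / inputs.n_samples)
                assert abs(getattr(mc, name) - p) < 3 * se + 1e-9, name

    def test_reproducible(self):
        inputs = DecisionInputs(tv=-2.0, sigma_delta=2.7, seed=5)
        assert decision_table_mc(inputs) == decision_table_mc(inputs)

    def test_noiseless_limit(self):
        t = decision_table_mc(DecisionInputs(tv=-2.0, sigma_delta=1e-9, n_samples=5000))
        assert t.p_incorrect_go == 0.0
        assert t.p_incorrect_stop == 0.0


class TestPpvNpv:
    def test_printed_ppv_from_raw_cells(self):
        # 0.0613 / 0.2836 -> prints 0.22
        t = decision_table_analytic(DecisionInputs(tv=-2.0, sigma_delta=2.70))
        assert t.p_correct_go == pytest.approx(0.0613, abs=0.0005)
        assert t.p_go == pytest.approx(0.2836, abs=0.001)
        assert round(ppv(t), 2) == 0.22

    def test_zero_numerator(self):
        t = DecisionTable(0.0, 0.3, 0.5, 0.2)
        assert ppv(t) == 0.0

    def test_zero_denominator_warns(self):
        t = DecisionTable(0.0, 0.0, 0.8, 0.2)
        with pytest.warns(UserWarning, match="PPV"):
            assert ppv(t) is None


class TestPower:
    def test_threshold_at_half_power(self):
        assert power_threshold(1.74, -2.0, 0.5) == pytest.approx(-2.0)

    def test_closed_form_threshold(self):
        # tv - 0.8416 * sigma
        assert power_threshold(1.74, -2.0, 0.8) == pytest.approx(
            -2.0 - stats.norm.ppf(0.8) * 1.74, abs=1e-9
        )
        assert power_threshold(1.74, -2.0, 0.8) == pytest.approx(-3.464, abs=0.01)

    def test_curve_monotone_decreasing(self):
        grid = np.linspace(-8, 0, 200)
        curve = power_curve(1.74, -2.0, grid)
        assert np.all(np.diff(curve) < 0)

    def test_grid_must_cover_tv(self):
        with pytest.raises(ValueError, match="cover"):
            power_curve(1.0, -2.0, np.linspace(-1, 0, 10))

    def test_bad_target_power(self):
        with pytest.raises(ValueError):
            power_threshold(1.0, -2.0, 1.5)


class TestRoc:
    def test_identical_arms_auc_half(self):
        r = roc_and_auc(MethodSummary(0.0, 1.0), MethodSummary(0.0, 1.0), n_draws=4000, seed=1)
        assert r.auc == pytest.approx(0.5, abs=0.03)
        assert r.auc_closed_form == pytest.approx(0.5)

    def test_empirical_matches_closed_form(self):
        rng = np.random.default_rng(3)
        for trial in range(4):
            d = MethodSummary(float(rng.uniform(-3, -0.5)), float(rng.uniform(0.5, 2)))
            p = MethodSummary(float(rng.uniform(-0.3, 0.5)), float(rng.uniform(0.5, 2)))
            r = roc_and_auc(d, p, n_draws=3000, seed=trial, n_bootstrap=200)
            mc_se = math.sqrt(r.auc_closed_form * (1 - r.auc_closed_form) / 3000) * 2
            assert abs(r.auc - r.auc_closed_form) < 3 * mc_se + 0.01

    def test_separation_limit(self):
        r = roc_and_auc(MethodSummary(-100.0, 1.0), MethodSummary(0.0, 1.0), n_draws=500, seed=0)
        assert r.auc == pytest.approx(1.0)

    def test_ci_brackets_auc(self):
        r = roc_and_auc(MethodSummary(-2.0, 1.0), MethodSummary(0.0, 1.0), n_draws=2000, seed=9)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]

    def test_bad_se(self):
        with pytest.raises(ValueError):
            MethodSummary(0.0, 0.0)


class TestConvergenceRate:
    def test_mc_converges_at_root_n(self):
        # |MC - analytic| scales as 1/sqrt(n): at n = 10^6 each cell is
        # within 4 binomial SEs for 10 random configurations
        rng = np.random.default_rng(7)
        for trial in range(10):
            inputs = DecisionInputs(
                tv=float(rng.uniform(-3, -1)),
                sigma_delta=float(rng.uniform(0.5, 3)),
                n_samples=1_000_000,
                seed=100 + trial,
            )
            mc = decision_table_mc(inputs)
            an = decision_table_analytic(inputs)
            for name in ("p_correct_go", "p_incorrect_go", "p_correct_stop", "p_incorrect_stop"):
                p = getattr(an, name)
                se = math.sqrt(max(p * (1 - p), 1e-12) / inputs.n_samples)
                assert abs(getattr(mc, name) - p) < 4 * se + 1e-9
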