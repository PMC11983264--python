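"""Calibration-for-benefit: identities, degenerate inputs, smooth curves."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from survbenefit import (
    PAPER_DEFAULT_CONFIG,
    SurvivalCurvePair,
    TimeGrid,
    grouped_calibration,
    km_overlay,
    rcs_basis,
    simulate_trial,
    smooth_calibration,
)
from survbenefit.nonparametric import kaplan_meier, surv_at

from conftest import trial_from_arrays


def grouped_identity_trial(n_per_group=40, n_groups=5, seed=0):
    """Censoring-free trial where each block's predicted benefit is set to
    its own observed (KM-difference) benefit, so the calibration points lie
    exactly on the identity line."""
    rng = np.random.default_rng(seed)
    times, events, arms, preds = [], [], [], []
    t_star = 1.0
    for g in range(n_groups):
        # distinct survival split per block, no censoring
        arm = np.r_[np.ones(n_per_group // 2, int), np.zeros(n_per_group // 2, int)]
        t = rng.exponential(0.5 + 0.4 * g, n_per_group) + 0.01
        times.append(t)
        events.append(np.ones(n_per_group, int))
        arms.append(arm)
        s1 = np.mean(t[arm == 1] > t_star)
        s0 = np.mean(t[arm == 0] > t_star)
        preds.append(np.full(n_per_group, s1 - s0))
    trial = trial_from_arrays(np.concatenate(times), np.concatenate(events), np.concatenate(arms))
    return trial, np.concatenate(preds), t_star


class TestGroupedCalibration:
    def test_identity_points_give_intercept_zero_slope_one(self):
        trial, pred, t_star = grouped_identity_trial()
        # observed-equal-predicted blocks may still tie across groups; jitter
        # block levels are distinct by construction here
        cal = grouped_calibration(trial, pred, t_star=t_star, n_groups=5)
        assert cal.a0 == pytest.approx(0.0, abs=1e-10)
        assert cal.a1 == pytest.approx(1.0, abs=1e-10)
        assert cal.mse == pytest.approx(0.0, abs=1e-20)

    def test_constant_predictions_rejected(self, default_trial):
        with pytest.raises(ValueError, match="constant"):
            grouped_calibration(default_trial.data, np.zeros(default_trial.data.n), t_star=2.0)

    def test_two_groups_rejected(self, default_trial):
        pred = default_trial.true_benefit("SP", 2.0)
        with pytest.raises(ValueError, match=">= 3"):
            grouped_calibration(default_trial.data, pred, t_star=2.0, n_groups=2)

    def test_one_group_reproduces_overall_bias_exactly(self, default_trial):
        d = default_trial.data
        pred = default_trial.true_benefit("SP", 2.0)
        one = grouped_calibration(d, pred, t_star=2.0, n_groups=1)
        five = grouped_calibration(d, pred, t_star=2.0, n_groups=5)
        # bias is grouping-free: whole-sample observed benefit minus mean prediction
        km1 = surv_at(kaplan_meier(d.subset(d.arm == 1)), 2.0)[0]
        km0 = surv_at(kaplan_meier(d.subset(d.arm == 0)), 2.0)[0]
        assert one.bias == pytest.approx(km1 - km0 - pred.mean(), abs=1e-12)
        assert five.bias == pytest.approx(one.bias, abs=1e-12)
        assert np.isnan(one.a1)

    def test_group_sizes_near_equal_and_partition(self, default_trial):
        d = default_trial.data
        pred = default_trial.true_benefit("SP", 2.0)
        cal = grouped_calibration(d, pred, t_star=2.0, n_groups=5)
        assert cal.group_size.sum() == d.n
        assert cal.group_size.max() - cal.group_size.min() <= 1

    def test_x_error_bars_are_min_max_range(self, default_trial):
        d = default_trial.data
        pred = default_trial.true_benefit("SP", 2.0)
        cal = grouped_calibration(d, pred, t_star=2.0, n_groups=5)
        assert np.all(cal.pred_min <= cal.pred_mean)
        assert np.all(cal.pred_mean <= cal.pred_max)
        # quantile groups are ordered in predicted benefit
        assert np.all(np.diff(cal.pred_mean) > 0)

    def test_rst_definition_runs_on_time_scale(self, default_trial):
        d = default_trial.data
        pred = default_trial.true_benefit("RST", 2.0)
        cal = grouped_calibration(d, pred, t_star=2.0, n_groups=5, definition="RST")
        assert cal.definition == "RST"
        assert np.all(np.abs(cal.observed[cal.group_valid]) <= 2.0)

    def test_oracle_predictions_well_calibrated_at_large_n(self):
        """True-benefit predictions on a large draw: slope CI covers 1,
        intercept CI covers 0."""
        sim = simulate_trial(dataclasses.replace(PAPER_DEFAULT_CONFIG, n=20000), seed=31)
        pred = sim.true_benefit("SP", 2.0)
        cal = grouped_calibration(sim.data, pred, t_star=2.0, n_groups=5)
        assert cal.a1_ci[0] < 1.0 < cal.a1_ci[1]
        assert cal.a0_ci[0] < 0.0 < cal.a0_ci[1]
        assert abs(cal.bias) < 0.02


class TestKmOverlay:
    def test_constant_prediction_mean_curve(self, default_trial):
        d = default_trial.data
        grid = TimeGrid.default(3.0, 30)
        ones = np.ones((d.n, 30))
        pair = SurvivalCurvePair(grid=grid, s1=ones, s0=ones)
        overlay = km_overlay(d, pair)
        for arm in (0, 1):
            np.testing.assert_allclose(overlay[arm]["pred_mean"], 1.0)

    def test_oracle_curves_track_km(self):
        """True survival curves averaged per arm stay inside the KM noise
        band on a large simulated draw."""
        sim = simulate_trial(dataclasses.replace(PAPER_DEFAULT_CONFIG, n=20000), seed=32)
        d = sim.data
        grid = TimeGrid.default(3.0, 25)
        pair = SurvivalCurvePair.from_exponential_rates(sim.true_rate1, sim.true_rate0, grid)
        overlay = km_overlay(d, pair)
        for arm in (0, 1):
            km_at = np.interp(
                grid.times, overlay[arm]["times"], overlay[arm]["km"], left=1.0
            )
            assert np.max(np.abs(km_at - overlay[arm]["pred_mean"])) < 0.03


class TestRcsBasis:
    def test_linear_in_the_tails(self):
        knots = np.array([-1.0, 0.0, 1.0])
        x = np.linspace(2.0, 5.0, 10)  # beyond the last knot
        basis = rcs_basis(x, knots)
        # each column is affine in x out there: second differences vanish
        for j in range(basis.shape[1]):
            assert np.allclose(np.diff(basis[:, j], 2), 0.0, atol=1e-9)

    def test_column_count_is_knots_minus_one(self):
        x = np.linspace(-2, 2, 50)
        for k in (3, 4, 5):
            knots = np.linspace(-1, 1, k)
            assert rcs_basis(x, knots).shape == (50, k - 1)


class TestSmoothCalibration:
    def test_oracle_model_tracks_identity(self):
        sim = simulate_trial(dataclasses.replace(PAPER_DEFAULT_CONFIG, n=8000), seed=33)
        grid = TimeGrid.default(6.0, 50)
        pair = SurvivalCurvePair.from_exponential_rates(sim.true_rate1, sim.true_rate0, grid)
        curve = smooth_calibration(sim.data, pair, t_star=2.0)
        dev = np.abs(curve.observed - curve.predicted)
        assert np.mean(dev) < 0.03
        assert np.all(np.abs(curve.observed) <= 1.0)

    def test_boundary_survival_clamped_not_crashed(self):
        rng = np.random.default_rng(4)
        n = 200
        trial = trial_from_arrays(
            rng.exponential(1, n) + 0.01, np.ones(n, int), np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        )
        grid = TimeGrid.default(5.0, 20)
        s1 = np.clip(rng.uniform(0.2, 1.0, (n, 1)) - 0.05 * np.arange(20) / 20, 0, 1)
        s1[0] = 1.0  # survival exactly 1 -> cll would be -inf without the clamp
        s0 = np.clip(s1 - rng.uniform(-0.1, 0.1, (n, 1)), 0.0, 1.0)
        pair = SurvivalCurvePair(grid=grid, s1=s1, s0=s0)
        curve = smooth_calibration(trial, pair, t_star=2.0)
        assert np.all(np.isfinite(curve.observed))

    def test_noise_model_gives_flat_observed_benefit(self):
        """Predictions independent of everything: the quasi-observed benefit
        stays near the (flat) average effect across the predicted range."""
        sim = simulate_trial(dataclasses.replace(PAPER_DEFAULT_CONFIG, n=4000), seed=35)
        rng = np.random.default_rng(36)
        grid = TimeGrid.default(6.0, 40)
        # random curves unrelated to the data
        r1 = rng.uniform(0.2, 0.8, sim.data.n)
        r0 = rng.uniform(0.2, 0.8, sim.data.n)
        pair = SurvivalCurvePair.from_exponential_rates(r1, r0, grid)
        curve = smooth_calibration(sim.data, pair, t_star=2.0)
        spread = np.ptp(curve.observed)
        pred_spread = np.ptp(curve.predicted)
        assert spread < 0.5 * pred_spread

    def test_invariant_to_participant_order(self):
        sim = simulate_trial(dataclasses.replace(PAPER_DEFAULT_CONFIG, n=500), seed=37)
        grid = TimeGrid.default(6.0, 30)
        pair = SurvivalCurvePair.from_exponential_rates(sim.true_rate1, sim.true_rate0, grid)
        curve = smooth_calibration(sim.data, pair, t_star=2.0)

        perm = np.random.default_rng(38).permutation(sim.data.n)
        d2 = sim.data.subset(perm)
        pair2 = SurvivalCurvePair.from_exponential_rates(
            sim.true_rate1[perm], sim.true_rate0[perm], grid
        )
        curve2 = smooth_calibration(d2, pair2, t_star=2.0)
        np.testing.assert_allclose(
            curve.observed[perm], curve2.observed, atol=1e-8
        )
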