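"""C-for-benefit: pair rules, matching, concordance vs brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survbenefit import (
    MatchedPairSet,
    c_for_benefit,
    concordance_for_benefit,
    match_by_benefit,
    match_by_covariates,
    observed_pair_benefit,
)

from conftest import trial_from_arrays


def brute_force_concordance(obs, pred):
    """O(P^2) double loop over pair-of-pair combinations with unequal
    observed benefit; predicted-benefit ties score 0.5."""
    num, den = 0.0, 0
    P = len(obs)
    for i in range(P):
        for j in range(i + 1, P):
            if obs[i] == obs[j]:
                continue
            den += 1
            hi, lo = (i, j) if obs[i] > obs[j] else (j, i)
            if pred[hi] > pred[lo]:
                num += 1.0
            elif pred[hi] == pred[lo]:
                num += 0.5
    return np.nan if den == 0 else num / den


def pair_set(obs, pred):
    obs = np.asarray(obs, int)
    pred = np.asarray(pred, float)
    k = len(obs)
    return MatchedPairSet(
        treated_idx=np.arange(k),
        control_idx=np.arange(k, 2 * k),
        observed_benefit=obs,
        pair_pred_benefit=pred,
        matching_mode="by_benefit",
        replicate_seed=None,
    )


class TestObservedPairBenefit:
    @pytest.mark.parametrize(
        "treated, control, expected",
        [
            ((5.0, 1), (3.0, 1), +1),   # control died first
            ((2.0, 1), (4.0, 1), -1),   # treated died first
            ((5.0, 1), (3.0, 0), 0),    # shorter follow-up censored
            ((2.0, 0), (4.0, 1), 0),
            ((3.0, 1), (3.0, 1), 0),    # equal times: neither is shorter
        ],
    )
    def test_rule(self, treated, control, expected):
        assert observed_pair_benefit(treated, control) == expected


class TestMatchByBenefit:
    def test_rank_sort_hand_trace(self):
        # treated preds (0.3, 0.1); control preds (0.25, 0.05)
        trial = trial_from_arrays([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0])
        pred = np.array([0.3, 0.1, 0.25, 0.05])
        pairs = match_by_benefit(trial, pred, seed=0)
        got = sorted(zip(pairs.treated_idx, pairs.control_idx))
        assert got == [(0, 2), (1, 3)]
        np.testing.assert_allclose(sorted(pairs.pair_pred_benefit), [0.075, 0.275])

    def test_balanced_arms_matching_is_seed_free(self):
        trial = trial_from_arrays([1, 2, 3, 4], [1, 0, 1, 1], [1, 1, 0, 0])
        pred = np.array([0.4, 0.1, 0.3, 0.2])
        a = match_by_benefit(trial, pred, seed=1)
        b = match_by_benefit(trial, pred, seed=999)
        np.testing.assert_array_equal(a.treated_idx, b.treated_idx)
        np.testing.assert_array_equal(a.control_idx, b.control_idx)

    def test_unbalanced_arms_exclude_exactly_the_excess(self):
        rng = np.random.default_rng(0)
        n1, n0 = 13, 10
        trial = trial_from_arrays(
            rng.exponential(1, n1 + n0) + 0.01,
            np.ones(n1 + n0, int),
            np.r_[np.ones(n1, int), np.zeros(n0, int)],
        )
        pred = rng.standard_normal(n1 + n0)
        sets = {tuple(sorted(match_by_benefit(trial, pred, seed=s).treated_idx)) for s in range(8)}
        assert all(len(s) == n0 for s in sets)
        assert len(sets) > 1, "exclusions should differ across seeds"


class TestMatchByCovariates:
    def test_identical_vectors_match_at_distance_zero(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 1.0, 2.0]})
        trial = trial_from_arrays([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0], cov=cov)
        pairs = match_by_covariates(trial, np.zeros(4), seed=0)
        got = sorted(zip(pairs.treated_idx, pairs.control_idx))
        assert got == [(0, 2), (1, 3)]

    def test_one_covariate_toy_exhaustive(self):
        # treated x = {0, 10}, control x = {1, 9}: optimal assignment pairs 0-1, 10-9
        cov = pd.DataFrame({"x": [0.0, 10.0, 1.0, 9.0]})
        trial = trial_from_arrays([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0], cov=cov)
        for seed in range(6):
            pairs = match_by_covariates(trial, np.zeros(4), seed=seed)
            assert sorted(zip(pairs.treated_idx, pairs.control_idx)) == [(0, 2), (1, 3)]

    def test_constant_covariate_falls_back_with_warning(self):
        cov = pd.DataFrame({"x": np.ones(6)})
        trial = trial_from_arrays([1, 2, 3, 4, 5, 6], [1] * 6, [1, 1, 1, 0, 0, 0], cov=cov)
        with pytest.warns(UserWarning, match="singular"):
            pairs = match_by_covariates(trial, np.zeros(6), seed=0)
        assert pairs.n_pairs == 3

    def test_propensity_option_runs(self, default_trial):
        d = default_trial.data.subset(np.arange(200))
        pred = np.random.default_rng(1).standard_normal(200)
        pairs = match_by_covariates(d, pred, seed=2, method="propensity")
        assert pairs.n_pairs == min(int((d.arm == 1).sum()), int((d.arm == 0).sum()))


class TestConcordance:
    def test_single_comparable_combination(self):
        c, _ = concordance_for_benefit(pair_set([1, -1], [0.2, -0.1]))
        assert c == 1.0

    def test_all_predicted_ties_give_half(self):
        c, _ = concordance_for_benefit(pair_set([1, -1, 0, 1], [0.3] * 4))
        assert c == 0.5

    def test_no_comparable_combinations_flagged(self):
        c, v = concordance_for_benefit(pair_set([1, 1, 1], [0.1, 0.2, 0.3]))
        assert np.isnan(c) and np.isnan(v)

    @given(
        st.lists(
            st.tuples(st.sampled_from([-1, 0, 1]), st.integers(-5, 5)),
            min_size=2,
            max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, items):
        obs = np.array([o for o, _ in items])
        pred = np.array([p for _, p in items], dtype=float) / 2.0  # induce ties
        expected = brute_force_concordance(obs, pred)
        got, _ = concordance_for_benefit(pair_set(obs, pred))
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.tuples(st.sampled_from([-1, 0, 1]), st.integers(-8, 8)), min_size=4, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance_and_antisymmetry(self, items):
        obs = np.array([o for o, _ in items])
        pred = np.array([p for _, p in items], dtype=float)
        c1, _ = concordance_for_benefit(pair_set(obs, pred))
        c2, _ = concordance_for_benefit(pair_set(obs, 2.5 * pred - 3.0))  # strictly monotone, exact
        c3, _ = concordance_for_benefit(pair_set(obs, -pred))
        if not np.isnan(c1):
            assert c2 == pytest.approx(c1, abs=1e-12)
            assert c3 == pytest.approx(1 - c1, abs=1e-12)


class TestCForBenefit:
    def test_replicated_estimate_equals_oracle_on_each_replicate(self, default_trial):
        """Production concordance equals the double-loop oracle on every
        replicate of a small matched analysis."""
        d = default_trial.data.subset(np.arange(300))
        rng = np.random.default_rng(3)
        pred = rng.standard_normal(300)
        res = c_for_benefit(d, pred, "by_benefit", n_replicates=5, seed=4)
        # replay the replicates with the same seed stream
        rng2 = np.random.default_rng(4)
        for r in range(5):
            rep_seed = int(rng2.integers(0, 2**31 - 1))
            pairs = match_by_benefit(d, pred, seed=rep_seed)
            oracle = brute_force_concordance(pairs.observed_benefit, pairs.pair_pred_benefit)
            assert res.per_replicate[r] == pytest.approx(oracle, abs=1e-12)

    def test_uninformative_predictions_near_half(self, default_trial):
        d = default_trial.data
        pred = np.random.default_rng(8).standard_normal(d.n)
        res = c_for_benefit(d, pred, "by_benefit", n_replicates=20, seed=9)
        assert res.estimate == pytest.approx(0.5, abs=0.04)
        assert res.ci_lower < 0.5 < res.ci_upper

    def test_informative_predictions_beat_half(self, default_trial):
        sim = default_trial
        pred = sim.true_benefit("SP", 2.0)
        res = c_for_benefit(sim.data, pred, "by_benefit", n_replicates=20, seed=10)
        assert res.estimate > 0.5
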