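"""Stacked propensity estimation, percentile trimming, nearest matching."""

import numpy as np
import pandas as pd
import pytest

from holcwells import (
    fit_propensity,
    match_nearest,
    simulate_matched_scenario,
    trim_by_percentile,
)
from holcwells.propensity import (
    PropensityModel,
    standardized_mean_differences,
)

import oracles


class TestStackedPropensity:
    def test_weights_on_simplex_and_stack_no_worse_than_best_learner(self):
        y, a, W, _ = simulate_matched_scenario(150, 1.0, seed=0)
        res = fit_propensity(W, a, k_folds=5, seed=1)
        w = res.weights
        assert np.all(w >= 0) and np.isclose(w.sum(), 1.0)
        best_single = min(v for k, v in res.cv_risk.items() if k != "stacked")
        assert res.cv_risk["stacked"] <= best_single + 1e-12

    def test_independent_labels_mean_score_near_treated_fraction(self):
        rng = np.random.default_rng(2)
        n = 2000
        X = rng.normal(size=(n, 5))
        a = rng.random(n) < 0.4  # independent of X
        res = fit_propensity(X, a.astype(int), k_folds=5, seed=3)
        assert abs(res.scores.mean() - a.mean()) < 0.02

    def test_scores_monotone_in_single_increasing_covariate(self):
        rng = np.random.default_rng(4)
        n = 1500
        x = np.sort(rng.normal(size=n))
        a = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x))).astype(int)
        res = fit_propensity(x[:, None], a, k_folds=5, seed=5)
        s = res.predict(np.linspace(x.min(), x.max(), 200)[:, None])
        assert np.all(np.diff(s) > -1e-9)

    def test_too_few_units_per_arm_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        a = np.r_[np.ones(10), np.zeros(40)].astype(int)
        with pytest.raises(ValueError, match="20"):
            PropensityModel(X, a).fit()

    def test_zero_variance_covariate_dropped(self, caplog):
        rng = np.random.default_rng(6)
        X = np.column_stack([rng.normal(size=200), np.full(200, 7.0)])
        a = (rng.random(200) < 0.5).astype(int)
        with caplog.at_level("WARNING"):
            res = fit_propensity(X, a, k_folds=5, seed=7)
        assert "zero-variance" in caplog.text
        assert np.isfinite(res.scores).all()


class TestTrimByPercentile:
    def test_200_equally_spaced_scores_drop_two_per_tail(self):
        scores = np.linspace(0.005, 0.995, 200)
        mask = trim_by_percentile(scores)
        assert (~mask[:2]).all() and (~mask[-2:]).all()
        assert mask[2:-2].all()

    def test_identical_scores_nothing_excluded(self):
        mask = trim_by_percentile(np.full(50, 0.5))
        assert mask.all()

    def test_retained_scores_lie_within_percentile_band(self):
        rng = np.random.default_rng(8)
        scores = rng.beta(2, 3, 500)
        mask = trim_by_percentile(scores)
        p1, p99 = np.percentile(scores, [1, 99])
        assert scores[mask].min() >= p1 and scores[mask].max() <= p99

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sort_based_quantile_oracle(self, seed):
        scores = np.random.default_rng(seed).random(157)
        got = trim_by_percentile(scores)
        want = oracles.quantile_trim_oracle(scores, 1.0, 99.0)
        assert (got == want).all()

    def test_per_arm_mode_trims_within_arms(self):
        rng = np.random.default_rng(9)
        scores = np.r_[rng.uniform(0.0, 0.5, 100), rng.uniform(0.5, 1.0, 100)]
        a = np.r_[np.zeros(100), np.ones(100)].astype(int)
        mask = trim_by_percentile(scores, mode="per_arm", a=a)
        for arm in (0, 1):
            want = oracles.quantile_trim_oracle(scores[a == arm], 1.0, 99.0)
            assert (mask[a == arm] == want).all()

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            trim_by_percentile(np.linspace(0, 1, 9))

    def test_trim_removes_at_most_band_plus_ties(self):
        rng = np.random.default_rng(10)
        scores = rng.random(1000)
        mask = trim_by_percentile(scores)
        assert (~mask).sum() <= int(np.ceil(0.02 * 1000)) + 2


class TestMatchNearest:
    def test_single_treated_matches_nearest_control(self):
        scores = {"t": 0.50, "c1": 0.40, "c2": 0.45, "c3": 0.70}
        ms = match_nearest(scores, ["t"], ["c1", "c2", "c3"])
        assert ms.pairs == [("t", "c2", pytest.approx(0.05))]

    def test_replacement_reuses_control_with_weight(self):
        scores = {"t1": 0.50, "t2": 0.51, "c": 0.52}
        ms = match_nearest(scores, ["t1", "t2"], ["c"])
        assert [p[1] for p in ms.pairs] == ["c", "c"]
        assert ms.control_weights["c"] == 2

    def test_ties_break_to_smallest_control_id(self):
        scores = {"t": 0.5, "cb": 0.6, "ca": 0.4}
        ms = match_nearest(scores, ["t"], ["cb", "ca"])
        assert ms.pairs[0][1] == "ca"

    def test_empty_control_arm_rejected(self):
        with pytest.raises(ValueError, match="control"):
            match_nearest({"t": 0.5}, ["t"], [])

    def test_every_gap_is_the_allpairs_minimum(self):
        rng = np.random.default_rng(11)
        t_ids = [f"t{i}" for i in range(100)]
        c_ids = [f"c{i}" for i in range(100)]
        scores = pd.Series(
            rng.random(200), index=t_ids + c_ids
        )
        ms = match_nearest(scores, t_ids, c_ids)
        for t, c, gap in ms.pairs:
            brute = min(abs(scores[t] - scores[cc]) for cc in c_ids)
            assert gap == pytest.approx(brute)
        assert [p[0] for p in ms.pairs] == t_ids  # each treated exactly once

    def test_affine_score_transform_preserves_matches(self):
        rng = np.random.default_rng(12)
        t_ids = [f"t{i}" for i in range(40)]
        c_ids = [f"c{i}" for i in range(40)]
        scores = pd.Series(rng.random(80), index=t_ids + c_ids)
        base = match_nearest(scores, t_ids, c_ids)
        affine = match_nearest(0.3 * scores + 0.1, t_ids, c_ids)
        assert [p[:2] for p in base.pairs] == [p[:2] for p in affine.pairs]


def test_matching_improves_covariate_balance_in_aggregate():
    """Across seeds, matching shrinks the mean |SMD| for nearly every covariate."""
    pre, post = [], []
    for seed in range(60):
        y, a, W, _ = simulate_matched_scenario(120, 1.0, seed=seed, confounding=1.0)
        ids = [f"u{i}" for i in range(len(a))]
        res = fit_propensity(W, a, k_folds=5, seed=seed)
        scores = pd.Series(res.scores, index=ids)
        treated = [i for i, ai in zip(ids, a) if ai == 1]
        controls = [i for i, ai in zip(ids, a) if ai == 0]
        ms = match_nearest(scores, treated, controls)
        pre.append(standardized_mean_differences(W, a))
        matched = treated + sorted(ms.control_weights)
        idx = [ids.index(i) for i in matched]
        wts = np.array([1.0] * len(treated) +
                       [ms.control_weights[c] for c in sorted(ms.control_weights)])
        post.append(standardized_mean_differences(
            W.iloc[idx], a[idx], weights=wts))
    mean_pre = pd.concat(pre, axis=1).mean(axis=1)
    mean_post = pd.concat(post, axis=1).mean(axis=1)
    assert (mean_post < mean_pre).sum() >= 9
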