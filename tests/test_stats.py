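"""Evaluation statistics: Pearson t-test, BH-FDR, daily binning, sparsity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from touchtrace.detrend import DetectorSeries
from touchtrace.stats import (
    bh_fdr,
    daily_binned_correlation,
    detector_sparsity,
    evaluate_predictions,
    pearson_r_test,
    performance_vs_activity,
    rmse,
)


def brute_force_bh(pvals, alpha=0.05):
    """Exhaustive step-up oracle: reject H(1..k) for the largest k with
    p_(k) <= k/m * alpha."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2, 3, 4, 7])
        r, t, p = pearson_r_test(x, x)
        assert r == 1.0 and p == 0.0

    def test_dof_convention_n_minus_2(self):
        # 791 evaluated hours -> t on 789 degrees of freedom
        rng = np.random.default_rng(0)
        x = rng.standard_normal(791)
        y = 0.5 * x + rng.standard_normal(791)
        r, t, p = pearson_r_test(x, y)
        expected_t = r * np.sqrt(789) / np.sqrt(1 - r**2)
        assert t == pytest.approx(expected_t, rel=1e-12)

    def test_matches_textbook_formula_and_scipy(self):
        from scipy import stats as ss

        x = np.array([2.1, 3.4, 1.2, 5.6, 4.4, 3.3, 2.2, 6.1, 0.5, 4.0])
        y = np.array([1.0, 2.2, 0.8, 4.9, 5.0, 2.9, 1.4, 5.5, 1.1, 3.6])
        r, t, p = pearson_r_test(x, y)
        n = len(x)
        sx, sy = x - x.mean(), y - y.mean()
        r_direct = (sx @ sy) / np.sqrt((sx @ sx) * (sy @ sy))
        assert r == pytest.approx(r_direct, abs=1e-12)
        t_direct = r_direct * np.sqrt(n - 2) / np.sqrt(1 - r_direct**2)
        assert t == pytest.approx(t_direct, abs=1e-12)
        r_sp, p_sp = ss.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_zero_variance_flagged_nan(self):
        r, t, p = pearson_r_test(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 50))
        r1, *_ = pearson_r_test(x, y)
        r2, *_ = pearson_r_test(3.0 * x - 7.0, 0.5 * y + 2.0)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestBHFDR:
    def test_single_small_p_rejected(self):
        reject, adj = bh_fdr([0.01], alpha=0.05)
        assert reject[0]

    def test_all_ones_none_rejected(self):
        reject, adj = bh_fdr(np.ones(6))
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_eight_mixed_pvalues_match_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205])
        reject, _ = bh_fdr(p)
        np.testing.assert_array_equal(reject, brute_force_bh(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_exhaustive_oracle_all_small_families(self, pvals, alpha):
        reject, adj = bh_fdr(pvals, alpha=alpha)
        np.testing.assert_array_equal(reject, brute_force_bh(pvals, alpha))
        assert np.all(np.diff(adj[np.argsort(pvals, kind="stable")]) >= -1e-12)


class TestDaily:
    def test_identity_prediction_daily_r_one(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(20, size=10 * 24).astype(float)
        hours = np.arange(10 * 24)
        r, p, n = daily_binned_correlation(y, y, hours)
        assert r == 1.0 and n == 10

    def test_within_day_shuffle_leaves_daily_sums(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(15, size=8 * 24).astype(float)
        pred = rng.poisson(15, size=8 * 24).astype(float)
        hours = np.arange(8 * 24)
        shuffled = pred.copy()
        for d in range(8):
            sl = slice(d * 24, (d + 1) * 24)
            shuffled[sl] = rng.permutation(shuffled[sl])
        r1, _, _ = daily_binned_correlation(pred, y, hours)
        r2, _, _ = daily_binned_correlation(shuffled, y, hours)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_partially_masked_days_dropped(self):
        rng = np.random.default_rng(9)
        y = rng.poisson(10, size=7 * 24).astype(float)
        hours = np.arange(7 * 24)
        mask = np.ones(len(y), dtype=bool)
        mask[30] = False  # corrupts day 1 -> 6 complete days remain
        r, p, n = daily_binned_correlation(y, y, hours, mask)
        assert n == 6 and r == 1.0
        mask[1::24] = False  # every day partially masked
        with pytest.raises(ValueError):
            daily_binned_correlation(y, y, hours, mask)

    def test_multiday_coupling_survives_daily_binning(self):
        """Multi-day structure shows up daily; a pure 24 h cycle does not."""
        rng = np.random.default_rng(4)
        t = np.arange(40 * 24)
        slow = np.sin(2 * np.pi * t / (6 * 24))
        fast = np.sin(2 * np.pi * t / 24)
        obs_slow = 50 + 20 * slow + rng.standard_normal(len(t))
        pred_slow = 50 + 20 * slow + rng.standard_normal(len(t))
        r_slow, p_slow, _ = daily_binned_correlation(pred_slow, obs_slow, t)
        obs_fast = 50 + 20 * fast + rng.standard_normal(len(t))
        pred_fast = 50 + 20 * fast + rng.standard_normal(len(t))
        r_fast, _, _ = daily_binned_correlation(pred_fast, obs_fast, t)
        assert r_slow > 0.8 and p_slow < 1e-4
        assert abs(r_fast) < 0.5


def test_too_few_days_raises():
    y = np.arange(3 * 24, dtype=float)
    with pytest.raises(ValueError):
        daily_binned_correlation(y, y, np.arange(len(y)))


class TestActivity:
    def test_sparsity_values(self):
        counts = np.zeros((100, 1), dtype=np.int64)
        counts[:60, 0] = 2
        s = DetectorSeries(hours=np.arange(100, dtype=np.int64), counts=counts)
        assert detector_sparsity(s)[0] == pytest.approx(0.4)

    def test_performance_declines_with_sparsity_detected(self):
        sparsity = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        model_r = 0.6 - 0.5 * sparsity + np.array([0.01, -0.02, 0.0, 0.02, -0.01])
        out = performance_vs_activity(model_r, sparsity)
        r, t, p = out["sparsity"]
        assert r < -0.9 and p < 0.05

    def test_constant_sparsity_flagged(self):
        out = performance_vs_activity(
            np.array([0.2, 0.4, 0.3, 0.5]), np.full(4, 0.5)
        )
        assert np.isnan(out["sparsity"][0])

    def test_requires_four_results(self):
        with pytest.raises(ValueError):
            performance_vs_activity(np.array([0.1, 0.2]), np.array([0.3, 0.4]))


def test_evaluate_predictions_report_shape():
    rng = np.random.default_rng(5)
    n = 12 * 24
    hours = np.arange(n)
    targets = rng.poisson(10, size=(n, 2)).astype(float)
    pred = targets + rng.standard_normal((n, 2))
    mask = np.ones(n, dtype=bool)
    rep = evaluate_predictions(pred, targets, hours, mask, ["D1", "D1-24h-d"])
    assert len(rep.channels) == 2
    for ch in rep.channels:
        assert ch.dof == ch.n_hours_evaluated - 2
        assert ch.rmse >= 0
        assert ch.fdr_rejected  # near-perfect predictions
    assert rep.daily["D1"][0] > 0.9
    d = rep.to_dict()
    assert set(d) == {"channels", "daily", "diagnostics"}
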