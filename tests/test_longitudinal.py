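"""Granger tests, propensity curves and linear fits."""

import numpy as np
import pytest

from ohf_engage.engagement_core import EngagementLedger, UserEngagementSeries
from ohf_engage.events import WEEK, ActivityPanel, BondEvent
from ohf_engage.longitudinal import (
    PropensityCurve,
    bond_propensity,
    fit_line,
    granger_test,
    lag_scan,
    retention_propensity,
)
from ohf_engage.synthetic_data import simulate_coupled_series


class TestGranger:
    def test_matches_statsmodels_f_test(self):
        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(42)
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        y[2:] += 0.3 * x[:-2]
        res = granger_test(x, y, lag=2)
        data = np.column_stack([y, x])  # statsmodels: col 2 causes col 1
        sm_res = grangercausalitytests(data, maxlag=2, verbose=False)
        f_sm, p_sm, *_ = sm_res[2][0]["ssr_ftest"]
        assert res.x_to_y.f_stat == pytest.approx(f_sm, rel=1e-8)
        assert res.x_to_y.p_value == pytest.approx(p_sm, rel=1e-8, abs=1e-12)

    def test_planted_lag2_coupling_detected(self):
        x, y = simulate_coupled_series(500, lag=2, coeff=0.8, seed=11)
        res = granger_test(x, y, lag=2)
        assert res.x_to_y.p_value < 1e-3
        assert res.y_to_x.p_value > 0.01  # no reverse structure

    def test_null_rejection_is_roughly_nominal(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.standard_normal(120)
            y = rng.standard_normal(120)
            if granger_test(x, y, lag=2).x_to_y.p_value < 0.05:
                rejections += 1
        # 3 binomial SEs around 0.05 at 200 reps
        assert 0.05 - 3 * 0.0154 <= rejections / reps <= 0.05 + 3 * 0.0154

    def test_noiseless_shifted_copy_is_perfectly_predictable(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        y = np.zeros(100)
        y[2:] = x[:-2]
        res = granger_test(x, y, lag=2)
        assert res.x_to_y.rss_unrestricted == pytest.approx(0.0, abs=1e-12)
        assert res.x_to_y.rss_restricted > 1.0
        assert res.x_to_y.p_value < 1e-12

    def test_unrestricted_rss_never_exceeds_restricted(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            res = granger_test(rng.standard_normal(80),
                               rng.standard_normal(80), lag=3)
            for d in (res.x_to_y, res.y_to_x):
                assert d.rss_unrestricted <= d.rss_restricted + 1e-12
                assert d.f_stat >= 0
                assert 0 <= d.p_value <= 1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            granger_test(np.ones(50), np.arange(50.0), lag=2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="length"):
            granger_test(np.arange(8.0), np.arange(8.0) ** 2, lag=2)

    def test_first_differencing_removes_shared_trend(self):
        rng = np.random.default_rng(9)
        trend = np.linspace(0, 50, 400)
        x = trend + rng.standard_normal(400)
        y = trend + rng.standard_normal(400)
        res = granger_test(x, y, lag=2, difference=True)
        assert res.differenced
        assert res.x_to_y.p_value > 0.01

    def test_lag_scan_prefers_true_lag(self):
        for seed in (21, 22, 23):
            x, y = simulate_coupled_series(800, lag=3, coeff=0.9, seed=seed)
            bics = lag_scan(x, y, max_lag=6, criterion="bic")
            assert min(bics, key=bics.get) == 3


def _curve(thresholds, numer, denom):
    return PropensityCurve(np.asarray(thresholds, float),
                           np.asarray(numer, float),
                           np.asarray(denom, float))


class TestBondPropensity:
    def test_constructed_arithmetic(self):
        ledger = EngagementLedger()
        for k in range(5):
            ledger.targeted[("i", f"z{k}")] = 0.1  # below threshold
        ledger.targeted[("i", "j")] = 2.0
        bonds = [BondEvent("i", "j", 100)]
        curve = bond_propensity(ledger, bonds, thresholds=[1.0])
        assert curve.denominators[0] == 1
        assert curve.proportions[0] == 1.0

    def test_threshold_zero_is_unfiltered(self):
        ledger = EngagementLedger()
        ledger.targeted[("a", "b")] = 0.5
        ledger.targeted[("a", "c")] = 1.5
        ledger.targeted[("b", "a")] = 3.0
        bonds = [BondEvent("a", "c", 10)]
        curve = bond_propensity(ledger, bonds, thresholds=[0.0])
        assert curve.denominators[0] == 3
        assert curve.proportions[0] == pytest.approx(1 / 3)

    def test_universe_adds_zero_pairs_at_threshold_zero(self):
        ledger = EngagementLedger()
        ledger.targeted[("a", "b")] = 1.0
        curve = bond_propensity(ledger, [], thresholds=[0.0, 0.5],
                                universe=[("c", "d"), ("d", "c")])
        assert curve.denominators[0] == 3
        assert curve.denominators[1] == 1

    def test_denominators_non_increasing_and_proportions_bounded(self, rng):
        ledger = EngagementLedger()
        users = [f"u{i}" for i in range(30)]
        for _ in range(200):
            i, j = rng.choice(30, 2, replace=False)
            ledger.targeted[(users[i], users[j])] = (
                ledger.targeted.get((users[i], users[j]), 0.0)
                + float(rng.exponential(0.7)))
        bonds = [BondEvent(users[i], users[j], 0)
                 for i, j in [(0, 1), (2, 3), (4, 5)]]
        curve = bond_propensity(ledger, bonds)
        assert (np.diff(curve.denominators) <= 0).all()
        p = curve.proportions[curve.defined()]
        assert ((p >= 0) & (p <= 1)).all()

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bond_propensity(EngagementLedger(), [])


class TestRetentionPropensity:
    def _panel(self, users, active):
        arr = np.asarray(active, dtype=bool)
        return ActivityPanel(0, arr.shape[1], users, arr)

    def _series(self, user, values):
        s = UserEngagementSeries(user, WEEK, 0)
        for w, v in values.items():
            s.values[w] = v
        return s

    def test_single_observation_bookkeeping(self):
        panel = self._panel(["A"], [[True, True]])
        series = {"A": self._series("A", {0: 2.0})}
        curve = retention_propensity(series, panel, thresholds=[0.0, 1.0, 2.0])
        assert list(curve.denominators) == [1, 1, 1]
        assert list(curve.proportions) == [1.0, 1.0, 1.0]

    def test_zero_capacity_only_defined_at_zero(self):
        panel = self._panel(["A", "B"], [[True, False], [False, True]])
        curve = retention_propensity({}, panel, thresholds=[0.0, 1.0])
        assert curve.denominators[0] == 2
        assert curve.denominators[1] == 0
        assert np.isnan(curve.proportions[1])

    def test_final_week_excluded(self):
        panel = self._panel(["A"], [[True, True, True]])
        series = {"A": self._series("A", {0: 1.0, 1: 1.0, 2: 9.0})}
        curve = retention_propensity(series, panel, thresholds=[5.0])
        # capacity 9.0 falls in the final week, which has no week t+1
        assert curve.denominators[0] == 0

    def test_fewer_than_two_weeks_rejected(self):
        panel = self._panel(["A"], [[True]])
        with pytest.raises(ValueError, match="2 weeks"):
            retention_propensity({}, panel)

    def test_misaligned_series_rejected(self):
        panel = self._panel(["A"], [[True, True]])
        bad = {"A": UserEngagementSeries("A", 86400, 0)}
        with pytest.raises(ValueError, match="7-day"):
            retention_propensity(bad, panel)

    def test_logistic_retention_gives_monotone_curve(self):
        rng = np.random.default_rng(17)
        users = [f"u{i}" for i in range(200)]
        caps = rng.exponential(2.0, size=(200, 9))
        prob = 1 / (1 + np.exp(-(-1.0 + 0.8 * caps)))
        nxt = rng.random((200, 9)) < prob
        active = np.zeros((200, 10), dtype=bool)
        active[:, 1:] = nxt
        panel = self._panel(users, active)
        series = {
            u: self._series(u, {w: caps[i, w] for w in range(9)})
            for i, u in enumerate(users)
        }
        curve = retention_propensity(series, panel,
                                     thresholds=np.arange(0, 4.5, 0.5))
        p = curve.proportions[curve.defined()]
        # monotone non-decreasing within binomial noise
        assert (np.diff(p) > -0.05).all()
        assert p[-1] > p[0]


class TestFitLine:
    def test_perfect_line(self):
        curve = _curve([0, 1, 2, 3], [0, 10, 20, 30], [100, 100, 100, 100])
        fit = fit_line(curve)
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_flat_scatter_has_near_zero_slope(self):
        rng = np.random.default_rng(2)
        n = 20
        y = 0.5 + 0.01 * rng.standard_normal(n)
        curve = _curve(np.arange(n), (y * 100).round(), np.full(n, 100.0))
        fit = fit_line(curve)
        assert abs(fit.slope) < 0.01
        assert fit.adjusted_r2 <= 1.0

    def test_matches_hand_normal_equations(self, rng):
        x = np.arange(12, dtype=float)
        y = rng.random(12)
        curve = _curve(x, y * 50, np.full(12, 50.0))
        fit = fit_line(curve)
        # hand-coded normal equations for slope/intercept
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm))
        intercept = ym - slope * xm
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        resid = y - (intercept + slope * x)
        r2 = 1 - (resid @ resid) / ((y - ym) @ (y - ym))
        adj = 1 - (1 - r2) * (12 - 1) / (12 - 2)
        assert fit.adjusted_r2 == pytest.approx(adj, abs=1e-9)

    def test_too_few_points_rejected(self):
        curve = _curve([0, 1], [1, 2], [10, 10])
        with pytest.raises(ValueError, match="3"):
            fit_line(curve)
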