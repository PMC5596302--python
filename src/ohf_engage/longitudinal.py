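"""Longitudinal analyses: Granger causality, propensity curves, linear fits.

Granger causality is implemented in its classic pairwise form: for each
direction, the target series is regressed on a constant and ``lag`` of its
own past values (restricted model), and additionally on ``lag`` past values
of the candidate cause (unrestricted model).  The F statistic

    F = ((RSS_r - RSS_u) / lag) / (RSS_u / (n - 2*lag - 1))

with (lag, n - 2*lag - 1) degrees of freedom tests whether the cause's
history improves prediction.  Both directions are always reported, since
establishing a one-way relationship requires rejecting one direction and
not the other.  Deterministic terms: constant only; an optional first
difference can be applied to both series before fitting for trending data.

Propensity curves summarise how an outcome probability grows with an
engagement score: at each threshold x the denominator counts observations
with score >= x and the numerator those with the outcome, giving the
cumulative "at least x" proportion the study's bond and retention analyses
use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .engagement_core import EngagementLedger, UserEngagementSeries
from .events import ActivityPanel, BondEvent, EventSeries, WEEK

__all__ = [
    "GrangerResult",
    "GrangerDirection",
    "PropensityCurve",
    "LinearFit",
    "granger_test",
    "lag_scan",
    "bond_propensity",
    "retention_propensity",
    "fit_line",
    "default_thresholds",
]


@dataclass(frozen=True)
class GrangerDirection:
    """One direction of a Granger test (cause -> effect)."""

    cause: str
    effect: str
    lag: int
    f_stat: float
    p_value: float
    rss_restricted: float
    rss_unrestricted: float
    n: int  # effective sample size after lagging


@dataclass(frozen=True)
class GrangerResult:
    """Two-way Granger test between series x and y."""

    lag: int
    x_to_y: GrangerDirection
    y_to_x: GrangerDirection
    differenced: bool


@dataclass
class PropensityCurve:
    """Cumulative outcome proportions over ascending score thresholds.

    ``proportions`` is NaN where the denominator is zero (undefined point).
    """

    thresholds: np.ndarray
    numerators: np.ndarray
    denominators: np.ndarray

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.numerators / self.denominators
        return np.where(self.denominators > 0, p, np.nan)

    def defined(self) -> np.ndarray:
        return self.denominators > 0


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    adjusted_r2: float
    n: int


def _as_array(series) -> np.ndarray:
    if isinstance(series, EventSeries):
        return np.asarray(series.counts, dtype=float)
    return np.asarray(series, dtype=float)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _one_direction(cause: np.ndarray, effect: np.ndarray, lag: int,
                   cause_name: str, effect_name: str) -> GrangerDirection:
    n = len(effect) - lag
    y = effect[lag:]
    own = np.column_stack([effect[lag - k:len(effect) - k] for k in range(1, lag + 1)])
    other = np.column_stack([cause[lag - k:len(cause) - k] for k in range(1, lag + 1)])
    const = np.ones((n, 1))
    rss_r = _ols_rss(y, np.hstack([const, own]))
    rss_u = _ols_rss(y, np.hstack([const, own, other]))
    df_den = n - 2 * lag - 1
    if df_den <= 0:
        raise ValueError(f"series too short for lag {lag} (df={df_den})")
    # guard: numerically rss_u can exceed rss_r by rounding
    num = max(rss_r - rss_u, 0.0) / lag
    if rss_u <= 0.0:
        f_stat = np.inf if num > 0 else 0.0
        p = 0.0 if num > 0 else 1.0
    else:
        f_stat = num / (rss_u / df_den)
        p = float(stats.f.sf(f_stat, lag, df_den))
    return GrangerDirection(cause_name, effect_name, lag, float(f_stat), p,
                            rss_r, rss_u, n)


def granger_test(
    x, y, lag: int = 2, difference: bool = False,
    names: tuple[str, str] = ("x", "y"),
) -> GrangerResult:
    """Two-way Granger causality F-test between aligned series.

    Parameters
    ----------
    x, y
        :class:`~ohf_engage.events.EventSeries` with equal bin width and
        aligned windows, or plain equal-length numeric sequences.
    lag
        Autoregression order p (the study reports lag-2 results).
    difference
        First-difference both series before fitting (for trending data).

    Raises
    ------
    ValueError
        For misaligned, too-short, or constant series.
    """
    if isinstance(x, EventSeries) and isinstance(y, EventSeries):
        if not x.aligned_with(y):
            raise ValueError("series are not aligned (bin width/anchor/length)")
        names = (x.name, y.name)
    xa, ya = _as_array(x), _as_array(y)
    if len(xa) != len(ya):
        raise ValueError("series lengths differ")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if difference:
        xa, ya = np.diff(xa), np.diff(ya)
    if len(xa) <= 3 * lag + 2:
        raise ValueError(f"need length > {3 * lag + 2} for lag {lag}, got {len(xa)}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant series: Granger regression is degenerate")
    return GrangerResult(
        lag=lag,
        x_to_y=_one_direction(xa, ya, lag, names[0], names[1]),
        y_to_x=_one_direction(ya, xa, lag, names[1], names[0]),
        differenced=difference,
    )


def lag_scan(x, y, max_lag: int = 8, difference: bool = False,
             criterion: str = "aic") -> dict[int, float]:
    """Information criterion of the unrestricted x->y regression per lag order.

    Utility for choosing a lag (the study analyses fix lag = 2).  ``aic``
    trades fit against 2 parameters; ``bic`` penalises by log(n) and is
    selection-consistent.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    xa, ya = _as_array(x), _as_array(y)
    if difference:
        xa, ya = np.diff(xa), np.diff(ya)
    if len(xa) <= 3 * max_lag + 2:
        raise ValueError(f"series too short for max_lag {max_lag}")
    # condition every fit on the same sample so AICs are comparable
    n = len(ya) - max_lag
    yv = ya[max_lag:]
    out: dict[int, float] = {}
    for lag in range(1, max_lag + 1):
        cols = [np.ones((n, 1))]
        cols.append(np.column_stack(
            [ya[max_lag - k:len(ya) - k] for k in range(1, lag + 1)]))
        cols.append(np.column_stack(
            [xa[max_lag - k:len(xa) - k] for k in range(1, lag + 1)]))
        X = np.hstack(cols)
        rss = _ols_rss(yv, X)
        k = X.shape[1]
        penalty = 2 * k if criterion == "aic" else k * np.log(n)
        out[lag] = float(n * np.log(max(rss, 1e-300) / n) + penalty)
    return out


def default_thresholds(values: Iterable[float], step: float = 0.25) -> np.ndarray:
    """Grid from 0 to the 99th percentile of ``values`` in ``step`` increments."""
    vals = np.asarray(list(values), dtype=float)
    hi = float(np.percentile(vals, 99)) if len(vals) else 0.0
    return np.arange(0.0, max(hi, step) + step / 2, step)


def bond_propensity(
    ledger: EngagementLedger,
    bonds: Sequence[BondEvent],
    thresholds: Sequence[float] | None = None,
    universe: Iterable[tuple[str, str]] | None = None,
) -> PropensityCurve:
    """Proportion of engager->engaged pairs that formed a bond, by targeted value.

    At threshold x the denominator counts ordered pairs (i, j) with
    targeted(i, j) >= x and the numerator those for which j left a first
    wall note on i's page.  The default pair universe is every pair with a
    positive targeted value; passing ``universe`` (e.g. all co-thread pairs)
    additionally includes zero-valued pairs, which enter the denominator at
    threshold 0.
    """
    if not ledger.targeted and universe is None:
        raise ValueError("empty ledger: no targeted pairs to analyse")
    values: dict[tuple[str, str], float] = dict(ledger.targeted)
    if universe is not None:
        for pair in universe:
            values.setdefault(pair, 0.0)
    bonded = {(b.engager_id, b.responder_id) for b in bonds}
    pairs = np.array(list(values.keys()), dtype=object)
    vals = np.array(list(values.values()), dtype=float)
    is_bonded = np.array([tuple(p) in bonded for p in pairs], dtype=bool)
    if thresholds is None:
        thresholds = default_thresholds(vals)
    thr = np.asarray(sorted(thresholds), dtype=float)
    denom = np.array([(vals >= t).sum() for t in thr], dtype=float)
    numer = np.array([(is_bonded & (vals >= t)).sum() for t in thr], dtype=float)
    return PropensityCurve(thr, numer, denom)


def retention_propensity(
    series: Mapping[str, UserEngagementSeries],
    panel: ActivityPanel,
    thresholds: Sequence[float] | None = None,
) -> PropensityCurve:
    """Proportion of (user, week) observations active in week t+1, by capacity in week t.

    Every user-week (u, t) with t before the final observed week is an
    observation with score = capacity earned by u in week t (zero if none);
    the outcome is u's activity indicator in week t+1.
    """
    if panel.n_weeks < 2:
        raise ValueError("need at least 2 weeks of observation")
    for s in series.values():
        if s.window_seconds != WEEK or s.anchor != panel.anchor:
            raise ValueError("capacity series must use 7-day windows on the panel anchor")
    caps = []
    outcomes = []
    for row, user in enumerate(panel.users):
        user_series = series.get(user)
        for t in range(panel.n_weeks - 1):
            cap = user_series.values.get(t, 0.0) if user_series else 0.0
            caps.append(cap)
            outcomes.append(bool(panel.active[row, t + 1]))
    vals = np.asarray(caps, dtype=float)
    out = np.asarray(outcomes, dtype=bool)
    if thresholds is None:
        thresholds = default_thresholds(vals)
    thr = np.asarray(sorted(thresholds), dtype=float)
    denom = np.array([(vals >= t).sum() for t in thr], dtype=float)
    numer = np.array([(out & (vals >= t)).sum() for t in thr], dtype=float)
    return PropensityCurve(thr, numer, denom)


def fit_line(curve: PropensityCurve) -> LinearFit:
    """OLS of proportion on threshold over the curve's defined points.

    Reports the slope, intercept and adjusted R-squared
    (1 - (1 - R2)(n - 1)/(n - 2)).
    """
    mask = curve.defined()
    x = curve.thresholds[mask]
    y = curve.proportions[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 defined points, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant proportions: R-squared undefined")
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adjusted_r2=float(model.rsquared_adj),
        n=n,
    )
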