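"""Survival statistics: Kaplan-Meier, median survival, log-rank, efficacy-curve fits.

Thin, typed wrappers around :mod:`lifelines` (product-limit estimation and
the two-group log-rank test) plus a nonlinear least-squares bi-exponential
fit ``f(x) = a e^{bx} + c e^{dx}`` used to summarise the relationship
between agent efficacy and median overall survival in population trials.
Times are in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import optimize, stats

__all__ = [
    "SurvivalCurve",
    "km_estimate",
    "median_survival",
    "logrank",
    "logrank_permutation_p",
    "fit_biexponential",
]


@dataclass
class SurvivalCurve:
    """Product-limit survival curve.

    ``times`` are the distinct observation times (months), ``survival`` the
    step-function values S(t) at those times; ``at_risk`` and ``events``
    the risk-set size and number of deaths at each time; ``censored`` marks
    times at which only censorings occurred.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    @property
    def median(self) -> float:
        return median_survival(self)


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D and equal length")
    if t.size == 0:
        raise ValueError("no observations")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    ``events`` is True for an observed death, False for right-censoring.
    Ties are handled with the standard convention (deaths precede
    censorings at the same time).
    """
    t, e = _validate(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table.iloc[1:] if 0.0 not in t else kmf.event_table
    # event_table always contains a t=0 row; drop it unless data start at 0
    tbl = kmf.event_table[kmf.event_table.index > 0] if np.all(t > 0) else kmf.event_table
    grid = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(),
        events=tbl["observed"].to_numpy(),
        censored=tbl["censored"].to_numpy() > 0,
    )


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5; NaN if S never reaches 0.5."""
    below = curve.survival <= 0.5
    if not below.any():
        return float("nan")
    return float(curve.times[np.argmax(below)])


def logrank(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df.

    Each group is ``(times, events)``.
    """
    ta, ea = _validate(*group_a)
    tb, eb = _validate(*group_b)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _logrank_chi2(t: np.ndarray, e: np.ndarray, in_a: np.ndarray) -> float:
    """Hand-rolled two-group log-rank chi-square (brute-force oracle).

    Walks the pooled distinct event times, accumulating observed-minus-
    expected deaths in group A and the hypergeometric variance.  Kept
    independent of the lifelines-backed :func:`logrank` so the two can be
    cross-checked against each other.
    """
    order = np.argsort(t, kind="stable")
    t, e, in_a = t[order], e[order], in_a[order]
    n = t.size
    obs_minus_exp = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        at_risk = n - i
        at_risk_a = int(in_a[i:].sum())
        d = int(e[i:j].sum())
        d_a = int((e[i:j] & in_a[i:j]).sum())
        if d > 0 and at_risk > 1:
            exp_a = d * at_risk_a / at_risk
            obs_minus_exp += d_a - exp_a
            var += (d * (at_risk_a / at_risk) * (1 - at_risk_a / at_risk)
                    * (at_risk - d) / (at_risk - 1))
        i = j
    if var == 0:
        return 0.0
    return obs_minus_exp**2 / var


def logrank_permutation_p(group_a, group_b, n_shuffles: int = 10_000,
                          seed: int = 0) -> float:
    """Permutation-null p-value for the log-rank statistic (label shuffling).

    Uses the hand-rolled statistic throughout, so the result is a fully
    independent check on the chi-square p-value of :func:`logrank`.
    """
    ta, ea = _validate(*group_a)
    tb, eb = _validate(*group_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    na = ta.size
    labels = np.zeros(t.size, dtype=bool)
    labels[:na] = True
    obs = _logrank_chi2(t, e, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        hits += _logrank_chi2(t, e, rng.permutation(labels)) >= obs - 1e-12
    return (hits + 1) / (n_shuffles + 1)


def _biexp(x, a, b, c, d):
    return a * np.exp(b * x) + c * np.exp(d * x)


def fit_biexponential(x, y, fix_c_zero: bool = False,
                      n_starts: int = 5, seed: int = 0
                      ) -> tuple[tuple[float, float, float, float], float]:
    """Least-squares fit of f(x) = a e^{bx} + c e^{dx}.

    Returns ``((a, b, c, d), r_squared)``.  Initialised from a log-linear
    fit (slow component from the bulk, fast component from the residual
    tail), with randomised multi-starts if the first attempt fails to
    converge.  With ``fix_c_zero`` the model reduces to a single
    exponential (c = d = 0 reported).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 (x, y) points")

    def r2(params):
        resid = y - _biexp(x, *params)
        ss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(resid**2)) / ss if ss > 0 else 1.0

    # log-linear initial guess for the dominant component
    pos = y > 0
    slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)

    if fix_c_zero:
        popt, _ = optimize.curve_fit(
            lambda xx, a, b: a * np.exp(b * xx), x, y, p0=[a0, b0], maxfev=20000
        )
        params = (float(popt[0]), float(popt[1]), 0.0, 0.0)
        return params, r2(params)

    # residual tail drives the second component's initial guess
    resid = y - a0 * np.exp(b0 * x)
    tail = resid[-max(3, x.size // 3):]
    xtail = x[-max(3, x.size // 3):]
    c0 = max(float(tail[-1]), 1e-8)
    d0 = b0 * 2 if b0 != 0 else 0.01
    if np.all(tail > 0) and tail.size >= 2:
        try:
            d0, logc0 = np.polyfit(xtail, np.log(tail), 1)
            c0 = float(np.exp(logc0))
        except Exception:
            pass

    rng = np.random.default_rng(seed)
    guesses = [(a0, b0, c0, d0)]
    guesses += [
        (a0 * rng.uniform(0.5, 2), b0 * rng.uniform(0.5, 2),
         c0 * rng.uniform(0.1, 10), d0 * rng.uniform(0.5, 2))
        for _ in range(n_starts - 1)
    ]
    last_err: Exception | None = None
    best = None
    for p0 in guesses:
        try:
            popt, _ = optimize.curve_fit(_biexp, x, y, p0=p0, maxfev=20000)
        except RuntimeError as err:
            last_err = err
            continue
        params = tuple(float(v) for v in popt)
        score = r2(params)
        if best is None or score > best[1]:
            best = (params, score)
    if best is None:
        raise RuntimeError(f"bi-exponential fit did not converge: {last_err}")
    return best
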