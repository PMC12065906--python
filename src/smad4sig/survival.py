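"""Kaplan-Meier estimation, log-rank testing and maxstat cut-point search.

The cut-point routine dichotomizes a continuous expression value by
maximally selected rank statistics: the standardized two-group log-rank
statistic is evaluated at every admissible cut between distinct expression
values (both sides must hold at least ``minprop`` of the samples) and the
cut with the largest |z| is selected.  Because the maximum over many
correlated cuts inflates the naive chi-square reference, significance is
assessed by permutation: expression values are shuffled against the
(time, event) pairs, the maximal |z| recomputed, and the p-value is the
smoothed exceedance fraction (b + 1) / (n_perm + 1).

The log-rank numerator at a fixed cut is written as a linear rank
statistic, sum over the high group of (event_i - H(t_i)) with H the
Nelson-Aalen cumulative hazard, and the variance is the usual
hypergeometric sum -- so z**2 at any fixed cut equals the ordinary
two-group log-rank chi-square exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk})


@dataclass
class CutpointResult:
    cutpoint: float
    max_statistic: float
    pvalue: float
    n_low: int
    n_high: int
    minprop: float


def km_estimate(time, event) -> KMCurve:
    """Product-limit survival estimate at the observed event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    ev_times = np.unique(time[event == 1])
    if ev_times.size == 0:
        return KMCurve(np.unique(time), np.ones(np.unique(time).size),
                       np.array([(time >= t).sum() for t in np.unique(time)]))
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    at_risk = np.array([(time >= t).sum() for t in ev_times])
    return KMCurve(ev_times, surv, at_risk)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, pvalue)."""
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _logrank_scores(time: np.ndarray, event: np.ndarray):
    """Per-sample log-rank scores and risk-set bookkeeping.

    Returns (scores a_i = event_i - H(t_i), event times, events per time d_j,
    at-risk indicator matrix B[i, j] = 1{time_i >= t_j}).
    """
    ev_times = np.unique(time[event == 1])
    B = time[:, None] >= ev_times[None, :]
    d = np.array([(event[time == t] == 1).sum() for t in ev_times], dtype=float)
    n_at_risk = B.sum(axis=0).astype(float)
    haz = d / n_at_risk
    H = B @ haz  # Nelson-Aalen cumhaz at each sample's time
    scores = event.astype(float) - H
    return scores, ev_times, d, B, n_at_risk


def _max_abs_z(order, scores, d, B, n_at_risk, lo, hi):
    """Maximal |z| over cuts k in [lo, hi) for a given sample ordering.

    Cut k puts the first k samples (in ``order``) in the low group.  Returns
    (|z| per cut, n_high at risk matrix rows reused by callers).
    """
    a_sorted = scores[order]
    B_sorted = B[order]
    cum_a = np.cumsum(a_sorted)
    cum_B = np.cumsum(B_sorted, axis=0)
    ks = np.arange(lo, hi)
    U = -cum_a[ks - 1]  # total score is zero, so high-group sum = -low sum
    n1 = n_at_risk[None, :] - cum_B[ks - 1]  # high-group at risk per event time
    frac = n1 / n_at_risk[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        hyper = d * frac * (1.0 - frac) * np.where(n_at_risk > 1,
                                                   (n_at_risk - d) / (n_at_risk - 1), 0.0)
    V = hyper.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(V > 0, np.abs(U) / np.sqrt(V), 0.0)
    return z, ks


def maxstat_cutpoint(
    expression,
    time,
    event,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cut-point for one expression variable.

    The high group is ``expression > cut`` with the cut placed midway
    between adjacent distinct values; tied values share a side.  The
    permutation p-value shuffles expression against survival.
    """
    x = np.asarray(expression, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for cut-point selection")
    if np.unique(x).size < 2:
        raise ValueError("expression must take at least 2 distinct values")
    if event.sum() == 0:
        raise ValueError("need at least one event")

    scores, ev_times, d, B, n_at_risk = _logrank_scores(time, event)
    kmin = max(int(np.ceil(minprop * n)), 1)
    lo, hi = kmin, n - kmin + 1
    if lo >= hi:
        raise ValueError("minprop leaves no admissible cut")

    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    distinct = xs[:-1] != xs[1:]  # cut after position k allowed iff xs[k-1] != xs[k]
    z_all, ks = _max_abs_z(order, scores, d, B, n_at_risk, lo, hi)
    admissible = distinct[ks - 1]
    if not admissible.any():
        raise ValueError("no admissible cut between distinct values")
    z_adm = np.where(admissible, z_all, -np.inf)
    best = int(np.argmax(z_adm))
    k_best = int(ks[best])
    z_best = float(z_all[best])
    cut = float(0.5 * (xs[k_best - 1] + xs[k_best]))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        # shuffling expression against (time, event) and re-sorting is the
        # same as assigning the samples to the sorted-x slots uniformly at
        # random; tied-x slots stay unsplittable via the admissibility mask
        perm = rng.permutation(n)
        z_p, _ = _max_abs_z(perm, scores, d, B, n_at_risk, lo, hi)
        if np.where(admissible, z_p, -np.inf).max() >= z_best:
            exceed += 1
    pvalue = (exceed + 1.0) / (n_perm + 1.0)

    n_low = k_best
    return CutpointResult(cut, z_best, float(pvalue), n_low, n - n_low, minprop)


def fixed_cut_z(expression, time, event, cut: float) -> float:
    """Standardized log-rank z for the split expression > ``cut``."""
    x = np.asarray(expression, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    scores, _, d, B, n_at_risk = _logrank_scores(time, event)
    high = x > cut
    U = scores[high].sum()
    n1 = B[high].sum(axis=0).astype(float)
    frac = n1 / n_at_risk
    with np.errstate(invalid="ignore", divide="ignore"):
        hyper = d * frac * (1.0 - frac) * np.where(n_at_risk > 1,
                                                   (n_at_risk - d) / (n_at_risk - 1), 0.0)
    V = hyper.sum()
    return float(np.abs(U) / np.sqrt(V)) if V > 0 else 0.0
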