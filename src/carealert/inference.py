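"""Two-sample binomial inference for proportion indices.

Implements every statistic the trial analysis reports for a pair of
independent binomial counts (x1/n1 vs x2/n2):

* Cohen's arcsine effect size  h = |2 asin(sqrt(p1)) - 2 asin(sqrt(p2))|;
* the pooled-variance two-proportion Z test;
* the unpooled Wald confidence interval for p1 - p2;
* the Miettinen-Nurminen (MN) score interval: inversion of the score test
  whose variance uses maximum-likelihood estimates of (p1, p2) restricted to
  p1 - p2 = delta, inflated by N/(N-1);
* the Chan-Zhang exact unconditional interval: inversion of two one-sided
  exact tests (alpha/2 each) whose p-value is the supremum over the nuisance
  proportion of the exact tail probability of the MN score statistic,
  computed by full enumeration of the joint binomial outcome space;
* a two-group McNemar contrast of paired threshold-status changes, for the
  response-bias analysis.

The restricted MLE under p1 - p2 = delta has a closed form as the root of a
cubic (Farrington & Manning's parametrization); it is used both for speed
and so the exact enumeration can evaluate the statistic on the whole
outcome grid at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom, norm

from .errors import DataError, ResourceError
from .scoring import PairedChangeCounts

_EXACT_N_MAX = 200


@dataclass(frozen=True)
class TwoSampleCounts:
    """Successes/trials for two independent groups."""

    x1: int
    n1: int
    x2: int
    n2: int
    label1: str = "group1"
    label2: str = "group2"

    def __post_init__(self) -> None:
        for x, n in ((self.x1, self.n1), (self.x2, self.n2)):
            if n < 1:
                raise DataError("each group needs at least one trial")
            if not 0 <= x <= n:
                raise DataError(f"need 0 <= x <= n, got x={x}, n={n}")

    @property
    def p1(self) -> float:
        return self.x1 / self.n1

    @property
    def p2(self) -> float:
        return self.x2 / self.n2

    @property
    def diff(self) -> float:
        return self.p1 - self.p2

    def swapped(self) -> "TwoSampleCounts":
        return TwoSampleCounts(
            self.x2, self.n2, self.x1, self.n1, self.label2, self.label1
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Bundle of two-sample comparison statistics."""

    counts: TwoSampleCounts
    p1: float
    p2: float
    diff: float
    z: Optional[float]
    p_value: Optional[float]
    h: float
    alpha: float
    cis: dict = field(default_factory=dict)  # method name -> (low, high)

    def to_dict(self) -> dict:
        d = {
            "x1": self.counts.x1,
            "n1": self.counts.n1,
            "x2": self.counts.x2,
            "n2": self.counts.n2,
            "p1": self.p1,
            "p2": self.p2,
            "diff": self.diff,
            "z": self.z,
            "p_value": self.p_value,
            "cohen_h": self.h,
            "alpha": self.alpha,
        }
        for method, (lo, hi) in self.cis.items():
            d[f"ci_{method}_low"] = lo
            d[f"ci_{method}_high"] = hi
        return d


def cohen_h(counts: TwoSampleCounts) -> float:
    """Cohen's arcsine effect size, reported as an absolute value."""
    phi1 = 2.0 * math.asin(math.sqrt(counts.p1))
    phi2 = 2.0 * math.asin(math.sqrt(counts.p2))
    return abs(phi1 - phi2)


def pooled_z_test(counts: TwoSampleCounts) -> tuple[float, float]:
    """Two-proportion Z test with pooled variance.

    z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)) with
    pbar = (x1 + x2)/(n1 + n2); two-sided p from the standard normal.
    """
    pbar = (counts.x1 + counts.x2) / (counts.n1 + counts.n2)
    if pbar in (0.0, 1.0):
        raise DataError("degenerate pooled proportion: no variation")
    se = math.sqrt(pbar * (1 - pbar) * (1 / counts.n1 + 1 / counts.n2))
    z = counts.diff / se
    return z, 2.0 * norm.sf(abs(z))


def wald_unpooled_ci(
    counts: TwoSampleCounts, alpha: float = 0.05
) -> tuple[float, float]:
    """Unpooled Wald interval for p1 - p2, clamped to [-1, 1]."""
    p1, p2 = counts.p1, counts.p2
    se = math.sqrt(
        p1 * (1 - p1) / counts.n1 + p2 * (1 - p2) / counts.n2
    )
    zc = norm.ppf(1 - alpha / 2)
    return max(counts.diff - zc * se, -1.0), min(counts.diff + zc * se, 1.0)


def _restricted_mle(
    p1h: np.ndarray, p2h: np.ndarray, n1: int, n2: int, delta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form MLE of (p1, p2) under the constraint p1 - p2 = delta.

    Vectorized over broadcastable arrays of observed proportions and delta.
    """
    theta = n2 / n1
    a = 1.0 + theta
    b = -(1.0 + theta + p1h + theta * p2h + delta * (theta + 2.0))
    c = delta**2 + delta * (2.0 * p1h + theta + 1.0) + p1h + theta * p2h
    d = -p1h * delta * (1.0 + delta)
    v = b**3 / (27.0 * a**3) - b * c / (6.0 * a**2) + d / (2.0 * a)
    s2 = b**2 / (9.0 * a**2) - c / (3.0 * a)
    s = np.sqrt(np.maximum(s2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(s > 0, np.clip(v / np.where(s > 0, s, 1.0) ** 3, -1, 1), 0.0)
    w = (np.pi + np.arccos(ratio)) / 3.0
    p1t = np.where(s > 0, 2.0 * s * np.cos(w) - b / (3.0 * a), p1h)
    p2t = np.clip(p1t - delta, 0.0, 1.0)
    p1t = np.clip(p1t, 0.0, 1.0)
    return p1t, p2t


def mn_score_stat(
    counts: TwoSampleCounts, delta, x1=None, x2=None
) -> np.ndarray:
    """MN score statistic z(delta), vectorized over delta (and outcomes).

    ``x1``/``x2`` override the observed counts (used by the exact
    enumeration to evaluate the statistic over the whole outcome space).
    """
    n1, n2 = counts.n1, counts.n2
    p1h = np.asarray(counts.x1 if x1 is None else x1, dtype=float) / n1
    p2h = np.asarray(counts.x2 if x2 is None else x2, dtype=float) / n2
    delta = np.asarray(delta, dtype=float)
    p1t, p2t = _restricted_mle(p1h, p2h, n1, n2, delta)
    N = n1 + n2
    var = (p1t * (1 - p1t) / n1 + p2t * (1 - p2t) / n2) * (N / (N - 1.0))
    return (p1h - p2h - delta) / np.sqrt(np.maximum(var, 1e-300))


def mn_score_ci(
    counts: TwoSampleCounts, alpha: float = 0.05, tol: float = 1e-8
) -> tuple[float, float]:
    """Miettinen-Nurminen score interval for p1 - p2.

    Bounds are the delta values where the restricted-MLE score statistic,
    variance inflated by N/(N-1), crosses +-z_{1-alpha/2}; found by
    bracketed root search.  Defined for all valid counts including x = 0
    and x = n.
    """
    zc = norm.ppf(1 - alpha / 2)
    diff = counts.diff
    eps = 1e-11

    def f_low(d: float) -> float:
        return float(mn_score_stat(counts, d)) - zc

    def f_high(d: float) -> float:
        return float(mn_score_stat(counts, d)) + zc

    if diff <= -1 + eps:
        low = -1.0
    else:
        low = brentq(f_low, -1 + eps, diff, xtol=tol)
    if diff >= 1 - eps:
        high = 1.0
    else:
        high = brentq(f_high, diff, 1 - eps, xtol=tol)
    return low, high


def _exact_tail_sup(
    counts: TwoSampleCounts, delta: float, grid_points: int
) -> tuple[float, float]:
    """Supremum over the nuisance p2 of the exact one-sided tail probs.

    Returns (p_lower, p_upper): the sup over p2 of P(T <= t_obs) and
    P(T >= t_obs), where T is the MN score statistic at ``delta`` evaluated
    on the full Bin(n1, p2+delta) x Bin(n2, p2) outcome space.
    """
    n1, n2 = counts.n1, counts.n2
    xx1 = np.arange(n1 + 1)[:, None]
    xx2 = np.arange(n2 + 1)[None, :]
    T = mn_score_stat(counts, delta, x1=xx1, x2=xx2)
    t_obs = float(mn_score_stat(counts, delta))
    tol = 1e-9
    upper_mask = T >= t_obs - tol
    lower_mask = T <= t_obs + tol

    lo = max(0.0, -delta)
    hi = min(1.0, 1.0 - delta)
    # open-interval grid: the boundary is degenerate (all mass on one outcome)
    p2_grid = lo + (np.arange(1, grid_points + 1) - 0.5) / grid_points * (hi - lo)

    p_upper = 0.0
    p_lower = 0.0
    for p2 in p2_grid:
        pmf1 = binom.pmf(np.arange(n1 + 1), n1, p2 + delta)
        pmf2 = binom.pmf(np.arange(n2 + 1), n2, p2)
        p_upper = max(p_upper, float(pmf1 @ upper_mask @ pmf2))
        p_lower = max(p_lower, float(pmf1 @ lower_mask @ pmf2))
    return p_lower, p_upper


def exact_unconditional_pvalues(
    counts: TwoSampleCounts, delta: float, grid_points: int = 200
) -> tuple[float, float]:
    """One-sided exact unconditional p-values at the hypothesized delta.

    The interval of :func:`chan_zhang_ci` is the set of delta for which both
    values exceed alpha/2.
    """
    if counts.n1 > _EXACT_N_MAX or counts.n2 > _EXACT_N_MAX:
        raise ResourceError(
            f"exact enumeration supports n <= {_EXACT_N_MAX} per group; "
            "use the Miettinen-Nurminen interval instead"
        )
    return _exact_tail_sup(counts, delta, grid_points)


def chan_zhang_ci(
    counts: TwoSampleCounts,
    alpha: float = 0.05,
    grid_points: int = 200,
    refine_tol: float = 1e-4,
) -> tuple[float, float]:
    """Chan-Zhang exact unconditional interval for p1 - p2.

    Test inversion: a candidate delta is retained when neither one-sided
    supremum p-value (over a uniform nuisance grid of ``grid_points``
    values, extremity ordered by the MN score statistic) falls to alpha/2
    or below.  Bound location uses a coarse scan refined by bisection.
    """
    if counts.n1 > _EXACT_N_MAX or counts.n2 > _EXACT_N_MAX:
        raise ResourceError(
            f"exact enumeration supports n <= {_EXACT_N_MAX} per group; "
            "use the Miettinen-Nurminen interval instead"
        )
    a2 = alpha / 2.0

    def accepted(delta: float) -> bool:
        p_lo, p_up = _exact_tail_sup(counts, delta, grid_points)
        return p_lo > a2 and p_up > a2

    diff = counts.diff
    eps = 1e-9
    step = 0.01

    def _edge(inside: float, outside: float) -> float:
        """Bisect between an accepted and a rejected delta."""
        while abs(outside - inside) > refine_tol:
            mid = 0.5 * (inside + outside)
            if accepted(mid):
                inside = mid
            else:
                outside = mid
        return inside

    # walk outward from the observed difference until rejection
    low_in, low_out = diff, None
    d = diff
    while d > -1.0:
        d = max(d - step, -1.0 + eps)
        if accepted(d):
            low_in = d
            if d <= -1.0 + eps:
                break
        else:
            low_out = d
            break
    low = -1.0 if low_out is None else _edge(low_in, low_out)

    high_in, high_out = diff, None
    d = diff
    while d < 1.0:
        d = min(d + step, 1.0 - eps)
        if accepted(d):
            high_in = d
            if d >= 1.0 - eps:
                break
        else:
            high_out = d
            break
    high = 1.0 if high_out is None else _edge(high_in, high_out)
    return low, high


def mcnemar_two_group(
    control: PairedChangeCounts, alert: PairedChangeCounts
) -> tuple[float, float]:
    """Two-group McNemar contrast of net threshold-status change.

    Per group, with b = observations that were threshold at pretest but not
    at first check-in and c = the reverse, the net-change proportion is
    d = (b - c)/N with variance v = (b + c - (b - c)^2/N)/N^2.  The statistic
    z = (d_alert - d_control)/sqrt(v_control + v_alert) is positive when the
    ALERT arm shifts more strongly toward fewer threshold reports at first
    check-in; two-sided p from the standard normal.  A group with no paired
    observations contributes d = 0, v = 0 (one-sample reduction).
    """
    if control.n_pre_only + control.n_post_only + alert.n_pre_only + alert.n_post_only == 0:
        raise DataError("no discordant paired observations in either group")

    def _dv(t: PairedChangeCounts) -> tuple[float, float]:
        if t.n_total == 0:
            return 0.0, 0.0
        b, c, N = t.n_pre_only, t.n_post_only, t.n_total
        d = (b - c) / N
        v = (b + c - (b - c) ** 2 / N) / N**2
        return d, v

    d1, v1 = _dv(control)
    d2, v2 = _dv(alert)
    if v1 + v2 <= 0:
        raise DataError("zero variance: no discordant observations")
    z = (d2 - d1) / math.sqrt(v1 + v2)
    return z, 2.0 * norm.sf(abs(z))


def compare(
    counts: TwoSampleCounts,
    methods: Sequence[str] = ("wald", "mn"),
    alpha: float = 0.05,
) -> ComparisonResult:
    """Bundle the requested statistics into one record.

    ``methods`` selects confidence intervals from {"wald", "mn", "cz"};
    the pooled Z test is skipped (None) when the pooled proportion is
    degenerate (0 or 1).
    """
    try:
        z, p = pooled_z_test(counts)
    except DataError:
        z, p = None, None
    cis = {}
    for m in methods:
        if m == "wald":
            cis[m] = wald_unpooled_ci(counts, alpha)
        elif m == "mn":
            cis[m] = mn_score_ci(counts, alpha)
        elif m == "cz":
            cis[m] = chan_zhang_ci(counts, alpha)
        else:
            raise DataError(f"unknown CI method {m!r}")
    return ComparisonResult(
        counts=counts,
        p1=counts.p1,
        p2=counts.p2,
        diff=counts.diff,
        z=z,
        p_value=p,
        h=cohen_h(counts),
        alpha=alpha,
        cis=cis,
    )
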