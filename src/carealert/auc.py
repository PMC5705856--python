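"""Trapezoidal AUC contrast of bimonthly proportion trajectories.

The longitudinal comparison of the two arms summarizes each arm's
bimonthly proportion index (threshold/assessed or improved/threshold) by
the trapezoidal area under the trajectory, converts the two areas into
relative proportions (r1 + r2 = 1), and runs the same two-sample proportion
machinery on (round(r_i * n_i), n_i), where n_i is the arm's total relevant
denominator over the 12 months.  The effective n is an approximation: the
source analyses do not define one, and the totals-based denominator matches
the denominators used by the totals-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .inference import ComparisonResult, TwoSampleCounts, compare

#: Bin-center abscissae (months) of the six 2-month periods.
DEFAULT_MIDPOINTS = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0)


@dataclass(frozen=True)
class TrajectorySeries:
    """One arm's proportion trajectory over the bimonthly periods."""

    arm: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    weights: Optional[tuple[int, ...]] = None  # per-period denominators

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise DataError("times and values must have equal length")
        if len(self.times) < 2:
            raise DataError("need at least two points for an AUC")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise DataError("period midpoints must be strictly increasing")


@dataclass(frozen=True)
class AucComparison:
    """AUC contrast between two arms."""

    arm1: str
    arm2: str
    auc1: float
    auc2: float
    relative1: float
    relative2: float
    effective_n1: int
    effective_n2: int
    result: ComparisonResult


def trapezoid_auc(series: TrajectorySeries) -> float:
    """Trapezoidal rule: sum of (t_{k+1}-t_k)(y_k + y_{k+1})/2."""
    return float(np.trapezoid(series.values, series.times))


def relative_auc(auc1: float, auc2: float) -> tuple[float, float]:
    """Normalize two areas to proportions summing to one."""
    total = auc1 + auc2
    if total <= 0:
        raise DataError("both AUCs are zero: relative proportions undefined")
    return auc1 / total, auc2 / total


def auc_difference_test(
    series1: TrajectorySeries,
    series2: TrajectorySeries,
    effective_n1: int,
    effective_n2: int,
    alpha: float = 0.05,
    methods: Sequence[str] = ("mn",),
) -> AucComparison:
    """Proportional difference test on the relative AUCs.

    Delegates to the two-sample machinery with counts
    (round(r_i * effective_n_i), effective_n_i).
    """
    if effective_n1 < 1 or effective_n2 < 1:
        raise DataError("effective n must be >= 1 per arm")
    a1, a2 = trapezoid_auc(series1), trapezoid_auc(series2)
    r1, r2 = relative_auc(a1, a2)
    counts = TwoSampleCounts(
        x1=int(round(r1 * effective_n1)),
        n1=effective_n1,
        x2=int(round(r2 * effective_n2)),
        n2=effective_n2,
        label1=series1.arm,
        label2=series2.arm,
    )
    return AucComparison(
        arm1=series1.arm,
        arm2=series2.arm,
        auc1=a1,
        auc2=a2,
        relative1=r1,
        relative2=r2,
        effective_n1=effective_n1,
        effective_n2=effective_n2,
        result=compare(counts, methods=methods, alpha=alpha),
    )


def series_from_indices(
    indices: pd.DataFrame,
    arm: str,
    index: str = "improvement",
    midpoints: Sequence[float] = DEFAULT_MIDPOINTS,
) -> TrajectorySeries:
    """Build an arm's trajectory from a bimonthly index table.

    ``index`` selects the proportion: "improvement" (improved/threshold) or
    "threshold" (threshold/assessed).  Periods with a zero denominator
    contribute no point.
    """
    if index == "improvement":
        num, den = "n_improved", "n_threshold"
    elif index == "threshold":
        num, den = "n_threshold", "n_assessed"
    else:
        raise DataError("index must be 'improvement' or 'threshold'")
    sub = indices[(indices["arm"] == arm) & (indices["period"] != "ALL")]
    times, values, weights = [], [], []
    for _, row in sub.sort_values("period").iterrows():
        d = int(row[den])
        if d == 0:
            continue
        times.append(float(midpoints[int(row["period"]) - 1]))
        values.append(int(row[num]) / d)
        weights.append(d)
    return TrajectorySeries(
        arm=arm, times=tuple(times), values=tuple(values), weights=tuple(weights)
    )
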