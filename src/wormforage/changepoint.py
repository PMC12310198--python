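"""Two-segment regression changepoint analysis of cumulative event curves.

A worm that "decides" to switch from local to global search shows a sharp
kink in its cumulative reorientation curve Ω(t).  Following the standard
two-line residual-minimization procedure, each curve is split at every
admissible grid index, an independent ordinary least-squares line is fit
to each side, and the split minimizing the total residual sum of squares
wins.  The slope difference ``s1 - s2`` measures how abrupt the apparent
rate change is and the transition time is the intersection of the two
fitted lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rate_analysis import _event_times, _time_grid

#: relative tolerance below which two segment slopes count as equal
#: (degenerate changepoint: the fitted lines have no meaningful intersection)
_SLOPE_TOL = 1e-9


@dataclass
class CumulativeCurve:
    """Cumulative event count Ω on a uniform time grid.

    ``omega`` is non-decreasing; integer counts for real event streams,
    float for analytic fixtures.
    """

    time_grid: np.ndarray
    omega: np.ndarray


@dataclass
class ChangepointResult:
    """Best two-segment OLS fit of one cumulative curve.

    ``t_trans`` is the intersection time of the two fitted lines; when the
    slopes are (numerically) equal the intersection is undefined, the
    split's grid time is reported instead and ``degenerate`` is set.
    """

    s1: float
    s2: float
    slope_diff: float
    t_trans: float
    split_index: int
    rss_total: float
    b1: float
    b2: float
    degenerate: bool
    worm_id: int | None = None


def cumulative_curve(traj, grid_step: float, total_duration: float) -> CumulativeCurve:
    """Ω(t) = number of events at or before t, on a uniform grid from 0 to T."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    ev = np.sort(_event_times(traj))
    grid = _time_grid(total_duration, grid_step)
    omega = np.searchsorted(ev, grid, side="right").astype(float)
    return CumulativeCurve(time_grid=grid, omega=omega)


def _prefix_ols(x: np.ndarray, y: np.ndarray):
    """Per-split OLS summaries for every prefix and suffix of (x, y).

    Returns, for each admissible split k (left = points [0, k), right =
    points [k, n)), the slope, intercept and residual sum of squares of
    both independent regressions, computed from prefix sums in O(n).
    """
    n = len(x)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg(lo_sum, hi_sum, m):
        sx = hi_sum[0] - lo_sum[0]
        sy = hi_sum[1] - lo_sum[1]
        sxx = hi_sum[2] - lo_sum[2]
        sxy = hi_sum[3] - lo_sum[3]
        syy = hi_sum[4] - lo_sum[4]
        sxx_c = sxx - sx * sx / m
        sxy_c = sxy - sx * sy / m
        syy_c = syy - sy * sy / m
        slope = sxy_c / sxx_c
        intercept = (sy - slope * sx) / m
        rss = np.maximum(syy_c - sxy_c * sxy_c / sxx_c, 0.0)
        return slope, intercept, rss

    return n, (cx, cy, cxx, cxy, cyy), seg


def two_segment_fit(curve: CumulativeCurve, min_seg: float = 2.0) -> ChangepointResult:
    """Best split of a cumulative curve into two independent OLS lines.

    Exhaustive search over all splits leaving at least ``min_seg`` minutes
    of grid on each side (never fewer than 2 points).  Ties in total RSS go
    to the smallest split index.  The two lines are fit without a
    continuity constraint, so their intersection defines the transition
    time ``t_trans = (b2 - b1) / (s1 - s2)``.
    """
    x = np.asarray(curve.time_grid, dtype=float)
    y = np.asarray(curve.omega, dtype=float)
    n = len(x)
    step = x[1] - x[0]
    min_pts = max(2, int(round(min_seg / step)))
    if n < 2 * min_pts:
        raise ValueError(f"curve too short: {n} points, need >= {2 * min_pts}")

    _, sums, seg = _prefix_ols(x, y)
    cx, cy, cxx, cxy, cyy = sums
    ks = np.arange(min_pts, n - min_pts + 1)

    zero = (np.zeros(1),) * 5
    left_lo = tuple(np.zeros_like(ks, dtype=float) for _ in range(5))
    left_hi = (cx[ks], cy[ks], cxx[ks], cxy[ks], cyy[ks])
    s1, b1, rss1 = seg(left_lo, left_hi, ks.astype(float))
    right_lo = left_hi
    right_hi = tuple(np.full_like(ks, c[-1], dtype=float) for c in (cx, cy, cxx, cxy, cyy))
    s2, b2, rss2 = seg(right_lo, right_hi, (n - ks).astype(float))

    total = rss1 + rss2
    best = int(np.argmin(total))  # argmin returns the first minimum on ties
    k = int(ks[best])
    s1b, s2b = float(s1[best]), float(s2[best])
    b1b, b2b = float(b1[best]), float(b2[best])
    scale = max(1.0, abs(s1b), abs(s2b))
    degenerate = abs(s1b - s2b) <= _SLOPE_TOL * scale
    if degenerate:
        t_trans = float(x[k])
    else:
        t_trans = (b2b - b1b) / (s1b - s2b)
    return ChangepointResult(
        s1=s1b, s2=s2b, slope_diff=s1b - s2b, t_trans=float(t_trans),
        split_index=k, rss_total=float(total[best]), b1=b1b, b2=b2b,
        degenerate=bool(degenerate),
    )


def population_changepoints(trajs: Sequence, grid_step: float = 0.5,
                            min_seg: float = 2.0,
                            total_duration: float = 45.0,
                            ) -> list[ChangepointResult]:
    """Per-worm two-segment fits, in input order.

    Worms with degenerate fits (equal slopes, e.g. no events at all) are
    retained and flagged rather than dropped, so population distributions
    keep their full denominator.
    """
    out = []
    for i, traj in enumerate(trajs):
        curve = cumulative_curve(traj, grid_step, total_duration)
        res = two_segment_fit(curve, min_seg=min_seg)
        res.worm_id = getattr(traj, "worm_id", i)
        out.append(res)
    return out
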