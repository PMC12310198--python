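"""Rolling-window rate curves and exponential-decay fitting.

The observable in the foraging assay is the reorientation rate measured in
a rolling window (2 min by default).  The population-mean rate decays as
``alpha * exp(-gamma * t) + beta``; fitting that three-parameter curve to
the mean rolling rate is how the kinetic constants of the simulator are
estimated from data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .simulator import Trajectory


@dataclass
class RateCurve:
    """Reorientation rate sampled on a time grid.

    ``rates`` is the (population mean) rate in events/min at each grid
    time; ``sd`` is the across-worm standard deviation (None for a single
    worm); ``n_worms`` is the number of contributing worms.
    """

    time_grid: np.ndarray
    rates: np.ndarray
    n_worms: int = 1
    sd: np.ndarray | None = None


@dataclass
class DecayFit:
    """Bounded nonlinear least-squares fit of ``alpha*exp(-gamma*t) + beta``."""

    alpha_hat: float
    beta_hat: float
    gamma_hat: float
    rss: float
    converged: bool


def _event_times(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.event_times
    return np.asarray(traj, dtype=float)


def _time_grid(total_duration: float, grid_step: float) -> np.ndarray:
    n = int(math.floor(total_duration / grid_step + 1e-9))
    grid = np.arange(n + 1) * grid_step
    if grid[-1] < total_duration - 1e-9:
        grid = np.append(grid, total_duration)
    return grid


def rolling_rate(traj, window: float, grid_step: float,
                 total_duration: float) -> RateCurve:
    """Rate in a centered rolling window, truncated at the boundaries.

    At each grid time t the window is ``[max(0, t - w/2), min(T, t + w/2))``
    and the rate is the event count in that half-open interval divided by
    its actual length, so boundary windows are renormalized rather than
    biased low.  An empty trajectory yields an all-zero curve.
    """
    if window <= 0 or grid_step <= 0:
        raise ValueError("window and grid_step must be positive")
    ev = np.sort(_event_times(traj))
    grid = _time_grid(total_duration, grid_step)
    lo = np.maximum(0.0, grid - window / 2.0)
    hi = np.minimum(total_duration, grid + window / 2.0)
    counts = np.searchsorted(ev, hi, side="left") - np.searchsorted(ev, lo, side="left")
    rates = counts / (hi - lo)
    return RateCurve(time_grid=grid, rates=rates, n_worms=1, sd=None)


def population_rate(trajs: Sequence, window: float, grid_step: float,
                    total_duration: float) -> RateCurve:
    """Pointwise mean and SD of per-worm rolling rates on a shared grid."""
    if len(trajs) == 0:
        raise ValueError("need at least one trajectory")
    curves = [rolling_rate(t, window, grid_step, total_duration).rates for t in trajs]
    # mean/SD are symmetric in the worms; sorting each column makes the
    # floating-point reduction independent of worm ordering
    stack = np.sort(np.vstack(curves), axis=0)
    grid = _time_grid(total_duration, grid_step)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(trajs) > 1 else None
    return RateCurve(time_grid=grid, rates=mean, n_worms=len(trajs), sd=sd)


def fit_decay(curve: RateCurve) -> DecayFit:
    """Fit ``alpha*exp(-gamma*t) + beta`` to a rate curve by least squares.

    Ordinary (unweighted) least squares with all three parameters bounded
    below by zero.  The starting point is scale-free and deterministic:
    ``alpha0 = max(rate) - min(rate)``, ``beta0 = min(rate)``,
    ``gamma0 = 3 / T``.  On solver failure the best iterate is still
    returned with ``converged=False``.
    """
    t = np.asarray(curve.time_grid, dtype=float)
    y = np.asarray(curve.rates, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 grid points to fit 3 parameters")
    span = t[-1] - t[0]

    def resid(p):
        a, b, g = p
        return a * np.exp(-g * t) + b - y

    p0 = [max(y.max() - y.min(), 1e-12), y.min(), 3.0 / span]
    res = least_squares(resid, p0, bounds=([0.0, 0.0, 0.0], [np.inf] * 3),
                        ftol=1e-14, xtol=1e-14, gtol=1e-14)
    a, b, g = res.x
    return DecayFit(alpha_hat=float(a), beta_hat=float(b), gamma_hat=float(g),
                    rss=float(np.sum(res.fun ** 2)), converged=bool(res.success))


def half_life(gamma: float) -> float:
    """Half-life ``ln 2 / gamma`` of the decaying factor, in minutes.

    Interpretable as the memory timescale of the last food encounter.
    """
    if gamma <= 0:
        raise ValueError("half_life requires gamma > 0")
    return math.log(2.0) / gamma
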