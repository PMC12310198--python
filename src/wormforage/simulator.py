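"""Exact stochastic simulation of foraging reorientation events.

When *C. elegans* is removed from food, its rate of sharp reorientations
(pirouettes/omega turns) decays from roughly 1.5 events/min toward a low
baseline.  This module models each worm as a two-event Gillespie system:

* event 1 — a reorientation, which increments the cumulative count Ω; its
  propensity is coupled linearly to a decaying signalling factor M,
  ``a1 = (alpha / M0) * M + beta``;
* event 2 — first-order decay of the factor, ``M -> M - 1``, with
  propensity ``a2 = gamma * M``.

Because M decays first order, the ensemble mean of ``a1`` follows
``alpha * exp(-gamma * t) + beta``: the population rate decays smoothly
while individual trajectories remain genuinely stochastic, which is the
point of the model — apparently abrupt "local-to-global" switches can arise
from sampling noise alone.  A ``constant`` mode (``a1 = alpha + beta``
fixed, M untouched) provides the time-homogeneous Poisson control.

The simulation is Gillespie's direct method: draw the waiting time from the
total propensity, ``tau = -ln(r1) / a0``, then pick the event with
probability ``a_i / a0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger("wormforage.simulator")

#: events/min — fitted amplitude of the population decay curve.
DEFAULT_ALPHA = 1.49
#: events/min — baseline reorientation rate as t -> infinity.
DEFAULT_BETA = 0.1937
#: 1/min — decay constant of the fitted population rate curve.
DEFAULT_GAMMA = 0.11
#: 1/min — slower literature estimate of the decay constant (~10 min half-life).
GAMMA_SLOW = 0.07
#: initial count of the decaying factor; large so that M decays quasi-continuously.
DEFAULT_M0 = 1000
#: min — length of the off-food recording window.
DEFAULT_DURATION = 45.0

_RNG_BLOCK = 4096  # uniforms drawn per batch in the event loop


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Kinetic constants and run settings for one simulated population.

    Parameters
    ----------
    alpha
        Rate amplitude (events/min): initial excess rate above baseline.
    beta
        Baseline rate (events/min): rate once the factor M is exhausted.
    gamma
        First-order decay constant of M (1/min).
    M0
        Initial count of the decaying factor (dimensionless integer >= 0).
    duration
        Total simulated time per worm (min).
    n_worms
        Population size.
    seed
        Master RNG seed; per-worm streams are spawned from it.
    mode
        ``"decaying"`` for the coupled two-event system, ``"constant"``
        for a time-homogeneous control with rate ``alpha + beta``.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    M0: int = DEFAULT_M0
    duration: float = DEFAULT_DURATION
    n_worms: int = 1
    seed: int = 0
    mode: str = "decaying"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ConfigurationError("rate constants must be non-negative")
        if self.M0 < 0 or int(self.M0) != self.M0:
            raise ConfigurationError("M0 must be a non-negative integer")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.n_worms < 1:
            raise ConfigurationError("n_worms must be >= 1")
        if self.mode not in ("decaying", "constant"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


class PropensityState(NamedTuple):
    """Event propensities (probability per unit time) at a given M."""

    a1: float  # reorientation propensity, events/min
    a2: float  # decay propensity, events/min
    a0: float  # total propensity = a1 + a2


@dataclass
class Trajectory:
    """One worm's simulated event stream.

    ``event_times`` are the reorientation times (min, strictly increasing).
    ``m_path`` is the piecewise-constant path of the factor M as an
    ``(k, 2)`` array of ``(time, M)`` rows, starting at ``(0, initial_M)``;
    M drops by exactly 1 at each decay event and never goes below 0.
    """

    worm_id: int
    event_times: np.ndarray
    m_path: np.ndarray
    initial_M: int

    @property
    def n_events(self) -> int:
        return len(self.event_times)


# ---------------------------------------------------------------------------
# Elementary Gillespie steps (exposed for testing; the worm loop inlines them)
# ---------------------------------------------------------------------------

def compute_propensities(M: int, params: SimulationParams) -> PropensityState:
    """Propensities of the two events given the current factor count M.

    In decaying mode ``a1 = alpha*M/M0 + beta`` and ``a2 = gamma*M``;
    in constant mode ``a1 = alpha + beta`` and ``a2 = 0`` regardless of M.
    """
    if params.mode == "constant":
        a1 = params.alpha + params.beta
        return PropensityState(a1, 0.0, a1)
    if params.M0 == 0:
        if M > 0:
            raise ConfigurationError("M > 0 with M0 = 0 in decaying mode")
        a1 = params.beta
    elif not 0 <= M <= params.M0:
        raise ValueError(f"M={M} outside [0, {params.M0}]")
    else:
        a1 = params.alpha * M / params.M0 + params.beta
    a2 = params.gamma * M
    return PropensityState(a1, a2, a1 + a2)


def draw_interval(a0: float, r1: float) -> float:
    """Waiting time to the next event: ``tau = -ln(r1) / a0``.

    ``r1`` must lie in (0, 1]; callers resample on r1 == 0 so that tau
    stays finite.  ``a0 <= 0`` means no event can ever fire.
    """
    if a0 <= 0:
        raise ValueError("a0 <= 0: no event possible; caller must terminate")
    if not 0 < r1 <= 1:
        raise ValueError("r1 must be in (0, 1]")
    return -math.log(r1) / a0


def select_event(props: PropensityState, r2: float) -> int:
    """Pick the firing event: smallest i with ``r2*a0 <= sum(a_1..a_i)``.

    Returns 1 (reorientation) or 2 (decay of M); over the ensemble of r2,
    event i fires with probability ``a_i / a0``.
    """
    if props.a0 <= 0:
        raise ValueError("a0 <= 0: no event to select")
    return 1 if r2 * props.a0 <= props.a1 else 2


def assign_initial_M(r: float, params: SimulationParams) -> int:
    """Initial factor count giving worm j a starting rate of r events/min.

    Inverts ``a1 = alpha*M/M0 + beta`` at t=0: ``M_j = M0*(r - beta)/alpha``,
    rounded half-up to the nearest integer and clamped to [0, M0].  A draw
    below the baseline beta clamps to 0 (the worm starts at baseline rate).
    """
    if params.alpha <= 0:
        raise ConfigurationError("assign_initial_M requires alpha > 0")
    raw = params.M0 * (r - params.beta) / params.alpha
    if r < params.beta:
        logger.debug("initial rate %.4g below baseline %.4g; M_j clamped to 0",
                     r, params.beta)
    m_j = math.floor(raw + 0.5)  # round half up
    return int(min(max(m_j, 0), params.M0))


# ---------------------------------------------------------------------------
# Worm and population simulation
# ---------------------------------------------------------------------------

def simulate_worm(params: SimulationParams, initial_M: int,
                  rng: np.random.Generator, worm_id: int = 0) -> Trajectory:
    """Run the Gillespie direct method for one worm until ``duration``.

    The loop repeats {draw waiting time; select event; apply; advance t}
    and stops when the next event would land past the end of the recording
    (that event is discarded).  When the total propensity hits zero
    (M exhausted with beta == 0) no further event is possible and the worm
    simply coasts to the end of the recording.
    """
    if params.mode == "decaying" and not 0 <= initial_M <= params.M0:
        raise ValueError(f"initial_M={initial_M} outside [0, {params.M0}]")
    T = params.duration
    constant = params.mode == "constant"
    alpha, beta, gamma, M0 = params.alpha, params.beta, params.gamma, params.M0

    M = int(initial_M)
    t = 0.0
    events: list[float] = []
    m_times = [0.0]
    m_vals = [M]

    # uniforms are consumed strictly in draw order (r1 then r2 per step),
    # batched for speed; the stream is identical to scalar draws.
    buf = rng.random(_RNG_BLOCK)
    bi = 0
    while True:
        if constant:
            a1 = alpha + beta
            a0 = a1
        else:
            a1 = (alpha * M / M0 + beta) if M0 > 0 else beta
            a0 = a1 + gamma * M
        if a0 <= 0.0:
            break  # absorbing: jump to duration, nothing more can fire
        if bi >= _RNG_BLOCK - 1:
            buf = rng.random(_RNG_BLOCK)
            bi = 0
        r1 = buf[bi]
        bi += 1
        while r1 == 0.0:  # measure-zero guard: -ln(0) is infinite
            r1 = rng.random()
        t += -math.log(r1) / a0
        if t > T:
            break
        r2 = buf[bi]
        bi += 1
        if r2 * a0 <= a1:
            events.append(t)
        else:
            M -= 1
            m_times.append(t)
            m_vals.append(M)

    return Trajectory(
        worm_id=worm_id,
        event_times=np.asarray(events, dtype=float),
        m_path=np.column_stack([np.asarray(m_times), np.asarray(m_vals, dtype=float)]),
        initial_M=int(initial_M),
    )


def simulate_population(params: SimulationParams,
                        initial_rates: Sequence[float] | None = None,
                        ) -> list[Trajectory]:
    """Simulate ``n_worms`` independent worms.

    Each worm gets an independent RNG stream spawned from the master seed,
    keyed by its index, so per-worm trajectories are reproducible and do not
    reshuffle when ``n_worms`` changes.  ``initial_rates`` (one draw per
    worm, events/min) sets heterogeneous starting factor counts through
    :func:`assign_initial_M`; by default every worm starts at ``M0``.
    """
    n = params.n_worms
    if initial_rates is None:
        initial_ms = [params.M0] * n
    else:
        if len(initial_rates) != n:
            raise ValueError("need exactly one initial rate per worm")
        initial_ms = [assign_initial_M(r, params) for r in initial_rates]

    children = np.random.SeedSequence(params.seed).spawn(n)
    return [
        simulate_worm(params, initial_ms[i],
                      np.random.Generator(np.random.PCG64(children[i])),
                      worm_id=i)
        for i in range(n)
    ]


def expected_cumulative(t: np.ndarray | float, params: SimulationParams) -> np.ndarray | float:
    """Closed-form ensemble mean of Ω(t) for worms initialized at M0.

    Integral of the mean rate ``alpha*exp(-gamma*s) + beta`` from 0 to t:
    ``(alpha/gamma)*(1 - exp(-gamma*t)) + beta*t`` (limit ``alpha*t + beta*t``
    as gamma -> 0).
    """
    t = np.asarray(t, dtype=float)
    if params.gamma == 0:
        out = (params.alpha + params.beta) * t
    else:
        out = (params.alpha / params.gamma) * (1.0 - np.exp(-params.gamma * t)) \
            + params.beta * t
    return out if out.ndim else float(out)
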