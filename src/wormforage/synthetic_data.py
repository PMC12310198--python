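"""Surrogate "experimental" data generators.

The curated tracking dataset behind the foraging analysis (per-worm
reorientation times for ~1631 worms recorded for 45 min off food) is not
redistributable, so every analysis stage is exercised against surrogates
that reproduce its statistical structure: heterogeneous initial rates with
a population mean near 1.5 events/min, and an exponentially decaying mean
rate.  Surrogates are generated by the simulator itself with
heterogeneous initial factor counts, which is exactly how the in-silico
population of the study is built.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .changepoint import CumulativeCurve
from .simulator import SimulationParams, Trajectory, simulate_population

#: events/min — population mean initial reorientation rate of the surrogate.
DEFAULT_MEAN_RATE = 1.5
#: gamma-family shape parameter giving SD = mean/2 (0.75 events/min at mean 1.5),
#: echoing the broad spread of observed initial rates.
DEFAULT_DISPERSION = 4.0


@dataclass(frozen=True)
class InitialRateModel:
    """Distribution of per-worm initial reorientation rates (events/min).

    ``family`` is one of:

    * ``"gamma"`` — gamma distribution with mean ``mean_rate`` and shape
      ``dispersion`` (SD = mean/sqrt(dispersion)); the default surrogate.
    * ``"truncated-normal"`` — normal with the same mean/SD convention,
      truncated below at ``floor``.
    * ``"empirical-file"`` — resample with replacement from a provided
      rate CSV (column ``rate0``), mirroring how initial conditions are
      drawn from observed rates when real data are available.

    ``dispersion = inf`` degenerates to a point mass at ``mean_rate``.
    """

    mean_rate: float = DEFAULT_MEAN_RATE
    dispersion: float = DEFAULT_DISPERSION
    floor: float = 0.0
    family: str = "gamma"
    empirical_path: str | None = None

    def __post_init__(self) -> None:
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.family not in ("gamma", "truncated-normal", "empirical-file"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "empirical-file" and not self.empirical_path:
            raise ValueError("empirical-file family needs empirical_path")


def sample_initial_rates(model: InitialRateModel, n: int,
                         seed: int | np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. initial rates from the model, reproducibly by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.Generator(np.random.PCG64(seed))
    if not np.isfinite(model.dispersion):
        return np.full(n, model.mean_rate)
    if model.family == "gamma":
        shape = model.dispersion
        scale = model.mean_rate / shape
        return rng.gamma(shape, scale, size=n)
    if model.family == "truncated-normal":
        sd = model.mean_rate / np.sqrt(model.dispersion)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(model.mean_rate, sd, size=n - filled)
            keep = draw[draw >= model.floor]
            out[filled:filled + len(keep)] = keep
            filled += len(keep)
        return out
    rates = pd.read_csv(model.empirical_path)["rate0"].to_numpy(dtype=float)
    return rng.choice(rates, size=n, replace=True)


def make_surrogate_experiment(params: SimulationParams,
                              rate_model: InitialRateModel | None = None,
                              out_dir: str | Path | None = None,
                              ) -> tuple[list[Trajectory], np.ndarray]:
    """Simulate a full heterogeneous population standing in for real data.

    Initial rates are drawn from ``rate_model`` (default gamma family)
    using an RNG stream derived from ``params.seed`` but independent of
    the per-worm simulation streams.  If ``out_dir`` is given, writes
    ``events.csv`` (``worm_id,event_time_min``), ``initial_rates.csv``
    and a ``manifest.json`` recording every parameter and the seed.

    Returns the trajectories and the drawn initial rates.
    """
    from . import io as wio  # deferred: io imports nothing from here

    rate_model = rate_model or InitialRateModel()
    rate_rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(0x5EED,))))
    rates = sample_initial_rates(rate_model, params.n_worms, rate_rng)
    trajs = simulate_population(params, initial_rates=rates)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wio.write_events_csv(trajs, out_dir / "events.csv")
        pd.DataFrame({
            "worm_id": [t.worm_id for t in trajs],
            "rate0": np.round(rates, 6),
        }).to_csv(out_dir / "initial_rates.csv", index=False)
        manifest = {
            "generator": "make_surrogate_experiment",
            "params": asdict(params),
            "rate_model": asdict(rate_model),
            "seed": params.seed,
            "synthetic": True,
        }
        wio.write_manifest(out_dir / "manifest.json", manifest)
    return trajs, rates


def make_piecewise_fixture(s1: float, s2: float, t_break: float,
                           duration: float, grid_step: float) -> CumulativeCurve:
    """Noiseless continuous piecewise-linear cumulative curve.

    Slope ``s1`` up to ``t_break``, then ``s2``; a two-segment fit must
    recover (s1, s2, t_break) exactly (up to degeneracy when s1 == s2).
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("slopes must be non-negative")
    if not 0 < t_break < duration:
        raise ValueError("t_break must lie strictly inside (0, duration)")
    n = int(round(duration / grid_step))
    grid = np.arange(n + 1) * grid_step
    omega = np.where(grid <= t_break,
                     s1 * grid,
                     s1 * t_break + s2 * (grid - t_break))
    return CumulativeCurve(time_grid=grid, omega=omega)
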