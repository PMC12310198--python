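"""File formats, config loading, validation and provenance manifests.

Event streams travel as plain CSV with a mandatory header
``worm_id,event_time_min`` and times in decimal minutes (6+ significant
digits, preserving the floating-point time resolution of the simulator).
Changepoint tables, rate curves and divergence reports use the CSV/JSON
layouts documented on each writer.  Every pipeline artifact directory
carries a ``manifest.json`` with the fully-resolved configuration, its
hash, and the package version, so runs are reproducible from the manifest
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .changepoint import ChangepointResult
from .rate_analysis import DecayFit, RateCurve
from .simulator import Trajectory

logger = logging.getLogger("wormforage.io")

EVENT_COLUMNS = ["worm_id", "event_time_min"]


class ValidationError(ValueError):
    """Raised when an input file violates the documented format."""


# ---------------------------------------------------------------------------
# Event streams
# ---------------------------------------------------------------------------

def write_events_csv(trajs: Sequence[Trajectory], path: str | Path) -> None:
    """One row per reorientation: ``worm_id,event_time_min``.

    Worms with zero events still appear in the companion manifest /
    initial-rate files but contribute no rows here.
    """
    rows = []
    for t in trajs:
        for ev in t.event_times:
            rows.append((t.worm_id, ev))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df["event_time_min"] = df["event_time_min"].map(lambda v: f"{v:.8g}")
    df.to_csv(path, index=False)


def write_m_path_csv(trajs: Sequence[Trajectory], path: str | Path) -> None:
    """Piecewise-constant factor paths: ``worm_id,time_min,M``."""
    rows = []
    for t in trajs:
        for time, m in t.m_path:
            rows.append((t.worm_id, f"{time:.8g}", int(m)))
    pd.DataFrame(rows, columns=["worm_id", "time_min", "M"]).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate an event CSV.

    Checks the exact header, numeric times, and per-worm strictly
    increasing event order; violations raise :class:`ValidationError`
    naming the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    if list(df.columns) != EVENT_COLUMNS:
        raise ValidationError(
            f"{path}: expected header {','.join(EVENT_COLUMNS)!r}, "
            f"got {','.join(map(str, df.columns))!r}")
    times = pd.to_numeric(df["event_time_min"], errors="coerce")
    bad = times.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"{path}: non-numeric event_time_min at row {row}")
    df["event_time_min"] = times
    for worm, grp in df.groupby("worm_id", sort=False):
        t = grp["event_time_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0])
            row = int(grp.index[i + 1]) + 1
            raise ValidationError(
                f"{path}: non-increasing event times for worm {worm!r} at row {row}")
    return df


def events_by_worm(df: pd.DataFrame) -> list[tuple[Any, np.ndarray]]:
    """Split an event table into (worm_id, event_times) pairs, input order."""
    return [(worm, grp["event_time_min"].to_numpy(dtype=float))
            for worm, grp in df.groupby("worm_id", sort=False)]


# ---------------------------------------------------------------------------
# Analysis artifacts
# ---------------------------------------------------------------------------

def write_rate_curve_csv(curve: RateCurve, path: str | Path) -> None:
    """``time_min,mean_rate,sd_rate,n`` — SD blank for single-worm curves."""
    sd = curve.sd if curve.sd is not None else np.full_like(curve.rates, np.nan)
    pd.DataFrame({
        "time_min": curve.time_grid,
        "mean_rate": curve.rates,
        "sd_rate": sd,
        "n": curve.n_worms,
    }).to_csv(path, index=False)


def write_fit_json(fit: DecayFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "alpha": fit.alpha_hat, "beta": fit.beta_hat, "gamma": fit.gamma_hat,
        "rss": fit.rss, "converged": fit.converged,
    }, indent=2) + "\n")


CHANGEPOINT_COLUMNS = ["worm_id", "s1", "s2", "slope_diff", "t_trans",
                       "rss_total", "degenerate"]


def write_changepoints_csv(results: Sequence[ChangepointResult],
                           path: str | Path) -> None:
    pd.DataFrame([{
        "worm_id": r.worm_id, "s1": r.s1, "s2": r.s2,
        "slope_diff": r.slope_diff, "t_trans": r.t_trans,
        "rss_total": r.rss_total, "degenerate": r.degenerate,
    } for r in results]).to_csv(path, index=False)


def read_changepoints_csv(path: str | Path) -> list[ChangepointResult]:
    df = pd.read_csv(path)
    missing = [c for c in CHANGEPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [ChangepointResult(
        s1=row.s1, s2=row.s2, slope_diff=row.slope_diff, t_trans=row.t_trans,
        split_index=-1, rss_total=row.rss_total, b1=float("nan"),
        b2=float("nan"), degenerate=bool(row.degenerate), worm_id=row.worm_id,
    ) for row in df.itertuples()]


# ---------------------------------------------------------------------------
# Config and manifests
# ---------------------------------------------------------------------------

def load_config(path: str | Path, allowed_keys: Iterable[str] | None = None,
                ) -> dict[str, Any]:
    """Load a flat YAML/JSON key-value config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict[str, Any]) -> None:
    """Provenance sidecar: resolved config, its hash, package version."""
    payload = dict(config)
    payload["config_hash"] = config_hash(config)
    payload["version"] = __version__
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
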