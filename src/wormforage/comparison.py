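"""Distribution comparison: Jensen-Shannon divergence and the M0 sweep.

The question the model-comparison stage answers is whether a candidate
model's joint distribution of (slope difference, transition time) is as
close to a reference distribution as sampling noise allows.  Distributions
are binned on shared 2-D edges, compared with the Jensen-Shannon
divergence (natural log, so JSD ≤ ln 2), and the sensitivity of the model
to the granularity of the decaying factor is probed by sweeping the
initial count M0 over decades (1000, 100, 10, 1) with replicate
populations, followed by Tukey's range test on the replicate JSD groups.
The binary model (M0 = 1) is a genuine two-state system — its rate is
either ``alpha + beta`` or ``beta`` — and is expected to stand apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .changepoint import ChangepointResult, CumulativeCurve, population_changepoints
from .simulator import SimulationParams, simulate_population

logger = logging.getLogger("wormforage.comparison")


@dataclass
class BinnedDistribution:
    """Joint 2-D histogram over (slope difference, transition time).

    ``probs`` sums to 1; any pairwise comparison requires identical edges.
    """

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    probs: np.ndarray


@dataclass
class DivergenceReport:
    """Replicate JSD values per model variant plus the Tukey comparison.

    ``jsd_matrix`` has shape (n_replicates, len(m0_values)), in nats.
    ``tukey_table`` lists every group pair with mean difference and the
    Tukey-adjusted p-value; ``anova_p`` is the one-way ANOVA p-value.
    """

    m0_values: list[int]
    jsd_matrix: np.ndarray
    tukey_table: pd.DataFrame
    n_replicates: int
    anova_p: float = float("nan")

    def group_means(self) -> dict[int, float]:
        return {m0: float(self.jsd_matrix[:, j].mean())
                for j, m0 in enumerate(self.m0_values)}


# ---------------------------------------------------------------------------
# Binning and divergences
# ---------------------------------------------------------------------------

def bin_distribution(results: Sequence[ChangepointResult],
                     edges_x: np.ndarray, edges_y: np.ndarray,
                     ) -> BinnedDistribution:
    """Normalized joint histogram of (slope_diff, t_trans).

    Values outside the edge range are clipped into the end bins, so no
    probability mass is discarded.
    """
    if len(results) == 0:
        raise ValueError("cannot bin an empty result set")
    edges_x = np.asarray(edges_x, dtype=float)
    edges_y = np.asarray(edges_y, dtype=float)
    x = np.array([r.slope_diff for r in results], dtype=float)
    y = np.array([r.t_trans for r in results], dtype=float)
    # clip strictly inside the outer edges so histogram2d keeps everything
    x = np.clip(x, edges_x[0], edges_x[-1])
    y = np.clip(y, edges_y[0], edges_y[-1])
    h, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    return BinnedDistribution(edges_x, edges_y, h / h.sum())


def _check_edges(P: BinnedDistribution, Q: BinnedDistribution) -> None:
    if not (np.array_equal(P.bin_edges_x, Q.bin_edges_x)
            and np.array_equal(P.bin_edges_y, Q.bin_edges_y)):
        raise ValueError("distributions must share bin edges")


def kl_divergence(P: BinnedDistribution, Q: BinnedDistribution) -> float:
    """Kullback-Leibler divergence sum_x P(x) ln(P(x)/Q(x)), in nats.

    Bins with P = 0 contribute nothing; P > 0 where Q = 0 gives +inf
    (absolute-continuity failure — never happens inside the JSD mixture).
    """
    _check_edges(P, Q)
    p = P.probs.ravel()
    q = Q.probs.ravel()
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def jsd(P: BinnedDistribution, Q: BinnedDistribution) -> float:
    """Jensen-Shannon divergence ½D(P‖M) + ½D(Q‖M) with M = (P+Q)/2.

    Symmetric, always finite, bounded by ln 2 in nats.
    """
    _check_edges(P, Q)
    mix = BinnedDistribution(P.bin_edges_x, P.bin_edges_y,
                             0.5 * (P.probs + Q.probs))
    return 0.5 * kl_divergence(P, mix) + 0.5 * kl_divergence(Q, mix)


def marginal_jsd(P: BinnedDistribution, Q: BinnedDistribution) -> tuple[float, float]:
    """JSD of the slope-difference and transition-time marginals separately."""
    _check_edges(P, Q)
    out = []
    for axis in (1, 0):  # sum over the other axis
        p = P.probs.sum(axis=axis)
        q = Q.probs.sum(axis=axis)
        m = 0.5 * (p + q)
        def kl(a, b):
            mask = a > 0
            return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))
        out.append(0.5 * kl(p, m) + 0.5 * kl(q, m))
    return out[0], out[1]


def reference_edges(results: Sequence[ChangepointResult], bins: int = 20,
                    lo_pct: float = 0.5, hi_pct: float = 99.5,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Shared bin edges spanning the central mass of a reference set.

    ``bins`` equal-width bins between the 0.5th and 99.5th percentile of
    each coordinate; out-of-range values are later clipped into the end
    bins by :func:`bin_distribution`.
    """
    x = np.array([r.slope_diff for r in results], dtype=float)
    y = np.array([r.t_trans for r in results], dtype=float)
    ex = np.linspace(*np.percentile(x, [lo_pct, hi_pct]), bins + 1)
    ey = np.linspace(*np.percentile(y, [lo_pct, hi_pct]), bins + 1)
    for e in (ex, ey):
        if e[0] == e[-1]:  # degenerate reference: widen artificially
            e += np.linspace(-0.5, 0.5, bins + 1)
    return ex, ey


# ---------------------------------------------------------------------------
# The M0 sweep study
# ---------------------------------------------------------------------------

def m0_sweep_study(reference: Sequence[ChangepointResult],
                   params_base: SimulationParams,
                   m0_values: Sequence[int],
                   n_replicates: int,
                   initial_rates_source: Callable[[int, np.random.Generator], np.ndarray],
                   seed: int,
                   bins: int = 20,
                   grid_step: float = 0.5,
                   min_seg: float = 2.0,
                   ) -> DivergenceReport:
    """Replicate JSD-to-reference study across M0 variants, with Tukey HSD.

    For each M0 and replicate a fresh population is simulated (initial
    rates drawn from ``initial_rates_source(n, rng)``), its changepoint
    distribution binned on edges fixed by the reference, and the JSD to
    the binned reference computed.  The replicate JSD groups are then
    compared by one-way ANOVA and Tukey's range test.

    Fully reproducible: the replicate seeds are spawned from ``seed`` and
    keyed by (variant, replicate), so adding variants or replicates does
    not reshuffle earlier ones.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    if len(m0_values) == 0:
        raise ValueError("m0_values must be non-empty")

    edges_x, edges_y = reference_edges(reference, bins=bins)
    ref_binned = bin_distribution(reference, edges_x, edges_y)

    root = np.random.SeedSequence(seed)
    jsd_matrix = np.empty((n_replicates, len(m0_values)))
    for j, m0 in enumerate(m0_values):
        for rep in range(n_replicates):
            child = np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(j, rep))
            rate_rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence(entropy=root.entropy,
                                       spawn_key=(j, rep, 1))))
            sim_seed = int(child.generate_state(1)[0] % (2 ** 31))
            params = replace(params_base, M0=int(m0), seed=sim_seed)
            rates = initial_rates_source(params.n_worms, rate_rng)
            trajs = simulate_population(params, initial_rates=rates)
            res = population_changepoints(trajs, grid_step=grid_step,
                                          min_seg=min_seg,
                                          total_duration=params.duration)
            cand = bin_distribution(res, edges_x, edges_y)
            jsd_matrix[rep, j] = jsd(ref_binned, cand)
        logger.info("M0=%d: mean JSD %.4f", m0, jsd_matrix[:, j].mean())

    groups = [jsd_matrix[:, j] for j in range(len(m0_values))]
    if len(groups) > 1:
        anova_p = float(stats.f_oneway(*groups).pvalue)
        hsd = stats.tukey_hsd(*groups)
        rows = []
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                rows.append({
                    "group_a": m0_values[a],
                    "group_b": m0_values[b],
                    "mean_diff": float(groups[a].mean() - groups[b].mean()),
                    "p_adj": float(hsd.pvalue[a, b]),
                })
        table = pd.DataFrame(rows)
    else:
        anova_p = float("nan")
        table = pd.DataFrame(columns=["group_a", "group_b", "mean_diff", "p_adj"])

    return DivergenceReport(m0_values=list(m0_values), jsd_matrix=jsd_matrix,
                            tukey_table=table, n_replicates=n_replicates,
                            anova_p=anova_p)


# ---------------------------------------------------------------------------
# Trajectory matching
# ---------------------------------------------------------------------------

def best_match(reference_curve: CumulativeCurve,
               candidates: Sequence[CumulativeCurve]) -> tuple[int, float]:
    """Candidate cumulative curve with the highest Pearson correlation.

    All curves must share the reference time grid.  Zero-variance
    candidates (e.g. no events) have undefined correlation and are
    skipped.  Ties go to the smallest index.
    """
    ref = np.asarray(reference_curve.omega, dtype=float)
    if ref.std() == 0:
        raise ValueError("reference curve has zero variance")
    best_i, best_c = -1, -np.inf
    for i, cand in enumerate(candidates):
        if not np.array_equal(cand.time_grid, reference_curve.time_grid):
            raise ValueError("candidate grid differs from reference grid")
        v = np.asarray(cand.omega, dtype=float)
        if v.std() == 0:
            logger.debug("candidate %d has zero variance; skipped", i)
            continue
        c = float(np.corrcoef(ref, v)[0, 1])
        if c > best_c:
            best_i, best_c = i, c
    if best_i < 0:
        raise ValueError("no candidate with finite correlation")
    return best_i, best_c
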