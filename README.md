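# wormforage

Stochastic modeling and changepoint analysis of *C. elegans* foraging
reorientation kinetics.

## The problem

When a worm is taken off food, its rate of sharp reorientations decays
from about 1.5 events/min toward a low baseline over tens of minutes.
Individual worms often *look* like they make a single abrupt switch from
an intense "local search" to a sparse "global search" — a behavior
usually read as a discrete internal decision.  But reorientations are
Poissonian point events, and random bunching of events from a smoothly
decaying rate can masquerade as an abrupt switch.  This package provides
the machinery to make that argument quantitative:

1. **Simulator** — an exact Gillespie two-event system per worm:
   a reorientation (Ω ← Ω + 1) with propensity
   `a₁ = (α/M₀)·M + β`, and first-order decay of a signalling factor
   (M ← M − 1) with propensity `a₂ = γ·M`.  Since M decays first order,
   the ensemble reorientation rate follows `α·e^(−γt) + β` while
   individual event streams stay genuinely stochastic.  A constant-rate
   mode (`a₁ = α + β` fixed) is the time-homogeneous control.
2. **Rate analysis** — rolling-window rate curves (centered 2-min window)
   and bounded nonlinear least-squares fitting of the three-parameter
   decay, plus the memory half-life `ln 2 / γ`.
3. **Changepoint** — the classic two-segment regression: every worm's
   cumulative reorientation curve is split at the index minimizing the
   summed residual error of two independent OLS lines; the slope
   difference `s₁ − s₂` measures apparent abruptness and the line
   intersection defines the transition time.
4. **Comparison** — joint (slope difference, transition time)
   distributions are compared with the Jensen-Shannon divergence
   (natural log, ≤ ln 2), and the sensitivity of the model to the
   granularity of M is probed by sweeping M₀ ∈ {1000, 100, 10, 1} with
   replicate populations and Tukey's range test.  M₀ = 1 is a true
   two-state system and is the variant the data can reject.
5. **Synthetic data** — surrogate "experimental" populations
   (heterogeneous initial rates, gamma family, mean 1.5 events/min) so
   the whole stack is testable without the curated tracking dataset.

## Worked example

```python
import numpy as np
import wormforage as wf

params = wf.SimulationParams(n_worms=1631, seed=42)   # defaults: alpha=1.49,
trajs = wf.simulate_population(params)                # beta=0.1937, gamma=0.11,
                                                      # M0=1000, 45 min
curve = wf.population_rate(trajs, window=2.0, grid_step=0.5, total_duration=45.0)
fit = wf.fit_decay(curve)
print(f"alpha={fit.alpha_hat:.4f}  beta={fit.beta_hat:.4f}  gamma={fit.gamma_hat:.4f}")
print(f"half-life of M: {wf.half_life(fit.gamma_hat):.2f} min")

res = wf.population_changepoints(trajs)
sd = np.array([r.slope_diff for r in res])
print(f"median slope difference: {np.median(sd):.3f} events/min")
print(f"fraction with slope_diff > 1: {np.mean(sd > 1):.2f}")
```

prints

```
alpha=1.4545  beta=0.1955  gamma=0.1082
half-life of M: 6.40 min
median slope difference: 0.751 events/min
fraction with slope_diff > 1: 0.31
```

The fitted constants recover the generating kinetics (α and γ within a
few percent), and the changepoint analysis of the very same smoothly
decaying model yields a *continuum* of slope differences — roughly a
third of the in-silico worms would be called abrupt "deciders" even
though no decision mechanism exists in the model.

The same pipeline is available from a shell:

```bash
wormforage simulate --n-worms 200 --seed 4 --out events.csv
wormforage fit --events events.csv --out fit.json
wormforage changepoint --events events.csv --out cp.csv
wormforage compare --reference cp.csv --candidate cp.csv --out cmp.json
wormforage sweep --reference cp.csv --m0 1000,100,10,1 --replicates 20 --seed 1 --out sweep.json
```

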