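# Methods

## Model

Each worm is an independent continuous-time Markov jump process with two
event channels over state (Ω, M):

* reorientation, Ω ← Ω + 1, propensity `a₁ = (α/M₀)·M + β`;
* factor decay, M ← M − 1, propensity `a₂ = γ·M`.

M is a phenomenological signalling factor whose count couples
multiplicatively to the reorientation propensity; because its decay is
first order, E[M(t)] = M₀·e^(−γt) and the ensemble reorientation rate is
`α·e^(−γt) + β`.  The expected cumulative count for a worm started at M₀
is `(α/γ)(1 − e^(−γt)) + β·t`.  A printed rate-of-change convention
would make the decay propensity negative; propensities must be
non-negative, so the implemented decay propensity is `γ·M`, which is the
form consistent with the exponential solution for M.

Simulation is Gillespie's direct method: waiting time
`τ = −ln(r₁)/a₀` with `a₀ = a₁ + a₂`, event selection by the cumulative
rule (event 1 iff `r₂·a₀ ≤ a₁`).  `r₁ = 0` is resampled (infinite τ);
`r₁ = 1` (τ = 0) is accepted as a measure-zero case.  When `a₀ = 0`
(M exhausted with β = 0) no event can ever fire and the worm coasts to
the end of the recording.  Uniform variates are consumed strictly in
draw order but generated in batches for speed; the stream is identical
to scalar draws.

In `constant` mode `a₁ ≡ α + β` and `a₂ ≡ 0` with M untouched — the
time-homogeneous Poisson control used to show that apparent abrupt rate
changes arise even without any time dependence.

## Parameters

| name | units | default | meaning |
|---|---|---|---|
| α | events/min | 1.49 | amplitude of the decaying rate component |
| β | events/min | 0.1937 | baseline rate as t → ∞ |
| γ | 1/min | 0.11 | decay constant of M (alternative estimate 0.07 kept as `GAMMA_SLOW`; its half-life ln2/0.07 ≈ 9.9 min is the "memory" of the last food encounter) |
| M₀ | count | 1000 | initial factor count; large ⇒ quasi-continuous decay |
| duration | min | 45 | recording window (the quoted "~40 min timescale" is treated as approximate) |

Heterogeneous initial conditions: worm j's starting count is
`M_j = round(M₀(r − β)/α)` clamped to [0, M₀], where r is that worm's
initial rate draw.  Rounding is half-up because M is a discrete count;
draws below β clamp to 0 (baseline-rate worm), draws above α + β clamp
to M₀ — the representable initial-rate band is [β, α + β], so the
*realized* mean initial rate of a surrogate population sits slightly
below the rate-model mean.

RNG discipline: per-worm streams are spawned from the master seed via
`SeedSequence(seed).spawn`, keyed by worm index, so individual worms are
reproducible and enlarging the population never reshuffles earlier
worms.  Sweep replicates are keyed by (variant, replicate) the same way.

## Rate curves and decay fitting

Rates are measured in a centered rolling window (default 2 min) on a
0.5-min grid; at the boundaries the window is truncated to the recording
and the count renormalized by the effective window length, which avoids
the artificial early-rate dip a trailing window would create.  The
population curve is the pointwise mean/SD across worms (the per-column
reduction is sorted first so the result is bitwise order-invariant).

`fit_decay` is ordinary (unweighted) nonlinear least squares of
`α·e^(−γt) + β` on the mean curve, all parameters bounded below by 0,
with the deterministic scale-free start (range, minimum, 3/T).  The
choice of mean-curve fitting (rather than any histogram-based loss) and
of unweighted residuals reflects how the kinetic constants are assigned
from the average population rate.  On exact curves the fit is an
identity map to solver tolerance; on a 1631-worm simulated population it
recovers α and γ within a few percent and β within ~15% (β is weakly
identified over 45 min because the decaying term has not fully died).

## Changepoint analysis

Per worm, the cumulative count Ω(t) is discretized on a uniform 0.5-min
grid (events exactly at a grid time count at that time) and split
exhaustively at every index leaving at least 2 min (≥ 4 points) per
side.  Each side gets an independent OLS line — no continuity
constraint, because the transition time is defined as the intersection
of the two lines and an intersection is only meaningful for
unconstrained lines.  The split minimizing total RSS wins; ties go to
the smallest index.  All splits are evaluated in O(n) from prefix sums
of (x, y, x², xy, y²); equality with a brute-force per-split `polyfit`
oracle is property-tested.  When the two slopes agree within 1e−9
(relative) the intersection is numerically meaningless: the split's grid
time is reported and the result flagged degenerate rather than dropped,
keeping population denominators intact.  No "decider" threshold is
built in — the slope-difference distribution is continuous, which is the
scientific point.

Regressing cumulative counts (rather than windowed rates) matches the
cumulative-curve presentation of the analysis being reproduced; it is
recorded here because the alternative would change the distributions.

## Distribution comparison and the M₀ sweep

The joint (slope difference, transition time) distribution is binned on
a shared 20×20 grid spanning the 0.5th–99.5th percentiles of the
*reference* set, with out-of-range mass clipped into the end bins (no
mass discarded; degenerate fits with wild intersection times land in the
end bins).  KL and JSD use natural log; JSD ≤ ln 2 and is symmetric and
always finite because both divergences are taken against the mixture.
Marginal-JSD utilities are provided, but the joint histogram is primary.

The M₀ sweep simulates `n_replicates` fresh populations per variant
(default 400 worms each at desk scale; the reference surrogate uses
1631 worms to pin down the bin edges), computes each replicate's JSD to
the fixed reference, then compares the groups by one-way ANOVA and
Tukey's range test.  Tukey is computed with `scipy.stats.tukey_hsd`,
whose studentized-range p-values are exact rather than clipped at
0.001, so p-values far below the three-star level are reported as such.
With an M₀ = 1000-like reference, the M₀ = 1000/100/10 groups are
statistically indistinguishable while the binary M₀ = 1 group — a true
two-state system whose slope-difference distribution is bimodal — is
separated at p ≪ 0.001.

`best_match` ranks candidate cumulative curves by Pearson correlation
with a reference curve on a shared grid (cumulative counts, not rate
curves); zero-variance candidates are skipped.

## Synthetic data

The surrogate generator stands in for a curated tracking dataset that
cannot be redistributed (~1631 worms, 45-min recordings, mean initial
rate ≈ 1.5 events/min, exponentially decaying mean rate).  Initial rates
default to a gamma family with mean 1.5 events/min and shape 4
(SD 0.75), chosen to echo the visibly broad observed spread of initial
rates; truncated-normal and empirical-resampling families are available.
Every generator is a pure function of (parameters, seed), and surrogate
event CSVs are byte-identical across reruns.

What the surrogate does *not* emulate: pheromone-track and collision
interactions between co-recorded worms (which inflate early experimental
rates), and any neuronal mechanism behind M.  Tests passing on the
surrogate therefore validate the algorithmic stack and the model's
internal consistency, not the fit of the model to real recordings.

## Numerical choices and limitations

* Two-segment RSS values are clamped at 0 from below (prefix-sum
  cancellation can produce −1e−25-scale values).
* The decay fit can stall on degenerate inputs (e.g. all-zero curves);
  `converged=False` is then reported with the best iterate.
* Problem sizes: acceptance-level runs use 1631-worm reference
  populations, 400-worm sweep replicates, 20 replicates per variant, and
  500–10,000 worms for the ensemble statistics — sizes at which every
  statistical check has comfortable margin while a full run stays in the
  tens of seconds.
* JSD magnitudes depend on the (unpublished) binning of the original
  analysis and on the reference distribution; only orderings and
  significance patterns are comparable across implementations, not raw
  JSD values.
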