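"""Unit and property tests for the Gillespie event simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wormforage as wf
from wormforage.simulator import PropensityState


class TestPropensities:
    @pytest.mark.parametrize("M, kw, a1, a2", [
        # fitted constants at full factor count: a1 = alpha + beta, a2 = gamma*M0
        (1000, dict(alpha=1.49, beta=0.1937, gamma=0.11, M0=1000), 1.6837, 110.0),
        # decay exhausted: only the baseline remains
        (0, dict(alpha=1.49, beta=0.1937, gamma=0.11, M0=1000), 0.1937, 0.0),
        # half-depleted linearity
        (500, dict(alpha=2.0, beta=0.0, gamma=0.1, M0=1000), 1.0, 50.0),
    ])
    def test_examples(self, M, kw, a1, a2):
        props = wf.compute_propensities(M, wf.SimulationParams(**kw))
        assert props.a1 == pytest.approx(a1, abs=1e-12)
        assert props.a2 == pytest.approx(a2, abs=1e-12)
        assert props.a0 == props.a1 + props.a2

    def test_constant_mode_is_time_invariant(self):
        params = wf.SimulationParams(alpha=1.5, beta=0.0, mode="constant")
        for M in (0, 500, 1000):
            props = wf.compute_propensities(M, params)
            assert props == PropensityState(1.5, 0.0, 1.5)

    def test_m0_zero_with_m_positive_rejected(self):
        params = wf.SimulationParams(M0=0)
        with pytest.raises(wf.ConfigurationError):
            wf.compute_propensities(1, params)

    def test_m_outside_range_rejected(self, base_params):
        with pytest.raises(ValueError):
            wf.compute_propensities(1001, base_params)


class TestDrawInterval:
    @pytest.mark.parametrize("a0, r1, tau", [
        (3.7, 1.0, 0.0),                    # ln 1 = 0
        (2.0, math.exp(-1.0), 0.5),         # closed form
        (4.0, 0.25, math.log(4.0) / 4.0),   # -ln(0.25)/4
    ])
    def test_closed_form(self, a0, r1, tau):
        assert wf.draw_interval(a0, r1) == pytest.approx(tau, abs=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wf.draw_interval(0.0, 0.5)
        with pytest.raises(ValueError):
            wf.draw_interval(1.0, 0.0)


class TestSelectEvent:
    def test_cumulative_rule_by_hand(self):
        # r2*a0 = 0.5*4 = 2 > a1 = 1, so the decay event fires
        assert wf.select_event(PropensityState(1.0, 3.0, 4.0), 0.5) == 2

    def test_boundary_r2_zero(self):
        assert wf.select_event(PropensityState(0.2, 5.0, 5.2), 0.0) == 1

    def test_selection_frequency_matches_relative_propensity(self, rng):
        # a1 is 10% of a0 -> event 1 should fire ~10% of the time
        props = PropensityState(1.0, 9.0, 10.0)
        draws = rng.random(10_000)
        frac = np.mean([wf.select_event(props, r) == 1 for r in draws])
        assert frac == pytest.approx(0.1, abs=4 * math.sqrt(0.1 * 0.9 / 10_000))


class TestAssignInitialM:
    @pytest.mark.parametrize("r, expected", [
        (1.49 + 0.1937, 1000),  # full amplitude
        (0.1937, 0),            # baseline only
        (1.0, 541),             # round(1000*0.8063/1.49)
        (0.05, 0),              # below baseline: clamped
        (10.0, 1000),           # above full amplitude: clamped
    ])
    def test_inversion(self, r, expected, base_params):
        assert wf.assign_initial_M(r, base_params) == expected

    def test_propensity_roundtrip_within_rounding(self, base_params):
        # with continuous M the assigned a1 would equal r; rounding costs
        # at most alpha/(2*M0)
        for r in (0.3, 0.7, 1.2, 1.6):
            m = wf.assign_initial_M(r, base_params)
            a1 = wf.compute_propensities(m, base_params).a1
            assert abs(a1 - r) <= base_params.alpha / (2 * base_params.M0) + 1e-12

    def test_alpha_zero_rejected(self):
        with pytest.raises(wf.ConfigurationError):
            wf.assign_initial_M(1.0, wf.SimulationParams(alpha=0.0))


class TestSimulateWorm:
    def test_null_process_produces_nothing(self, rng):
        params = wf.SimulationParams(alpha=0.0, beta=0.0, gamma=0.0, M0=10)
        traj = wf.simulate_worm(params, 10, rng)
        assert traj.n_events == 0
        assert traj.m_path.shape == (1, 2)
        assert traj.m_path[0, 1] == 10

    def test_constant_mode_event_count_is_poisson(self):
        # rate 1.5/min for 40 min -> Poisson(60): mean and variance both 60
        params = wf.SimulationParams(alpha=1.5, beta=0.0, duration=40.0,
                                     mode="constant", n_worms=10_000, seed=13)
        counts = np.array([t.n_events for t in wf.simulate_population(params)])
        assert counts.mean() == pytest.approx(60.0, abs=4 * math.sqrt(60 / 10_000))
        assert counts.var() == pytest.approx(60.0, rel=0.06)

    def test_m0_one_is_a_two_state_system(self):
        # with M0=1 the instantaneous rate is either alpha+beta or beta
        params = wf.SimulationParams(M0=1, n_worms=50, seed=3)
        for traj in wf.simulate_population(params):
            ms = traj.m_path[:, 1]
            assert set(ms) <= {0.0, 1.0}
            assert len(ms) <= 2  # at most one decay event

    def test_identical_seed_bit_identical_streams(self):
        params = wf.SimulationParams(n_worms=8, duration=15.0, seed=99)
        a = wf.simulate_population(params)
        b = wf.simulate_population(params)
        for x, y in zip(a, b):
            assert np.array_equal(x.event_times, y.event_times)
            assert np.array_equal(x.m_path, y.m_path)

    def test_worm_streams_stable_under_population_growth(self):
        small = wf.simulate_population(wf.SimulationParams(n_worms=3, duration=10.0, seed=5))
        large = wf.simulate_population(wf.SimulationParams(n_worms=6, duration=10.0, seed=5))
        for x, y in zip(small, large[:3]):
            assert np.array_equal(x.event_times, y.event_times)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.0, 3.0), beta=st.floats(0.0, 0.5),
           gamma=st.floats(0.0, 0.5), m0=st.integers(0, 200),
           seed=st.integers(0, 2**20))
    def test_trajectory_invariants(self, alpha, beta, gamma, m0, seed):
        params = wf.SimulationParams(alpha=alpha, beta=beta, gamma=gamma,
                                     M0=m0, duration=20.0, seed=seed)
        rng = np.random.Generator(np.random.PCG64(seed))
        traj = wf.simulate_worm(params, m0, rng)
        ev = traj.event_times
        assert np.all(np.diff(ev) > 0)
        assert np.all((ev >= 0) & (ev <= params.duration))
        ms = traj.m_path[:, 1]
        assert np.all(np.diff(ms) == -1)  # each decay event drops M by 1
        assert np.all(ms >= 0)
        assert ms[0] == m0


class TestSimulatePopulation:
    def test_singleton(self, base_params):
        trajs = wf.simulate_population(wf.SimulationParams(n_worms=1, seed=0))
        assert len(trajs) == 1

    def test_full_amplitude_rates_start_at_m0(self):
        params = wf.SimulationParams(n_worms=4, duration=5.0, seed=1)
        rates = [params.alpha + params.beta] * 4
        for t in wf.simulate_population(params, initial_rates=rates):
            assert t.initial_M == params.M0

    def test_rate_length_mismatch(self):
        params = wf.SimulationParams(n_worms=3, seed=0)
        with pytest.raises(ValueError):
            wf.simulate_population(params, initial_rates=[1.0, 2.0])

    def test_initial_population_rate_matches_assigned_rates(self, rng):
        # self-consistency: the rolling rate at t=0 reflects the mean of
        # the assigned initial rates (drawn inside the representable band
        # [beta, alpha+beta]), corrected for decay across the first window
        params = wf.SimulationParams(n_worms=400, seed=17)
        rates = rng.uniform(0.3, 1.6, size=400)
        trajs = wf.simulate_population(params, initial_rates=rates)
        curve = wf.population_rate(trajs, 2.0, 0.5, params.duration)
        g = params.gamma
        expected = (rates.mean() - params.beta) * (1 - math.exp(-g)) / g \
            + params.beta
        se = curve.sd[0] / math.sqrt(400)
        assert abs(curve.rates[0] - expected) < 3 * se


class TestConstantModeIntervals:
    def test_waiting_times_are_exponential(self):
        """KS test of pooled inter-event intervals against Exponential(a0)."""
        from scipy import stats
        a0 = 1.5
        params = wf.SimulationParams(alpha=a0, beta=0.0, duration=40.0,
                                     mode="constant", n_worms=200, seed=8)
        intervals = []
        for traj in wf.simulate_population(params):
            intervals.append(np.diff(traj.event_times, prepend=0.0))
        pooled = np.concatenate(intervals)[:10_000]
        assert len(pooled) == 10_000
        p = stats.kstest(pooled, "expon", args=(0, 1 / a0)).pvalue
        assert p > 0.01
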