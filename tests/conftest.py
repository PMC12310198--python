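import numpy as np
import pytest

import wormforage as wf


@pytest.fixture(scope="session")
def base_params() -> wf.SimulationParams:
    """Default kinetics: alpha=1.49, beta=0.1937, gamma=0.11, M0=1000, 45 min."""
    return wf.SimulationParams()


@pytest.fixture(scope="session")
def small_population() -> list[wf.Trajectory]:
    """Tiny deterministic population reused across IO / CLI tests."""
    params = wf.SimulationParams(n_worms=5, duration=10.0, seed=7)
    return wf.simulate_population(params)


@pytest.fixture(scope="session")
def homogeneous_population(base_params) -> list[wf.Trajectory]:
    """500 worms at default kinetics, all initialized at M0 (shared across
    the ensemble-statistics tests to avoid re-simulating)."""
    params = wf.SimulationParams(n_worms=500, seed=42)
    return wf.simulate_population(params)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(20250925))
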