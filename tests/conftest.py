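import pytest

from tetrapulse import Condition, KineticParams, PopulationConfig, generate_population


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def small_population(params):
    """A small noisy WT population at one dose (shared, read-only)."""
    cfg = PopulationConfig(conditions=(Condition(6.0),), n_cells=20,
                           duration=720.0, seed=42)
    return generate_population(cfg, params)


@pytest.fixture(scope="session")
def noiseless_dose_series(params):
    """One noise-free cell per dose, throttle on (shared, read-only)."""
    cfg = PopulationConfig(conditions=tuple(Condition(d) for d in (3.0, 6.0, 12.0)),
                           n_cells=1, duration=1440.0,
                           cv_beta=0.0, cv_kt=0.0, sigma_add=0.0, seed=0)
    return generate_population(cfg, params)
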