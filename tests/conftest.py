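import numpy as np
import pytest

from nerveimpedance import (
    CircuitParameters,
    FrequencyGrid,
    GROUP_NAMES,
    default_initial_parameters,
    reference_state_parameters,
)


@pytest.fixture(scope="session")
def reference_initials() -> CircuitParameters:
    return default_initial_parameters("reference")


@pytest.fixture(scope="session")
def state_params() -> dict[str, CircuitParameters]:
    return {g: reference_state_parameters(g) for g in GROUP_NAMES}


@pytest.fixture(scope="session")
def sweep_grid() -> FrequencyGrid:
    return FrequencyGrid.default_sweep()


@pytest.fixture(scope="session")
def coarse_grid() -> FrequencyGrid:
    """35-point log grid used for fast fitting tests."""
    return FrequencyGrid.log_spaced(35)


def random_state_like_parameters(rng: np.random.Generator,
                                 decades: float = 3.0) -> CircuitParameters:
    """A physically plausible random parameter set: one of the reference
    tissue states jittered log-uniformly by up to ``decades``."""
    base = reference_state_parameters(
        GROUP_NAMES[int(rng.integers(len(GROUP_NAMES)))]).to_vector()
    return CircuitParameters.from_vector(
        base * 10.0 ** rng.uniform(-decades, decades, 8))
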