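import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    from neuroenergetics.kinetics import default_parameters
    return default_parameters()


@pytest.fixture(scope="session")
def fitness_thresholds(params):
    """Glucose-fitness thresholds at 5 mM lactate for all demand levels."""
    from neuroenergetics.sweep import glucose_threshold
    return {level: glucose_threshold(level, 5.0, params, tol=0.01)
            for level in ("low", "intermediate", "high")}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
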