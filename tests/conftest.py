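import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import codadiff as cd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_counts():
    rng = np.random.default_rng(42)
    values = rng.poisson(50, size=(30, 10))
    return cd.CountMatrix(values, [f"f{i}" for i in range(30)], [f"s{j}" for j in range(10)])


@pytest.fixture(scope="session")
def small_groups():
    return cd.GroupAssignment({f"s{j}": ("A" if j < 5 else "B") for j in range(10)})


@pytest.fixture(scope="session")
def signal_sim():
    """Low-variance benchmark dataset with clear signal, 20 per group."""
    design = cd.SimDesign(n_features=400, n_per_group=20, dispersion="low")
    return cd.simulate(design, seed=7)
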