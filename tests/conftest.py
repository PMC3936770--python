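import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230101)


@pytest.fixture(scope="session")
def standard_scheme():
    from cpgsim import preset_scheme

    return preset_scheme("standard")


@pytest.fixture(scope="session")
def collab_scheme():
    from cpgsim import preset_scheme

    return preset_scheme("full_feedback")


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once so individual tests time only physics."""
    import cpgsim as c

    cfg = c.SimulationConfig(L=4, generations=1, seed=0)
    c.run_trajectory(c.all_m(4), c.preset_scheme("full_feedback"), cfg)
    geo = c.build_geometry(3, 3)
    c.run_spatial_trajectory(
        c.all_m(6), c.preset_scheme("spatial_default"),
        c.SimulationConfig(L=6, generations=1, seed=0), geo,
    )
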