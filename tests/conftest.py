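import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import foulfit as ff

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MECHANISMS = ["complete", "intermediate", "standard", "cake"]


@pytest.fixture(scope="session")
def grid60():
    """Default 1-min grid over a 60-min window (h)."""
    return ff.default_time_grid(60)


@pytest.fixture(scope="session")
def grid120():
    return ff.default_time_grid(120)


def deadend_series(mechanism, jo=400.0, depth=0.25, t_end=1.0, grid=None):
    """Noiseless dead-end curve declining to depth·Jo at t_end."""
    grid = ff.default_time_grid(60) if grid is None else grid
    k = ff.calibrate_k(mechanism, jo, depth * jo, t_end, family="dead_end")
    return ff.simulate_deadend(ff.BlockingParams(mechanism, Jo=jo, K=k), grid), k


def crossflow_series(mechanism, jo=400.0, jr=60.0, depth=1.1, t_end=1.0, grid=None):
    """Noiseless crossflow curve declining to depth·JR at t_end."""
    grid = ff.default_time_grid(60) if grid is None else grid
    k = ff.calibrate_k(mechanism, jo, depth * jr, t_end, jr=jr, family="crossflow")
    params = ff.BlockingParams(mechanism, Jo=jo, K=k, JR=jr, family="crossflow")
    return ff.simulate_crossflow(params, grid), k
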