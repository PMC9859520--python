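import random

import pytest

from stochcolony import GrowthConfig, SSAConfig, WorkerPlan, build_serial_pathway


@pytest.fixture
def multi4():
    return build_serial_pathway(4, "multi_enz")


@pytest.fixture
def single4():
    return build_serial_pathway(4, "single_enz")


@pytest.fixture
def decay_model():
    """1-reaction S+E->P+E with S=1000, E=10, k=0.001: the pseudo-first-order
    death process with per-molecule rate c = k*E = 0.01."""
    return build_serial_pathway(1)


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def reference_cfg():
    """The benchmark reference settings: interval 0.1, horizon 3."""
    return SSAConfig(method="tau_leaping", interval=0.1, max_time=3.0, seed=0)


@pytest.fixture
def small_plan():
    return WorkerPlan(n_workers=2, cells_per_worker=50)


@pytest.fixture
def default_growth():
    return GrowthConfig()
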