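import numpy as np
import pytest
from hypothesis import settings

from paddyspec import SynthConfig, default_grid, simulate_scene

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_scene():
    """A compact seeded scene shared by unit tests (12 plots of 7 px side)."""
    cfg = SynthConfig(
        rows=60,
        cols=80,
        plot_side=7,
        n_plots=12,
        class_mix=(4 / 12, 5 / 12, 3 / 12),
        seed=11,
    )
    return simulate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
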