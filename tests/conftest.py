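import numpy as np
import pytest

from clonoscope.lineage import ObjectMatrix, build_forest
from clonoscope.sim_colony import (
    SimulationConfig,
    export_tracking_matrix,
    simulate,
)


@pytest.fixture(scope="session")
def clockwork_config():
    """One founder dividing like clockwork: no senescence, no lifetime
    variance, first division at exactly 1.0 d (96 frames)."""
    return SimulationConfig(
        n_founders=1,
        n_frames=375,
        p_senescent_daughter=0.0,
        lifetime_mean_d=1.0,
        lifetime_sd_d=0.0,
        founder_lag_mean_d=0.0,
        media_perturbation_sd=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def clockwork_experiment(clockwork_config):
    return simulate(clockwork_config)


@pytest.fixture(scope="session")
def clockwork_matrix(clockwork_experiment):
    return export_tracking_matrix(clockwork_experiment)


@pytest.fixture(scope="session")
def small_experiment():
    """A stochastic default-parameter colony tracked for two days."""
    cfg = SimulationConfig(n_founders=2, n_frames=200, rng_seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_forest(small_experiment):
    return build_forest(export_tracking_matrix(small_experiment))


@pytest.fixture()
def toy_division_matrix():
    """Three columns: one parent over frames 0-10, two daughters 11-19."""
    values = np.zeros((20, 3), dtype=int)
    values[0:11, 0] = 1
    values[11:20, 1] = 1
    values[11:20, 2] = 2
    return ObjectMatrix(values=values, cells=["a", "b", "c"])
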