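import numpy as np
import pytest

from hdfmap import (
    RunConfig,
    VoxelGrid,
    run_pipeline,
    simulate_dataset,
)


def small_run_config(seed: int = 7) -> RunConfig:
    """A short acquisition (10 s, 6 channels) for fast integration tests."""
    cfg = RunConfig()
    cfg.sim.seed = seed
    cfg.sim.duration_s = 10.0
    cfg.sim.n_channels = 6
    return cfg.validate()


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    return small_run_config()


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg.sim)


@pytest.fixture(scope="session")
def small_run(small_cfg, small_dataset):
    recording, stream, truth = small_dataset
    grid = VoxelGrid(origin=np.zeros(3))
    result = run_pipeline(recording, stream, small_cfg, grid=grid)
    return result, truth
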