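import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ramanferm as rf

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return rf.WavenumberGrid.default()


@pytest.fixture(scope="session")
def library(grid):
    return rf.build_pure_library(grid=grid)


@pytest.fixture(scope="session")
def scenario0():
    """One full synthetic transfer study (fixed seed), shared across tests."""
    return rf.generate_transfer_scenario(seed=0)


@pytest.fixture(scope="session")
def transfer0(scenario0):
    sc = scenario0
    return rf.transfer_experiment(sc.base_calibration, sc.validation_batch,
                                  sc.fed_batch, sc.titrations)


@pytest.fixture(scope="session")
def transfer_runs():
    """Ten independent transfer studies (seeds 0-9) for the direction checks."""
    runs = []
    for seed in range(10):
        sc = rf.generate_transfer_scenario(seed=seed)
        res = rf.transfer_experiment(sc.base_calibration, sc.validation_batch,
                                     sc.fed_batch, sc.titrations)
        runs.append((sc, res))
    return runs


def random_cropped_dataset(rng, n=12, low=450.0, high=520.0):
    """Small dataset at the 'cropped' stage for preprocessing unit tests."""
    grid = rf.WavenumberGrid(np.arange(low, high + 1.0))
    base = 100.0 + 10.0 * np.sin(grid.values / 17.0)
    x = base + rng.normal(0.0, 1.0, size=(n, len(grid)))
    return rf.SpectralDataset(grid=grid, intensities=x, stage="cropped")
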