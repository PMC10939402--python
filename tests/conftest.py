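"""Shared fixtures: synthetic benchmarks and a trained model zoo.

The full-size benchmark and its trained ensemble are session-scoped since
training is the expensive step; several tests interrogate the same zoo.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hardivine.model import (
    SplitSpec,
    TrainConfig,
    default_learner_specs,
    split_train_test,
    train,
)
from hardivine.synthetic import make_benchmark, to_hardiness_dataset

BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def benchmark():
    """Full-size benchmark: 4 sites x 5 cultivars x 4 seasons, 1.0 degC noise."""
    ds = make_benchmark(
        n_sites=4, n_cultivars=5, n_seasons=4, seed=BENCHMARK_SEED, obs_noise_sd=1.0
    )
    data = to_hardiness_dataset(ds)
    assert len(data) >= 2000
    return ds, data


@pytest.fixture(scope="session")
def trained_zoo(benchmark):
    """Stacked ensemble trained on 90% of the benchmark; returns (zoo, train, test)."""
    _, data = benchmark
    tr, te = split_train_test(data, SplitSpec(0.10, BENCHMARK_SEED))
    cfg = TrainConfig(
        num_bag_folds=5,
        num_stack_levels=2,
        learner_specs=tuple(default_learner_specs(fast=True)),
        seed=BENCHMARK_SEED,
    )
    return train(tr, cfg), tr, te


@pytest.fixture(scope="session")
def small_linear_data():
    """Tiny regression problem with a known noiseless linear signal."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.normal(size=(400, 3)), columns=["x1", "x2", "x3"])
    y = pd.Series(2.0 * X["x1"] - X["x2"] + 0.5 * X["x3"], name="y")
    return X, y
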