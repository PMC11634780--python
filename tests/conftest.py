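import os

# many small linear-algebra ops: BLAS thread fan-out only adds contention
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pandas as pd
import pytest

import wmintermit as wm


@pytest.fixture(scope="session")
def small_session():
    """A small but fully featured synthetic session shared across tests."""
    cfg = wm.SimConfig(n_units=24, n_trials_per_condition=6, seed=101)
    spikes, trials, truth = wm.simulate_session(cfg)
    return cfg, spikes, trials, truth


@pytest.fixture(scope="session")
def small_rates(small_session):
    _, spikes, trials, _ = small_session
    return wm.preprocess.smooth_and_zscore_rates(spikes, trials)


@pytest.fixture(scope="session")
def poisson_raster():
    """Independent homogeneous Bernoulli trains for null CCG checks."""
    rng = np.random.default_rng(7)
    X = (rng.random((6, 15, 900)) < 0.006).astype(np.uint8)
    return wm.BinaryRaster(X, np.arange(6), np.arange(15), (500.0, 1400.0))
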