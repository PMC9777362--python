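import numpy as np
import pandas as pd
import pytest

import dualfactor as dfm


def small_generator_config(**overrides) -> dfm.GeneratorConfig:
    """One-wave, small-cell configuration for fast structural tests."""
    kwargs = dict(
        mu={("2014", g, a): 0.3 for g in ("boy", "girl") for a in (11, 13, 15)},
        waves=("2014",),
        n_per_cell=150,
        n_strata=3,
        clusters_per_stratum=4,
        cluster_sd=0.2,
        seed=7,
    )
    kwargs.update(overrides)
    return dfm.GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_config():
    return small_generator_config()


@pytest.fixture(scope="session")
def small_survey(small_config):
    return dfm.generate_survey(small_config)


@pytest.fixture(scope="session")
def small_scored(small_survey):
    return dfm.score_frame(small_survey)


@pytest.fixture(scope="session")
def default_config_cached():
    return dfm.default_config(n_per_cell=1000, seed=5)


def random_roc_dataset(rng, n_max=50):
    """A random small (scores, labels) pair with both classes present."""
    while True:
        n = rng.integers(4, n_max + 1)
        scores = rng.integers(0, 17, size=n).astype(float)
        labels = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
        if 0 < labels.sum() < n:
            return scores, labels
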