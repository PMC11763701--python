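import numpy as np
import pandas as pd
import pytest

from plasma_surv import (
    MultiOmicsCollection,
    OmicsDataset,
    SurvivalOutcome,
    harmonize,
)
from plasma_surv.simulate import BlockSpec, SimulationConfig, simulate_study


def make_outcome(times, events, ids=None):
    ids = ids if ids is not None else [f"s{i}" for i in range(len(times))]
    return SurvivalOutcome(
        pd.Series(times, index=ids, dtype=float),
        pd.Series(events, index=ids, dtype=int),
    )


def make_block(name, values, samples, features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"{name}_f{i}" for i in range(values.shape[0])]
    return OmicsDataset(name, pd.DataFrame(values, index=features, columns=samples))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """Two-block 120-sample study with dropout but no cell-level missing."""
    cfg = SimulationConfig(
        n_samples=120,
        blocks=(BlockSpec("A", 20), BlockSpec("B", 40)),
        block_dropout=0.2,
        cell_missing=0.0,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def reference_study():
    """The reference three-block design at its default settings."""
    return simulate_study(SimulationConfig(seed=11))
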