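"""Shared fixtures for the test suite.

Session-scoped fixtures cache the expensive objects (simulated trial, grown
forest) so unit tests across files reuse one copy.
"""

import numpy as np
import pandas as pd
import pytest

import upliftrules as ur
from upliftrules.schema import FeatureSchema, FeatureSpec
from upliftrules.data import TrialDataset
from upliftrules.tree import TreeGrowthParams


@pytest.fixture
def tiny_schema():
    return FeatureSchema([
        FeatureSpec("x", kind="continuous"),
        FeatureSpec("b", kind="binary"),
        FeatureSpec("c", kind="categorical", levels=("a", "b", "c")),
        FeatureSpec("T", role="treatment", kind="binary"),
        FeatureSpec("Y", role="outcome", kind="binary"),
    ])


@pytest.fixture
def tiny_ds(tiny_schema):
    rng = np.random.default_rng(7)
    n = 40
    X = pd.DataFrame({
        "x": rng.normal(size=n),
        "b": rng.integers(0, 2, size=n),
        "c": rng.choice(["a", "b", "c"], size=n),
    })
    t = rng.integers(0, 2, size=n)
    y = rng.integers(0, 2, size=n)
    return TrialDataset(X=X, t=t, y=y, schema=tiny_schema)


@pytest.fixture(scope="session")
def default_sim():
    """Default planted-effect fixture: (dataset, ground truth)."""
    cfg = ur.default_fixture_config(seed=0)
    return ur.simulate_rct(cfg)


@pytest.fixture(scope="session")
def small_forest(default_sim):
    """A 20-tree forest on the default fixture, shared across test files."""
    ds, _ = default_sim
    return ur.grow_forest(ds, TreeGrowthParams(), n_trees=20, seed=0)
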