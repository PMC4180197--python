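import numpy as np
import pandas as pd
import pytest

from gbscluster.data_model import FeatureSchema, MixedDataset
from gbscluster.synthetic import SyntheticConfig, generate


def make_mixed_dataset(rng, n=12, n_numeric=3, n_categorical=2, n_asym=0,
                       n_classes=2, missing_rate=0.0):
    """Random mixed-type dataset for property and oracle tests."""
    names, kinds, cols = [], {}, {}
    for i in range(n_numeric):
        name = f"num{i}"
        col = rng.normal(0, rng.uniform(0.5, 5.0), size=n)
        if missing_rate:
            col[rng.random(n) < missing_rate] = np.nan
        names.append(name)
        kinds[name] = "numeric"
        cols[name] = col
    for i in range(n_categorical):
        name = f"cat{i}"
        levels = rng.integers(2, 5)
        col = np.array([f"L{v}" for v in rng.integers(0, levels, size=n)],
                       dtype=object)
        if missing_rate:
            col[rng.random(n) < missing_rate] = None
        names.append(name)
        kinds[name] = "categorical"
        cols[name] = col
    for i in range(n_asym):
        name = f"bin{i}"
        col = np.array([str(v) for v in rng.integers(0, 2, size=n)], dtype=object)
        if missing_rate:
            col[rng.random(n) < missing_rate] = None
        names.append(name)
        kinds[name] = "asymmetric_binary"
        cols[name] = col
    schema = FeatureSchema(tuple(names), kinds, "cls")
    labels = np.array([f"C{v}" for v in rng.integers(0, n_classes, size=n)],
                      dtype=object)
    return MixedDataset(pd.DataFrame(cols, columns=names), labels, schema)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_synthetic():
    """One draw from the generator at its default study conditions
    (129 cases split 20/37/59/13 over 156 mixed features)."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_planted():
    """A fast planted dataset for protocol tests: 4 balanced subtypes,
    3 informative numerics among redundancy and noise, p = 14."""
    cfg = SyntheticConfig(
        class_sizes=(10, 10, 10, 10),
        n_informative_numeric=3,
        n_redundant=2,
        n_noise_numeric=5,
        n_categorical=4,
        n_informative_categorical=1,
        seed=7,
    )
    return generate(cfg)
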