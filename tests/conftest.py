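import numpy as np
import pytest

import microgeo as mg


@pytest.fixture(scope="session")
def default_dataset():
    """Reference synthetic scenario: 4 cities, 40/20/20/8 samples, 300 taxa."""
    table, truth = mg.generate_dataset(mg.SyntheticConfig(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def default_relative(default_dataset):
    table, truth = default_dataset
    return mg.filter_and_renormalize(table), truth


@pytest.fixture
def tiny_roster():
    """Two cheap candidates for structural ensemble tests."""
    roster = {c.id: c for c in mg.standard_roster()}
    return [roster["rf"], roster["rpart"]]


def random_confusion(rng, max_classes=8):
    k = rng.integers(2, max_classes + 1)
    n = rng.integers(10, 201)
    m = np.zeros((k, k), dtype=int)
    idx = rng.integers(0, k, size=(n, 2))
    for t, p in idx:
        m[t, p] += 1
    # guarantee every class has truth samples so G-mean covers all classes
    for i in range(k):
        if m[i].sum() == 0:
            m[i, rng.integers(0, k)] += 1
    return m


def random_scores(rng, max_classes=8):
    k = int(rng.integers(2, max_classes + 1))
    n = int(rng.integers(10, 201))
    y = rng.integers(0, k, size=n)
    for c in range(k):  # every class present in the truth
        y[rng.integers(0, n)] = c
    scores = np.round(rng.random((n, k)), 2)  # rounding forces ties
    return list(range(k)), scores, y
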