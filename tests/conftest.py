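import numpy as np
import pytest

from wildrank import IncompleteFactorialData


@pytest.fixture
def worked_example():
    """a=1, d=2, n=4 with one missing cell; every quantity hand-checkable."""
    values = np.array([[1.0, 3.0], [2.0, np.nan], [4.0, 2.0], [3.0, 5.0]])
    return IncompleteFactorialData(values=[values], observed=[~np.isnan(values)])


def random_incomplete(rng, a=2, d=3, n=(5, 6), tie_prob=0.3, miss_prob=0.2):
    """Small random incomplete dataset with ties, all cells >= 2 observed."""
    while True:
        values, observed = [], []
        for n_i in n:
            v = rng.integers(0, 6, size=(n_i, d)).astype(float)
            cont = rng.random((n_i, d)) > tie_prob
            v = np.where(cont, v + rng.random((n_i, d)), v)
            m = rng.random((n_i, d)) >= miss_prob
            values.append(v)
            observed.append(m)
        if all(m.sum(axis=0).min() >= 2 for m in observed):
            return IncompleteFactorialData(values=values, observed=observed)


@pytest.fixture
def random_dataset():
    return random_incomplete(np.random.default_rng(42))
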