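import numpy as np
import pytest

from cswolf import ObjectiveSpec, SyntheticSpec, make_classification


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    """A trivial 2-d problem on [0, 1]^2 (sphere objective)."""
    return ObjectiveSpec(
        d=2, lower=np.zeros(2), upper=np.ones(2), func=lambda x, _rng=None: float(np.sum(x**2))
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Small separable two-class dataset for fast wrapper tests."""
    return make_classification(
        SyntheticSpec(n_samples=60, n_features=12, n_informative=2, class_sep=3.0, seed=7)
    )
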