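import numpy as np
import pytest

from sparsefl import build_model, flatten
from sparsefl.synthetic import make_tabular


@pytest.fixture
def tiny_model():
    return build_model("tiny-mlp", 8, 2, seed=7, hidden=8)


@pytest.fixture
def tiny_params(tiny_model):
    return flatten(tiny_model)


@pytest.fixture
def tiny_batch():
    X, y = make_tabular(16, 8, n_classes=2, separation=2.0, seed=11)
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(123)
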