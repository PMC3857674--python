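import numpy as np
import pandas as pd
import pytest

from mixselect import expand_predictors, scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def s1_data():
    """One Scenario-1 replicate (n=250, K=4, continuous outcome)."""
    return scenario("s1").simulate(11)


@pytest.fixture
def s3_data():
    """One Scenario-3 replicate (T=400, K=4, counts with offset)."""
    return scenario("s3").simulate(11)


@pytest.fixture
def toy_ps(rng):
    """Small well-conditioned predictor set with a known true model."""
    X = rng.lognormal(0.0, 0.5, size=(120, 3))
    return expand_predictors(
        pd.DataFrame(X, columns=["X1", "X2", "X3"]),
        true_coef={"X1": 1.0, "X1*X2": 0.5},
    )
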