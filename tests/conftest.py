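import numpy as np
import pandas as pd
import pytest

from growthdesign import (
    BCCGParams,
    FitConfig,
    SamplingScheme,
    fit_bccg,
    make_fixture,
    random_bccg,
    simulate_dataset,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def height_model():
    return make_fixture("height")


@pytest.fixture(scope="session")
def height_dataset(height_model):
    """n=7000 dataset simulated from the height fixture with sqrt-age
    sampling; shared by fitting and bootstrap tests."""
    rng = np.random.default_rng(101)
    scheme = SamplingScheme(lambda_age=0.5, age_min=0.0, age_max=20.0, n=7000)
    return simulate_dataset(height_model, scheme, rng)


@pytest.fixture(scope="session")
def height_fit(height_dataset):
    return fit_bccg(
        height_dataset, FitConfig(xi=0.5, nu_curve_class="linear")
    )


@pytest.fixture(scope="session")
def single_age_dataset():
    """1000 measurements at one age from constant BCCG parameters
    (mu=50, sigma=0.1, nu=1) — the normal-theory reference case."""
    rng = np.random.default_rng(42)
    y = random_bccg([BCCGParams(50.0, 0.1, 1.0)] * 1000, rng)
    return pd.DataFrame({"age": np.full(1000, 8.0), "y": y})


@pytest.fixture(scope="session")
def single_age_fit(single_age_dataset):
    # nu held at its normal-case value: the normal-theory SE formulas this
    # fixture is compared against assume a two-parameter (mu, sigma) model
    return fit_bccg(single_age_dataset, FitConfig(xi=1.0, nu_value=1.0))
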