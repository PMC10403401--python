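import logging

import numpy as np
import pytest

import mfcbod as m


@pytest.fixture(autouse=True)
def _quiet_padding_warnings(caplog):
    # short-trace padding warnings are expected on synthetic data
    logging.getLogger("mfcbod.core").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def noiseless_params():
    return m.CurveParams(noise_sd=0.0, charge_per_mg=8.0, charge_intercept=20.0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_params):
    """20 noiseless synthetic experiments with a 6-experiment test split."""
    return m.generate_dataset(
        20, seed=101, n_test=6, params=noiseless_params
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy dataset for I/O and pipeline tests."""
    return m.generate_dataset(
        10, seed=42, n_test=3, params=m.CurveParams(noise_sd=0.002)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
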