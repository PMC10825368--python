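import numpy as np
import pandas as pd
import pytest

from uaeopt.anfis import AnfisRegressor
from uaeopt.doe import DEFAULT_FACTORS, generate_ccd
from uaeopt.synthetic import (
    RESPONSE_NAMES,
    coded_grid,
    evaluate_truth,
    make_ground_truth,
)

MEAN = np.array([s.mean for s in DEFAULT_FACTORS])
HALF = np.array([(s.maximum - s.mean) / 2.0 for s in DEFAULT_FACTORS])
DOMAINS = [(s.minimum, s.maximum) for s in DEFAULT_FACTORS]


def coded_to_actual(coded: np.ndarray) -> np.ndarray:
    return MEAN + np.atleast_2d(coded) * HALF


@pytest.fixture(scope="session")
def ccd_design():
    return generate_ccd(DEFAULT_FACTORS, n_center=6, alpha=2.0)


@pytest.fixture(scope="session")
def noise_free_truth():
    return make_ground_truth(seed=1, noise_fraction=0.0)


@pytest.fixture(scope="session")
def augmented_training_data(ccd_design, noise_free_truth):
    """Noise-free responses over the 30-run design plus a 3^4 coded grid."""
    coded = np.vstack([ccd_design.coded, coded_grid(3)])
    Y = evaluate_truth(noise_free_truth, coded)
    return coded, pd.DataFrame(Y, columns=RESPONSE_NAMES)


@pytest.fixture(scope="session")
def trained_models(augmented_training_data):
    """One hybrid-trained surrogate per response on the noise-free data."""
    coded, Y = augmented_training_data
    X = coded_to_actual(coded)
    return {
        name: AnfisRegressor(
            epochs=200, domain=DOMAINS, random_state=k
        ).fit(X, Y[name].to_numpy())
        for k, name in enumerate(RESPONSE_NAMES)
    }


@pytest.fixture(scope="session")
def heldout_points(noise_free_truth):
    rng = np.random.default_rng(99)
    coded = rng.uniform(-2.0, 2.0, size=(300, 4))
    return coded, evaluate_truth(noise_free_truth, coded)
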