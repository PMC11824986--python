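import numpy as np
import pytest

from mkelm import SyntheticSpec, generate_classification_data


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_blobs():
    """A small, moderately overlapping 3-class dataset."""
    return generate_classification_data(
        SyntheticSpec(n_samples=120, n_features=5, n_classes=3, seed=7)
    )


@pytest.fixture
def separable_blobs():
    """A 2-class dataset with separation far exceeding the noise."""
    return generate_classification_data(
        SyntheticSpec(
            n_samples=100,
            n_features=4,
            n_classes=2,
            cluster_separation=20.0,
            noise_sd=0.5,
            seed=3,
        )
    )
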