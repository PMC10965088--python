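import numpy as np
import pytest

from mrigrade import features, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom():
    """One noise-free severity-2 phantom."""
    return synthetic.generate_phantom(synthetic.PhantomSpec(severity=2, noise_sd=0.0, seed=7))


@pytest.fixture
def random_image(rng):
    return rng.random((16, 16))


@pytest.fixture(scope="session")
def bench200():
    """The seeded 200-image benchmark (50 per class, 64x64, default noise)
    with its 90-feature matrix; shared across the expensive tests."""
    ds = synthetic.generate_dataset(50, size=64, noise_sd=0.05, seed=2024)
    X, y = features.extract_feature_matrix(ds)
    return ds, X, y


@pytest.fixture(scope="session")
def cnn200(bench200):
    """The default CNN trained to convergence on the 200-image benchmark."""
    from mrigrade.cnn import SmallCNNClassifier, TrainConfig
    ds, _, _ = bench200
    model = SmallCNNClassifier(config=TrainConfig(epochs=100, seed=1)).fit(ds)
    return model


@pytest.fixture(scope="session")
def blobs4():
    """Well-separated 4-class Gaussian blobs (n=200, separation 10 sigma)."""
    rng = np.random.default_rng(0)
    centers = 10.0 * np.eye(4)  # distinct directions, so correlation
    X = np.vstack([c + rng.normal(scale=1.0, size=(50, 4)) for c in centers])
    y = np.repeat([1, 2, 3, 4], 50)
    return X, y
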