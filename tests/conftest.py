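import numpy as np
import pytest

from flowps import ExpressionDataset, SyntheticConfig, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(values, labels, sample_prefix="s", feature_prefix="g"):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    return ExpressionDataset(
        values=values,
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        feature_ids=[f"{feature_prefix}{j}" for j in range(s)],
        labels=np.asarray(labels, dtype=int),
    )


@pytest.fixture
def tiny_dataset():
    """12 samples x 4 features, separable on g0, balanced classes."""
    rng = np.random.default_rng(0)
    noise = rng.normal(scale=0.3, size=(12, 3))
    signal = np.array([0, 0, 0, 0, 0, 0, 3, 3, 3, 3, 3, 3], dtype=float)
    values = np.column_stack([signal + rng.normal(scale=0.3, size=12), noise])
    return make_dataset(values, [0] * 6 + [1] * 6)


@pytest.fixture
def random_labelled_dataset(rng):
    def _make(n=14, s=5, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        values = r.normal(size=(n, s))
        labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
        return make_dataset(values, labels)

    return _make


def synthetic(n=60, informative=10, noise=40, geometry="global",
              effect=2.0, frac=0.5, seed=0):
    return generate_synthetic(
        SyntheticConfig(
            n_samples=n,
            n_informative=informative,
            n_noise=noise,
            geometry=geometry,
            effect_size=effect,
            responder_fraction=frac,
            seed=seed,
        )
    )
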