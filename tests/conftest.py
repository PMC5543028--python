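import numpy as np
import pytest

from adbench.confidence import PredictionSet
from adbench.datasets import GeneratorSpec, generate_gaussian_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_dataset():
    """Two distant Gaussian blobs: every family should classify near-perfectly."""
    return generate_gaussian_dataset(
        GeneratorSpec(n=200, p=2, class_ratio=0.5, separation=8.0,
                      informative_fraction=1.0, seed=42),
        name="separable",
    )


@pytest.fixture(scope="session")
def intermediate_dataset():
    """Overlapping classes: error rate high enough to exercise AD measures."""
    return generate_gaussian_dataset(
        GeneratorSpec(n=300, p=10, class_ratio=0.5, separation=0.8,
                      informative_fraction=1.0, seed=7),
        name="intermediate",
    )


def make_prediction_set(tp, fn, tn, fp, ideal_ad, seed=0):
    """PredictionSet with exact confusion counts plus an AD vector.

    With ``ideal_ad=True`` every erroneous prediction receives a larger AD
    value than every correct one (and hence ranks least reliable within its
    predicted class); otherwise AD values are iid uniform.
    """
    rng = np.random.default_rng(seed)
    true = np.array([1] * (tp + fn) + [2] * (tn + fp))
    pred = np.array([1] * tp + [2] * fn + [2] * tn + [1] * fp)
    n = len(true)
    ad = rng.uniform(0.0, 0.4, n)
    if ideal_ad:
        wrong = pred != true
        ad[wrong] = rng.uniform(0.6, 1.0, wrong.sum())
    ps = PredictionSet(predicted_class=pred, p_hat=np.full(n, 1.0)).with_truth(true)
    return ps, ad
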