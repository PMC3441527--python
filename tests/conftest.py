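import numpy as np
import pandas as pd
import pytest

from prc2lnc.features import PWM, FeatureMatrix


def fm_from_array(X, labels=None, names=None, ids=None) -> FeatureMatrix:
    """Wrap a plain array as a FeatureMatrix for classifier/metric tests."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names if names is not None else [f"f{j}" for j in range(p)]
    ids = ids if ids is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame(X, index=pd.Index(ids, name="sample_id"), columns=names)
    return FeatureMatrix(df, None if labels is None else np.asarray(labels, int))


@pytest.fixture
def two_cloud_matrix():
    """Two well-separated Gaussian clouds in 2 features (n=20/20, 5 SD apart)."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(0.0, 1.0, (20, 2)), rng.normal(5.0, 1.0, (20, 2))])
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    return fm_from_array(X, y)


def random_pwm(rng, name, width=8) -> PWM:
    """A deterministic random count PWM for tests/simulations."""
    counts = rng.integers(0, 20, size=(4, width)).astype(float)
    counts[rng.integers(0, 4, size=width), np.arange(width)] += 30
    return PWM(name, counts)
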