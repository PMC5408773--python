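import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "precurve",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("precurve")


def random_scored_arrays(rng, max_n=80, heavy_ties=False, extreme_imbalance=False):
    """Random (scores, labels) with both classes present; optionally with a
    small tied-score alphabet and near-degenerate class balance."""
    n = int(rng.integers(2, max_n + 1))
    if heavy_ties:
        k = int(rng.integers(1, 6))
        scores = rng.integers(0, k + 1, n).astype(float)
    else:
        scores = rng.normal(size=n)
    if extreme_imbalance and n > 2:
        n_pos = 1 if rng.random() < 0.5 else n - 1
    else:
        n_pos = int(rng.integers(1, n))
    labels = np.zeros(n, bool)
    labels[rng.permutation(n)[:n_pos]] = True
    return scores, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
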