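import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def binormal_scores(rng):
    """Score/label generator with a known true AUC Phi(delta/sqrt(2))."""

    def make(delta: float, n_pos: int, n_neg: int, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        scores = np.concatenate(
            [local.normal(delta, 1.0, n_pos), local.normal(0.0, 1.0, n_neg)]
        )
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        return scores, labels

    return make
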