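import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tgfnn.network import Feature, FeatureSchema
from tgfnn.rules import RuleSet, init_from_rules

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_schema():
    """5 features: 3 continuous + 2 binary comorbidities."""
    return FeatureSchema(
        [
            Feature("sbp", "continuous"),
            Feature("lvef", "continuous"),
            Feature("sodium", "continuous"),
            Feature("diabetes", "categorical", n_levels=2, levels=("absent", "present")),
            Feature("renal_failure", "categorical", n_levels=2, levels=("absent", "present")),
        ]
    )


@pytest.fixture
def small_params(small_schema):
    """Seeded random params on the small schema: K=3 rules, C=2 classes."""
    params = init_from_rules(RuleSet([]), small_schema, K=3, seed=7)
    rng = np.random.default_rng(11)
    params.attention_raw = rng.normal(-0.5, 0.8, params.attention_raw.shape)
    params.connection_raw = rng.normal(-0.5, 0.8, params.connection_raw.shape)
    params.inference_raw = rng.normal(-0.5, 0.8, params.inference_raw.shape)
    params.smoothness.eps = 0.4
    return params


@pytest.fixture
def small_batch(small_schema):
    """8 model-space rows for the small schema (seeded)."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(8, 5))
    X[:, 3] = rng.integers(0, 2, 8)  # binary level codes
    X[:, 4] = rng.integers(0, 2, 8)
    y = rng.integers(0, 2, 8)
    return X, y
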