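import numpy as np
import pytest

import fcexplain as fx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """120 subjects, 10 regions (45 edges), strong planted signal."""
    return fx.generate_fc_dataset(
        fx.SyntheticSpec(n_per_class=60, N=10, effect_size=2.0, seed=42)
    )


@pytest.fixture
def small_spec():
    return fx.SyntheticSpec(n_per_class=60, N=10, effect_size=2.0, seed=42)


@pytest.fixture
def toy_model():
    """2-D linear separator with unit weights: logit = x1 + x2."""
    return fx.MarginClassifier(coef=np.array([1.0, 1.0]), intercept=0.0)
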