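import numpy as np
import pytest

from gaitnfc import synthetic
from gaitnfc.tsk import RuleBase, TSKRule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """4 gaits x 10 windows of 100 frames, committed default profiles."""
    return synthetic.generate_dataset(n_per_gait=10, length=100, seed=7)


def make_rulebase(centers, widths, consequents, class_codes=None):
    """Hand-built rule base for direct inference tests."""
    centers = np.atleast_2d(np.asarray(centers, float))
    widths = np.atleast_2d(np.asarray(widths, float))
    consequents = np.atleast_2d(np.asarray(consequents, float))
    rules = [
        TSKRule(center=c, width=w, consequent=p)
        for c, w, p in zip(centers, widths, consequents)
    ]
    kwargs = {}
    if class_codes is not None:
        kwargs["class_codes"] = class_codes
    return RuleBase(rules=rules, input_dim=centers.shape[1], **kwargs)


@pytest.fixture
def random_rulebase(rng):
    """3 rules over 4 dimensions with random parameters."""
    r, d = 3, 4
    return make_rulebase(
        rng.normal(size=(r, d)),
        rng.uniform(0.5, 2.0, size=(r, d)),
        rng.normal(size=(r, d + 1)),
    )
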