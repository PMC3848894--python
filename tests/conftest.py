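"""Shared fixtures: a scaled-down synthetic cohort and derived artifacts.

The small cohort keeps the default generator's geometry (large gene universe
relative to target/term sizes, so constructed intersections stay
significant) but uses fewer terms, miRNAs and samples for speed.
"""
import numpy as np
import pytest
from hypothesis import settings

from comimod.comi import build_profile, enumerate_pairs, filter_profile
from comimod.synthetic import SyntheticConfig, generate_train_test

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


SMALL_CONFIG = dict(
    n_genes=2000,
    n_mirnas=40,
    n_terms=12,
    n_planted_modules=4,
    n_pos=40,
    n_neg=40,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return generate_train_test(small_config, n_test_pos=30, n_test_neg=30)


@pytest.fixture(scope="session")
def small_pairs(small_cohorts):
    train, _ = small_cohorts
    return enumerate_pairs(train.targets, train.gobp, train.expr)


@pytest.fixture(scope="session")
def small_profiles(small_cohorts, small_pairs):
    train, test = small_cohorts
    return build_profile(train.expr, small_pairs), build_profile(test.expr, small_pairs)


@pytest.fixture(scope="session")
def small_filtered(small_profiles):
    train_profile, _ = small_profiles
    return filter_profile(train_profile)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
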