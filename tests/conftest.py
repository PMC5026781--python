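"""Shared fixtures: the worked-example states and small built-in models."""

import numpy as np
import pytest

from indelhist import AncestrySeq, Del, Ins, build_pwa
from indelhist.ratemodel import make_builtin_model


@pytest.fixture
def ancestor7():
    """Ancestor of the worked example: seven sites, tokens 1..7."""
    return AncestrySeq([1, 2, 3, 4, 5, 6, 7])


@pytest.fixture
def descendant7():
    """Descendant of the worked example: sites 2-4 deleted, 8-10 inserted."""
    return AncestrySeq([1, 5, 6, 8, 9, 10, 7])


@pytest.fixture
def example_pwa(ancestor7, descendant7):
    return build_pwa(ancestor7, descendant7)


@pytest.fixture
def four_event_ops():
    """The four-event history whose LHS has two two-event local histories."""
    return [Del(3, 3), Ins(5, 2), Del(2, 3), Ins(5, 1)]


@pytest.fixture
def dawg_model():
    return make_builtin_model(
        "dawg",
        {"lambda_I": 0.1, "f_I": [0.5, 0.3, 0.2],
         "lambda_D": 0.1, "f_D": [0.5, 0.3, 0.2]},
    )


@pytest.fixture
def long_indel_model():
    return make_builtin_model(
        "long_indel", {"lambda_1": 0.05, "mu_1": 0.1, "mu": [0.1, 0.03, 0.01]}
    )


@pytest.fixture
def flanked_model():
    return make_builtin_model(
        "flanked",
        {"g_I": [0.1, 0.05, 0.02, 0.01, 0.005, 0.002],
         "g_D": [0.12, 0.06, 0.03, 0.02, 0.01, 0.005]},
    )


@pytest.fixture
def single_site_model():
    """Single-site indel rates only; handy for exhaustive small sums."""
    return make_builtin_model("dawg", {"lambda_I": 0.2, "f_I": [1.0],
                                       "lambda_D": 0.2, "f_D": [1.0]})


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
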