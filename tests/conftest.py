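import numpy as np
import pytest

from freqstate import (SyntheticSpec, generate_cohort, make_layout,
                       make_templates)


@pytest.fixture(scope="session")
def layout20():
    return make_layout(20, seed=7)


@pytest.fixture(scope="session")
def layout60():
    return make_layout(60, seed=7)


@pytest.fixture(scope="session")
def templates4(layout20):
    return make_templates(4, layout20, seed=1)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_subjects=2, conditions=("wake", "LOC"),
                         n_templates=4, n_channels=20, duration_s=40.0,
                         snr=8.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


def rng(seed=0):
    return np.random.default_rng(seed)
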