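import numpy as np
import pytest

from noiseletter import StimulusSpec, make_letter_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template_h():
    return make_letter_template("H", checks_per_stroke=3)


@pytest.fixture
def lm_spec():
    return StimulusSpec.lm(0.3)


@pytest.fixture
def cm_spec():
    return StimulusSpec.cm(1.0)
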