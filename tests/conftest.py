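"""Shared fixtures.

The fuzzy c-means phantom runs are the expensive part of the suite, so
they are computed once per session and shared between the segmentation
unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from voxelpipe import segmentation as seg
from voxelpipe import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def three_class_nobias():
    phantom = synth.three_class_phantom(64, noise_sigma=5.0, bias_amp=0.0, seed=11)
    result = seg.fuzzy_cmeans(phantom.image, K=3, gain=False)
    return phantom, result


@pytest.fixture(scope="session")
def three_class_nobias_gain():
    phantom = synth.three_class_phantom(64, noise_sigma=5.0, bias_amp=0.0, seed=11)
    result = seg.fuzzy_cmeans(phantom.image, K=3, gain=True)
    return phantom, result


@pytest.fixture(scope="session")
def three_class_biased():
    phantom = synth.three_class_phantom(64, noise_sigma=5.0, bias_amp=0.2, seed=11)
    result = seg.fuzzy_cmeans(phantom.image, K=3, gain=True)
    return phantom, result


@pytest.fixture(scope="session")
def head_extraction():
    phantom = synth.head_phantom(64, seed=7)
    result = seg.brain_extract(phantom.image)
    return phantom, result


@pytest.fixture(scope="session")
def tooth():
    return synth.tooth_phantom(64, seed=5)
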