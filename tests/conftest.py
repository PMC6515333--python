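"""Shared fixtures: small phantom data and a tiny trained detector.

Everything is generated programmatically at collection time; the trained
detector uses a deliberately small configuration so the whole suite stays
desk-scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from myodetect import DetectorConfig, MyocardiumDetector, make_dataset
from myodetect.phantom import PhantomParams, make_slice


@pytest.fixture(scope="session")
def clean_slice():
    """A noiseless, bias-free mid-ventricular phantom slice."""
    params = PhantomParams(noise_sigma=0.0, bias_amplitude=0.0, seed=0)
    return params, make_slice(params)


@pytest.fixture(scope="session")
def default_slice():
    """One default phantom slice (noise + bias on)."""
    params = PhantomParams(seed=3)
    return params, make_slice(params)


@pytest.fixture(scope="session")
def small_dataset():
    """Ten small subjects, four slices each, constrained image sizes."""
    return make_dataset(10, 4, seed=7, variability={"image_size": (128, 160)})


@pytest.fixture(scope="session")
def tiny_config():
    """Reduced detector configuration for fast training in tests."""
    return DetectorConfig.small(pretrain_max_iter=60, finetune_epochs=8)


@pytest.fixture(scope="session")
def trained_results(small_dataset, tiny_config):
    """A detector fitted once and shared across pipeline/model tests."""
    return MyocardiumDetector(small_dataset, tiny_config).fit(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
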