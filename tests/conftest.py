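"""Shared fixtures: cohorts and cubes are expensive, so session-scoped."""

import logging

import numpy as np
import pytest
from hypothesis import settings

from osteospec.synthetic_data import (
    NoiseModel,
    make_tissue_template,
    synth_cohort,
    synth_cube,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

logging.disable(logging.WARNING)

#: a noise model with every stochastic term switched off (baseline retained)
NOISELESS = NoiseModel(
    additive_sigma=0.0, shot_scale=0.0, water_band_mu=0.0, water_band_sd=0.0
)

#: fully zero noise model: no baseline either
ZERO_NOISE = NoiseModel(
    additive_sigma=0.0,
    shot_scale=0.0,
    baseline_poly_coeffs=(0.0,),
    water_band_mu=0.0,
    water_band_sd=0.0,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default six-sample cohort (all modalities, default noise, seed 0)."""
    return synth_cohort(seed=0)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Six-sample cohort with all stochastic terms disabled."""
    return synth_cohort(noise=NOISELESS, seed=0)


@pytest.fixture(scope="session")
def default_template():
    """64x64 template with 3 osteons: the default segmentation target."""
    return make_tissue_template(64, 64, 3, seed=7)


@pytest.fixture(scope="session")
def default_raman_cube(default_template):
    """Fresh-bone Raman cube on the default template with default noise."""
    return synth_cube("raman", 1.0 / 365.25, default_template, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
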