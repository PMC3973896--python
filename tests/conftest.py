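"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from cytomech import mms
from cytomech.simulate import (ImagingConfig, MechanicsTruth,
                               generate_mms_sequence)

DEFAULT_TRUTH = dict(compressive_modulus_pa=400.0, tensile_modulus_pa=600.0,
                     adhesion_force_nn=30.0, h0_um=15.0, d0_um=18.0)


@pytest.fixture(scope="session")
def default_truth() -> MechanicsTruth:
    return MechanicsTruth(**DEFAULT_TRUTH)


@pytest.fixture(scope="session")
def noisefree_imaging() -> ImagingConfig:
    return ImagingConfig(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_imaging() -> ImagingConfig:
    return ImagingConfig(seed=0)  # default noise


@pytest.fixture(scope="session")
def noisefree_run(default_truth, noisefree_imaging):
    """(FrameSequence, truth table) for the default cell, noise-free."""
    return generate_mms_sequence(default_truth, noisefree_imaging)


@pytest.fixture(scope="session")
def noisy_run(default_truth, noisy_imaging):
    return generate_mms_sequence(default_truth, noisy_imaging)


@pytest.fixture(scope="session")
def measurement_config() -> mms.MeasurementConfig:
    return mms.MeasurementConfig()
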