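import numpy as np
import pytest

from centromorph import CentrioleSpec, ExpansionCalibration, ImagingSpec


@pytest.fixture(scope="session")
def calib() -> ExpansionCalibration:
    """Default gel calibration: 50 mm gel, 12 mm coverslip, 35 nm pixels."""
    return ExpansionCalibration(gel_size_mm=50.0)


@pytest.fixture
def noise_free(calib) -> ImagingSpec:
    return ImagingSpec(calib=calib, apply_noise=False, seed=0)


@pytest.fixture
def noisy(calib) -> ImagingSpec:
    return ImagingSpec(calib=calib, apply_noise=True, seed=0)


def top_spec(**kwargs) -> CentrioleSpec:
    kwargs.setdefault("view", "top")
    return CentrioleSpec(**kwargs)


def lateral_spec(**kwargs) -> CentrioleSpec:
    kwargs.setdefault("view", "lateral")
    kwargs.setdefault("tubulin_length_nm", 450.0)
    kwargs.setdefault("protein_coverage_frac", 0.5)
    kwargs.setdefault("protein_position_frac", 0.25)
    return CentrioleSpec(**kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
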