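import numpy as np
import pytest

from sporoquant import ImagingConfig


@pytest.fixture
def noise_free_imaging() -> ImagingConfig:
    """Default optics with all camera noise switched off."""
    return ImagingConfig().noise_free()


@pytest.fixture
def default_imaging() -> ImagingConfig:
    return ImagingConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
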