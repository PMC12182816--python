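"""Shared fixtures: canonical synthetic scenes reused across test modules."""

import numpy as np
import pytest

from pccor.core import AlgoParams
from pccor.simulate import PhantomConfig, generate

CLEAN_COEFFS = (0.8, 0.05, -0.04, 0.02, 0.6)


@pytest.fixture(scope="session")
def params():
    return AlgoParams()


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene with a basis-span background: exact-recovery oracle."""
    cfg = PhantomConfig(seed=1, background_coeffs=CLEAN_COEFFS,
                        noise_sd=0.0, contamination=0.0,
                        magnitude_noise_sd=0.0, air_noise_fraction=0.0)
    return generate(cfg)


@pytest.fixture(scope="session")
def nominal_scene():
    """Default noisy scene with ghosting annulus and moderate offset."""
    cfg = PhantomConfig(seed=7, background_coeffs=(1.2, 0.06, -0.05, 0.03, 0.8))
    return generate(cfg)


@pytest.fixture(scope="session")
def offset_free_scene():
    """Noisy scene with zero injected background."""
    cfg = PhantomConfig(seed=13)
    return generate(cfg)
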