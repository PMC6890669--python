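import logging

import numpy as np
import pytest

from tfmkit import (
    ElasticSubstrate,
    NoiseModel,
    generate_traction_pattern,
    random_bead_field,
    render_bead_images,
)

logging.getLogger("tfmkit").setLevel(logging.CRITICAL)


@pytest.fixture(scope="session")
def soft_substrate():
    """3 kPa polyacrylamide-like gel, the soft monolayer condition."""
    return ElasticSubstrate(young_modulus=3000.0, poisson_ratio=0.45)


@pytest.fixture(scope="session")
def stiff_substrate():
    """35 kPa gel, the stiff condition."""
    return ElasticSubstrate(young_modulus=35000.0, poisson_ratio=0.45)


@pytest.fixture(scope="session")
def smooth_pattern():
    """A 64x64 zero-mean monolayer-like traction pattern (Pa)."""
    return generate_traction_pattern(
        shape=(64, 64), spacing=1.6, peak_stress=200.0, correlation_length=8.0, seed=42
    )


@pytest.fixture(scope="session")
def bead_scene():
    """256x256 px noiseless bead reference image + bead field at 0.2 um/px."""
    beads = random_bead_field((256, 256), 0.2, seed=1)
    ref, _ = render_bead_images(beads, None, (256, 256), 0.2)
    return beads, ref


@pytest.fixture(scope="session")
def noise_20db():
    """Shot + read noise at roughly 20 dB SNR for the default bead scene."""
    return NoiseModel(gaussian_sd=4.0, poisson_scale=1.0)
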