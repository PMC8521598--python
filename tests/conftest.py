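import numpy as np
import pytest

import reoct as r

PITCH = 0.4  # µm/pixel
FWHM = 2.1  # µm, magnitude-PSF width


@pytest.fixture(scope="session")
def single_particle_field() -> r.EnFaceField:
    """Noise-free 256x256 plane with one particle at a subpixel position."""
    spec = r.PhantomSpec(particles=[(51.32, 50.87, 1.0)], seed=1)
    return r.synthesize_stack(spec, 1).field(0)


@pytest.fixture(scope="session")
def noise_stack_100() -> r.StackContainer:
    """100 frames of unit-power circular complex Gaussian noise, 256x256."""
    return r.synthesize_noise_stack((256, 256), PITCH, 1.0, 100, seed=2)


@pytest.fixture(scope="session")
def noisy_phantom() -> tuple[r.StackContainer, r.StackContainer]:
    """Standard noisy phantom stack (N=100) with its paired noise stack."""
    spec = r.default_phantom_spec("noise_only", seed=11)
    stack = r.synthesize_stack(spec, 100)
    noise = r.synthesize_noise_stack(
        spec.grid_size, spec.pitch, spec.noise_sigma, 100, seed=12
    )
    return stack, noise


def measure_fwhm(field: r.EnFaceField, upsample: int = 4) -> float:
    """Upsample, detect the brightest particle and fit its FWHM (µm)."""
    up = r.zeropad_upsample(field, upsample)
    centers = r.detect_particles(up, min_distance=30 * upsample)
    m = r.fit_psf(up, centers[0], window_px=73 * upsample)
    assert m.fit_ok
    return m.fwhm_um
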