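import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import reoct as r
from tests.conftest import PITCH

complex_fields = arrays(
    np.complex128,
    (16, 16),
    elements=st.complex_numbers(
        min_magnitude=0, max_magnitude=1e3, allow_nan=False, allow_infinity=False
    ),
)


class TestSpectrum:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(complex_fields)
    def test_parseval_and_round_trip(self, data):
        field = r.EnFaceField(data, PITCH)
        spec = r.to_spectrum(field)
        energy_space = np.sum(field.intensity)
        energy_k = np.sum(spec.power) / data.size
        assert energy_k == pytest.approx(energy_space, rel=1e-10, abs=1e-12)
        back = r.from_spectrum(spec)
        np.testing.assert_allclose(back.data, data, rtol=1e-10, atol=1e-10)

    def test_delta_has_flat_magnitude_spectrum(self):
        data = np.zeros((32, 32), complex)
        data[16, 16] = 1.0
        mag = np.abs(r.to_spectrum(r.EnFaceField(data, PITCH)).values)
        np.testing.assert_allclose(mag, 1.0, rtol=1e-10)

    def test_gaussian_fourier_pair(self):
        # real space-domain Gaussian of std sigma_x -> spectral magnitude
        # Gaussian of std sigma_k = 1/sigma_x (continuous-limit check)
        sigma_x = 2.0
        n = 512
        x = (np.arange(n) - n // 2) * PITCH
        xx, yy = np.meshgrid(x, x)
        field = r.EnFaceField(np.exp(-(xx**2 + yy**2) / (2 * sigma_x**2)), PITCH)
        spec = r.to_spectrum(field)
        prof = r.radial_power_profile(spec, bin_width=0.02)
        prof = prof[(prof["count"] > 0) & (prof["power"] > spec.dc_power() * 1e-6)]
        slope = np.polyfit(prof["kr"] ** 2, np.log(prof["power"]), 1)[0]
        sigma_k = 1.0 / np.sqrt(-slope)
        assert sigma_k == pytest.approx(1.0 / sigma_x, rel=0.01)

    def test_nyquist_kr_of_reference_sampling(self):
        assert r.nyquist_kr(0.4) == pytest.approx(7.85, abs=0.005)


class TestRadialProfile:
    def test_flat_for_white_noise(self, noise_stack_100):
        spec = r.to_spectrum(noise_stack_100.field(0))
        prof = r.radial_power_profile(spec, bin_width=0.5)
        prof = prof[prof["count"] > 100]
        assert prof["power"].max() / prof["power"].min() < 1.3

    def test_signal_plus_noise_plateaus_at_noise_floor(self, noisy_phantom):
        stack, noise = noisy_phantom
        spec = r.to_spectrum(stack.field(0))
        nspec = r.to_spectrum(noise.field(0))
        prof = r.radial_power_profile(spec, bin_width=0.5)
        floor = np.mean(nspec.power)
        outer = prof[prof["kr"] > 6.0]["power"].mean()
        assert outer == pytest.approx(floor, rel=0.1)
        # and the profile decreases from the signal band down to the plateau
        assert prof["power"].iloc[0] > 10 * outer
        assert spec.dc_power() > 100 * outer


class TestDynamicRange:
    def test_equal_powers_give_zero_db(self):
        # noise with constant unit spectral power; signal with unit DC power
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, (64, 64))
        noise = np.fft.ifft2(np.exp(1j * phase))
        signal = np.full((64, 64), 1.0 / 64**2, dtype=complex)  # DC amplitude 1
        dr = r.dynamic_range(r.EnFaceField(signal, PITCH), r.EnFaceField(noise, PITCH))
        assert dr.dr_db == pytest.approx(0.0, abs=1e-9)

    def test_noise_amplitude_x10_costs_20_db(self, noisy_phantom):
        stack, noise = noisy_phantom
        sig = stack.field(0)
        n1 = noise.field(0)
        n10 = r.EnFaceField(10 * n1.data, PITCH)
        assert r.dynamic_range(sig, n1).dr_db - r.dynamic_range(sig, n10).dr_db == (
            pytest.approx(20.0, abs=1e-9)
        )

    def test_global_phase_invariance(self, noisy_phantom):
        stack, noise = noisy_phantom
        sig, noi = stack.field(0), noise.field(0)
        rot = r.EnFaceField(sig.data * np.exp(1j * 1.2), PITCH)
        assert r.dynamic_range(rot, noi).dr_db == pytest.approx(
            r.dynamic_range(sig, noi).dr_db, abs=1e-9
        )

    def test_coherent_average_earns_20_db(self, noisy_phantom):
        stack, noise = noisy_phantom
        dr1 = r.dynamic_range(stack.field(0), noise.field(0)).dr_db
        dr100 = r.dynamic_range(
            r.coherent_average(stack, 100), r.coherent_average(noise, 100)
        ).dr_db
        assert dr100 - dr1 == pytest.approx(20.0, abs=0.5)

    def test_zero_dc_signal_is_degenerate(self):
        zero = r.EnFaceField(np.zeros((16, 16), complex), PITCH)
        ones = r.EnFaceField(np.ones((16, 16), complex), PITCH)
        with pytest.raises(ValueError, match="DC"):
            r.dynamic_range(zero, ones)


class TestPhaseCorrelationLimit:
    def test_noise_free_psf_is_nyquist_limited(self, single_particle_field):
        # particle at (51.32, 50.87) µm -> pixel (127, 128); window centered
        # there sees a flat phase spectrum -> last bin center, 7.85 rad/µm
        limit = r.phase_correlation_limit(single_particle_field, (127, 128))
        assert limit == pytest.approx(7.85, abs=0.05)

    def test_pure_noise_decorrelates_immediately(self, noise_stack_100):
        field = noise_stack_100.field(0)
        limit = r.phase_correlation_limit(field, (127, 127))
        assert limit == pytest.approx(0.05, abs=1e-12)

    def test_invariance_to_global_phase_and_integer_shift(self, single_particle_field):
        base = r.phase_correlation_limit(single_particle_field, (127, 128))
        rot = r.EnFaceField(single_particle_field.data * np.exp(1j * 0.9), PITCH)
        assert r.phase_correlation_limit(rot, (127, 128)) == base
        rolled = r.EnFaceField(np.roll(single_particle_field.data, (3, -2), (0, 1)), PITCH)
        assert r.phase_correlation_limit(rolled, (130, 126)) == base

    def test_limit_non_decreasing_in_n(self):
        spec = r.PhantomSpec(particles=[(51.2, 51.2, 1.0)], noise_sigma=1.6e-3, seed=9)
        stack = r.synthesize_stack(spec, 100)
        limits = [
            r.phase_correlation_limit(r.coherent_average(stack, n), (128, 128))
            for n in (1, 10, 100)
        ]
        assert limits[0] <= limits[1] <= limits[2]
        assert limits[2] > limits[0]  # averaging visibly extends the band

    def test_window_must_fit(self, single_particle_field):
        with pytest.raises(ValueError, match="window"):
            r.phase_correlation_limit(single_particle_field, (10, 10))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            r.PhaseCorrConfig(window=242)
        with pytest.raises(ValueError):
            r.PhaseCorrConfig(threshold=-1.0)
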