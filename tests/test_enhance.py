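import numpy as np
import pytest

import reoct as r
from reoct.enhance import fit_spectrum_model
from reoct.simulate import FWHM_TO_SIGMA
from tests.conftest import PITCH, measure_fwhm

SIGMA_K_TRUE = 1.0 / (2.1 * FWHM_TO_SIGMA)


class TestRefocus:
    def test_zero_defocus_is_identity(self, single_particle_field):
        out = r.refocus(single_particle_field, 0.0, 0.85)
        np.testing.assert_allclose(out.data, single_particle_field.data, atol=1e-10)

    def test_inverse_pair_and_energy(self, single_particle_field):
        fwd = r.refocus(single_particle_field, 25.0, 0.85)
        assert np.sum(fwd.intensity) == pytest.approx(
            np.sum(single_particle_field.intensity), rel=1e-12
        )
        back = r.refocus(fwd, -25.0, 0.85)
        np.testing.assert_allclose(back.data, single_particle_field.data, atol=1e-10)

    def test_restores_defocused_psf_width(self, single_particle_field):
        blurred = r.refocus(single_particle_field, 30.0, 0.85)
        assert measure_fwhm(blurred) > 3.0  # visibly defocused
        sharp = r.refocus(blurred, -30.0, 0.85)
        assert measure_fwhm(sharp) == pytest.approx(2.1, rel=0.02)

    def test_invalid_wavelength(self, single_particle_field):
        with pytest.raises(ValueError):
            r.refocus(single_particle_field, 10.0, 0.0)


class TestSpectrumModelFit:
    def test_recovers_generator_sigma_k(self, single_particle_field):
        model = fit_spectrum_model(single_particle_field)
        assert model.sigma_k == pytest.approx(SIGMA_K_TRUE, rel=0.01)
        assert model.noise_floor_power == 0.0

    def test_noise_floor_scales_as_power(self, noisy_phantom):
        stack, noise = noisy_phantom
        avg = r.coherent_average(stack, 100)
        n1 = noise.field(0)
        m1 = fit_spectrum_model(avg, n1)
        m2 = fit_spectrum_model(avg, r.EnFaceField(2 * n1.data, PITCH))
        assert m2.noise_floor_power == pytest.approx(4 * m1.noise_floor_power, rel=1e-9)

    def test_pure_noise_cannot_be_fitted(self, noise_stack_100):
        field = noise_stack_100.field(0)
        with pytest.raises(ValueError):
            fit_spectrum_model(field, field)


class TestBEMask:
    def test_b1_is_identity_mask(self, single_particle_field):
        model = fit_spectrum_model(single_particle_field)
        mask = r.build_be_mask(model, 1.0, (256, 256), PITCH)
        np.testing.assert_allclose(mask.gain, 1.0)

    def test_dc_gain_is_one_and_radial_symmetry(self, single_particle_field):
        model = fit_spectrum_model(single_particle_field)
        mask = r.build_be_mask(model, 2.0, (256, 256), PITCH)
        assert mask.gain[128, 128] == 1.0
        np.testing.assert_allclose(mask.gain, mask.gain.T)  # square grid symmetry

    def test_closed_form_large_b_limit_at_sigma_k(self):
        model = r.SpectrumModel(
            sigma_k=SIGMA_K_TRUE, dc_amplitude=1.0, noise_floor_power=0.0,
            fit_range=(0, 3),
        )
        b = 1e6
        mask = r.build_be_mask(model, b, (256, 256), PITCH)
        kx = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(256, PITCH))
        gain_interp = np.interp(SIGMA_K_TRUE, kx[128:], mask.gain[128, 128:])
        assert gain_interp == pytest.approx(np.exp(0.5), rel=0.01)

    def test_numeric_cap_is_respected(self):
        model = r.SpectrumModel(
            sigma_k=SIGMA_K_TRUE, dc_amplitude=1.0, noise_floor_power=0.0,
            fit_range=(0, 3),
        )
        mask = r.build_be_mask(model, 2.4, (256, 256), PITCH, max_gain_db=40.0)
        assert mask.gain.max() == pytest.approx(100.0)

    def test_b_below_one_rejected(self):
        model = r.SpectrumModel(1.0, 1.0, 0.0, (0, 1))
        with pytest.raises(ValueError):
            r.build_be_mask(model, 0.5, (64, 64), PITCH)

    def test_b2_mask_halves_noise_free_fwhm(self, single_particle_field):
        model = fit_spectrum_model(single_particle_field)
        mask = r.build_be_mask(model, 2.0, (256, 256), PITCH)
        enhanced = r.apply_be(single_particle_field, mask)
        assert measure_fwhm(enhanced) == pytest.approx(2.1 / 2, rel=0.02)


class TestApplyBE:
    def test_unit_mask_identity(self, single_particle_field):
        mask = r.BEMask(np.ones((256, 256)), 1.0, None, PITCH, PITCH)
        out = r.apply_be(single_particle_field, mask)
        np.testing.assert_allclose(out.data, single_particle_field.data, atol=1e-12)

    def test_white_noise_power_gain_is_mean_gain_squared(self, noise_stack_100):
        model = r.SpectrumModel(SIGMA_K_TRUE, 1.0, 0.0, (0, 3))
        mask = r.build_be_mask(model, 1.3, (256, 256), PITCH)
        field = noise_stack_100.field(0)
        out = r.apply_be(field, mask)
        measured = np.sum(out.intensity) / np.sum(field.intensity)
        # exact in expectation; a single 256^2 realisation fluctuates a bit
        assert measured == pytest.approx(np.mean(mask.gain**2), rel=0.05)

    def test_inverse_mask_round_trip(self, single_particle_field):
        model = fit_spectrum_model(single_particle_field)
        mask = r.build_be_mask(model, 1.8, (256, 256), PITCH)
        inv = r.BEMask(1.0 / mask.gain, 1.8, None, PITCH, PITCH)
        out = r.apply_be(r.apply_be(single_particle_field, mask), inv)
        np.testing.assert_allclose(out.data, single_particle_field.data, atol=1e-8)

    def test_shape_mismatch_rejected(self, single_particle_field):
        mask = r.BEMask(np.ones((64, 64)), 1.0, None, PITCH, PITCH)
        with pytest.raises(ValueError):
            r.apply_be(single_particle_field, mask)


class TestZeropadUpsample:
    def test_factor_one_identity(self, single_particle_field):
        out = r.zeropad_upsample(single_particle_field, 1)
        np.testing.assert_array_equal(out.data, single_particle_field.data)

    def test_band_limited_interpolation_identity(self):
        rng = np.random.default_rng(0)
        spec = np.zeros((64, 64), complex)
        spec[16:48, 16:48] = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        field = r.EnFaceField(np.fft.ifft2(np.fft.ifftshift(spec)), PITCH)
        up = r.zeropad_upsample(field, 3)
        np.testing.assert_allclose(up.data[::3, ::3], field.data, atol=1e-9)
        assert up.pitch_x == pytest.approx(PITCH / 3)

    def test_fwhm_converges_in_upsample_factor(self, single_particle_field):
        f2 = measure_fwhm(single_particle_field, upsample=2)
        f4 = measure_fwhm(single_particle_field, upsample=4)
        assert abs(f4 - f2) / f4 < 0.01


class TestNoiseFreeEfficiency:
    def test_re_factor_tracks_be_factor_up_to_nyquist(self, single_particle_field):
        """Noise-free limit: RE/BE efficiency within 5% of 1 for every b."""
        model = fit_spectrum_model(single_particle_field)
        baseline = measure_fwhm(single_particle_field)
        for b in (1.2, 1.6, 2.0, 2.4):
            mask = r.build_be_mask(model, b, (256, 256), PITCH)
            enhanced = r.apply_be(single_particle_field, mask)
            eff = (baseline / measure_fwhm(enhanced)) / b
            assert eff == pytest.approx(1.0, abs=0.05), f"b={b}"
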