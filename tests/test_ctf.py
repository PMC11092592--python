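"""CTF model, tilt-compensated power spectra, defocus fitting, handedness,
and strip phase-flip correction."""

import math
from dataclasses import replace

import numpy as np
import pytest

from tomokit.ctf import (
    CtfParams,
    TiltGeometry,
    ctf_modulate,
    ctf_value,
    determine_handedness,
    electron_wavelength,
    fit_defocus,
    phase_flip_correct,
    tile_defocus_offset,
    tilt_compensated_ps,
)
from tomokit.synthetic import simulate_ctf_micrograph


class TestWavelength:
    def test_known_values(self):
        # closed form evaluated independently
        assert electron_wavelength(300) == pytest.approx(0.019687, abs=2e-5)
        assert electron_wavelength(100) == pytest.approx(0.037013, abs=2e-5)

    def test_decreases_with_voltage(self):
        volts = [80, 120, 200, 300]
        lams = [electron_wavelength(v) for v in volts]
        assert np.all(np.diff(lams) < 0)


class TestCtfValue:
    def test_zero_frequency_gives_minus_amplitude_contrast(self, ctf_params):
        p = replace(ctf_params, defocus=20000.0)
        assert ctf_value(0.0, p) == pytest.approx(-p.amplitude_contrast)

    def test_first_zero_at_analytic_position(self):
        # w=0, Cs=0, phase=0: chi = pi*lambda*g^2*dz hits pi at g=1/sqrt(lam*dz)
        p = CtfParams(
            voltage=300, cs=0.0, amplitude_contrast=0.0, pixel_size=1.0,
            defocus=20000.0,
        )
        g_zero = 1.0 / math.sqrt(p.wavelength * p.defocus)
        assert abs(ctf_value(g_zero, p)) < 1e-10
        # strictly nonzero just inside
        assert abs(ctf_value(0.95 * g_zero, p)) > 0.1

    def test_bounded_by_one(self, ctf_params):
        p = replace(ctf_params, defocus=30000.0)
        g = np.linspace(0, 0.25, 1000)
        assert np.all(np.abs(ctf_value(g, p)) <= 1.0 + 1e-12)


class TestDefocusGradientGeometry:
    def test_tan_45_gives_distance(self):
        geom = TiltGeometry(tilt_angle=45.0, center=(0.0, 0.0))
        dz = tile_defocus_offset((1000.0, 0.0), geom, pixel_size=1.0)
        assert dz == pytest.approx(1000.0)

    def test_zero_tilt_means_zero_offset(self):
        geom = TiltGeometry(tilt_angle=0.0, center=(0.0, 0.0))
        for x in (-500, 0, 700):
            assert tile_defocus_offset((x, 0.0), geom, pixel_size=2.0) == 0.0

    def test_odd_in_handedness_theta_and_linear_in_distance(self):
        base = dict(tilt_axis_angle=0.0, center=(0.0, 0.0))
        g_pos = TiltGeometry(tilt_angle=30.0, handedness=1, **base)
        g_neg = TiltGeometry(tilt_angle=30.0, handedness=-1, **base)
        g_mirror = TiltGeometry(tilt_angle=-30.0, handedness=1, **base)
        dz = tile_defocus_offset((200.0, 0.0), g_pos, 1.0)
        assert tile_defocus_offset((200.0, 0.0), g_neg, 1.0) == -dz
        assert tile_defocus_offset((200.0, 0.0), g_mirror, 1.0) == -dz
        assert tile_defocus_offset((400.0, 0.0), g_pos, 1.0) == pytest.approx(2 * dz)

    def test_axis_angle_rotates_gradient_direction(self):
        # axis along x (psi=90): defocus varies along y, not x
        geom = TiltGeometry(tilt_angle=45.0, tilt_axis_angle=90.0, center=(0, 0))
        assert tile_defocus_offset((500.0, 0.0), geom, 1.0) == pytest.approx(
            0.0, abs=1e-9
        )
        assert tile_defocus_offset((0.0, 500.0), geom, 1.0) == pytest.approx(500.0)


@pytest.fixture()
def tilted_params():
    return CtfParams(
        voltage=300.0, cs=2.7, amplitude_contrast=0.07, pixel_size=3.0,
        defocus=25000.0,
    )


class TestTiltCompensatedPs:
    def test_zero_tilt_equals_plain_tile_average(self, tilted_params, rng):
        image = rng.normal(size=(256, 256))
        geom = TiltGeometry(tilt_angle=0.0)
        ps = tilt_compensated_ps(image, geom, tilted_params, tile=128)
        # independent plain average over the same tile grid
        acc = np.zeros((128, 128))
        count = 0
        for oy in (0, 64, 128):
            for ox in (0, 64, 128):
                patch = image[oy : oy + 128, ox : ox + 128]
                acc += np.abs(np.fft.fftshift(np.fft.fft2(patch - patch.mean()))) ** 2
                count += 1
        assert np.allclose(ps, acc / count)

    def test_nonpositive_tile_defocus_rejected(self, tilted_params):
        geom = TiltGeometry(tilt_angle=60.0)
        with pytest.raises(ValueError, match="non-positive defocus"):
            tilt_compensated_ps(
                np.zeros((512, 512)), geom, tilted_params, tile=128,
                defocus_ref=100.0,
            )

    def test_compensation_restores_ring_positions(self, tilted_params):
        """Rings of a 45-deg-tilted simulation must land where an untilted
        simulation at the same axis defocus puts them (within one Fourier px)."""
        from tomokit.ctf import radial_average

        p = tilted_params
        geom = TiltGeometry(tilt_angle=45.0, handedness=1)
        tilted = simulate_ctf_micrograph(
            (1024, 1024), p, geom=geom, seed=3, strip_width=32, noise_floor=0.0
        )
        untilted = simulate_ctf_micrograph(
            (1024, 1024), p, geom=None, seed=3, noise_floor=0.0
        )
        ps_comp = tilt_compensated_ps(tilted, geom, p, tile=256)
        ps_flat = tilt_compensated_ps(
            untilted, TiltGeometry(tilt_angle=0.0), p, tile=256
        )
        prof_comp = radial_average(ps_comp)
        prof_flat = radial_average(ps_flat)
        # compare first-minimum position (most sensitive single feature)
        lo, hi = 10, 60
        m1 = lo + np.argmin(prof_comp[lo:hi])
        m2 = lo + np.argmin(prof_flat[lo:hi])
        assert abs(int(m1) - int(m2)) <= 1


class TestFitDefocus:
    def test_noiseless_recovery_within_half_micron_tenth(self, ctf_params):
        p = replace(ctf_params, defocus=25000.0)
        img = simulate_ctf_micrograph((512, 512), p, seed=0, noise_floor=0.0)
        ps = tilt_compensated_ps(
            img, TiltGeometry(tilt_angle=0.0), p, tile=256, defocus_ref=25000.0
        )
        res = fit_defocus(
            ps, ctf_params, search_range=(15000, 40000), search_step=200
        )
        assert abs(res.defocus - 25000.0) <= 500.0
        assert res.score > 0.5

    def test_identifiability_of_distinct_defoci(self, ctf_params):
        fits = []
        for dz in (20000.0, 30000.0):
            p = replace(ctf_params, defocus=dz)
            img = simulate_ctf_micrograph((512, 512), p, seed=1)
            ps = tilt_compensated_ps(
                img, TiltGeometry(tilt_angle=0.0), p, tile=256, defocus_ref=dz
            )
            fits.append(
                fit_defocus(
                    ps, ctf_params, search_range=(15000, 40000), search_step=200
                ).defocus
            )
        assert fits[0] < 25000.0 < fits[1]

    def test_pure_noise_scores_low(self, ctf_params):
        rng = np.random.default_rng(314)
        scores = []
        for _ in range(5):
            img = rng.normal(size=(512, 512))
            ps = tilt_compensated_ps(
                img, TiltGeometry(tilt_angle=0.0), ctf_params, tile=256,
                defocus_ref=25000.0,
            )
            scores.append(
                fit_defocus(
                    ps, ctf_params, search_range=(15000, 40000), search_step=500
                ).score
            )
        assert np.median(np.abs(scores)) < 0.2

    def test_flat_spectrum_flagged(self, ctf_params):
        res = fit_defocus(
            np.ones((256, 256)), ctf_params, search_range=(15000, 40000)
        )
        assert res.flagged
        assert res.score == 0.0

    def test_empty_fit_band_rejected(self, ctf_params):
        with pytest.raises(ValueError, match="beyond Nyquist|too few"):
            fit_defocus(
                np.ones((256, 256)), ctf_params, fit_range=(0.4, 0.5)
            )


class TestHandedness:
    @pytest.mark.parametrize("true_hand", [1, -1])
    def test_recovers_programmed_sign(self, tilted_params, true_hand):
        p = tilted_params
        geom = TiltGeometry(tilt_angle=45.0, handedness=true_hand)
        img = simulate_ctf_micrograph((1024, 1024), p, geom=geom, seed=17,
                                      strip_width=32)
        result = determine_handedness(
            [img], [TiltGeometry(tilt_angle=45.0, handedness=1)], p,
            tile=256, defocus_ref=25000.0,
            search_range=(15000, 40000), search_step=200,
        )
        assert result.handedness == true_hand

    def test_untilted_input_rejected(self, tilted_params):
        with pytest.raises(ValueError, match="tilt"):
            determine_handedness(
                [np.zeros((64, 64))], [TiltGeometry(tilt_angle=0.0)],
                tilted_params,
            )


class TestPhaseFlip:
    def test_involution_at_zero_tilt(self, tilted_params, rng):
        image = rng.normal(size=(128, 128))
        geom = TiltGeometry(tilt_angle=0.0)
        twice = phase_flip_correct(
            phase_flip_correct(image, geom, tilted_params, strip_width=32),
            geom, tilted_params, strip_width=32,
        )
        assert np.abs(twice - image).max() / np.abs(image).max() < 1e-12

    def test_zero_tilt_equals_whole_image_flip(self, tilted_params, rng):
        image = rng.normal(size=(128, 128))
        geom = TiltGeometry(tilt_angle=0.0)
        out = phase_flip_correct(image, geom, tilted_params, strip_width=32)
        fy = np.fft.fftfreq(128, d=tilted_params.pixel_size)[:, None]
        fx = np.fft.rfftfreq(128, d=tilted_params.pixel_size)[None, :]
        sign = np.sign(ctf_value(np.hypot(fy, fx), tilted_params))
        sign[sign == 0] = 1.0
        expected = np.fft.irfft2(np.fft.rfft2(image) * sign, s=image.shape)
        assert np.abs(out - expected).max() < 1e-10

    def test_correction_improves_agreement_with_truth(self, tilted_params):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(2)
        truth = gaussian_filter(rng.normal(size=(256, 256)), 1.5)
        geom = TiltGeometry(tilt_angle=45.0)
        modulated = ctf_modulate(truth, geom, tilted_params, strip_width=32)
        corrected = phase_flip_correct(modulated, geom, tilted_params,
                                       strip_width=32)
        ncc_before = np.corrcoef(modulated.ravel(), truth.ravel())[0, 1]
        ncc_after = np.corrcoef(corrected.ravel(), truth.ravel())[0, 1]
        assert ncc_after > ncc_before

    def test_narrow_strip_rejected(self, tilted_params):
        with pytest.raises(ValueError, match="16"):
            phase_flip_correct(
                np.zeros((64, 64)), TiltGeometry(tilt_angle=0.0),
                tilted_params, strip_width=8,
            )

    def test_unfitted_defocus_rejected(self, ctf_params):
        with pytest.raises(ValueError, match="positive defocus"):
            phase_flip_correct(
                np.zeros((64, 64)), TiltGeometry(tilt_angle=0.0), ctf_params
            )
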