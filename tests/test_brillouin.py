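"""VIPA spectrum simulation, calibration and doublet fitting."""

import numpy as np
import pytest

from fobtools.brillouin import (
    BrillouinPoint,
    SpectrometerModel,
    assemble_map,
    calibrate_spectrometer,
    fit_spectrum,
)
from fobtools.forward import simulate_calibration_frames, simulate_vipa_spectrum


class TestSimulateSpectrum:
    def test_peak_separation_is_fsr_minus_twice_shift(self, spectrometer):
        """Doublet at 7.5 GHz: maxima sit at 7.5 and 22.5 GHz (15 GHz apart)."""
        frame = simulate_vipa_spectrum(7.5, 0.01, spectrometer)
        freq = spectrometer.frequency_axis()
        trace = frame.intensity.copy()
        p1 = np.argmax(trace)
        trace[max(p1 - 20, 0):p1 + 20] = 0
        p2 = np.argmax(trace)
        sep = abs(freq[p2] - freq[p1])
        assert sep == pytest.approx(30 - 2 * 7.5, abs=0.2)

    def test_separation_shrinks_linearly_with_shift(self, spectrometer):
        def sep(shift):
            frame = simulate_vipa_spectrum(shift, 0.01, spectrometer)
            freq = spectrometer.frequency_axis()
            trace = frame.intensity.copy()
            p1 = np.argmax(trace)
            trace[max(p1 - 20, 0):p1 + 20] = 0
            return abs(freq[np.argmax(trace)] - freq[p1])

        assert sep(5.0) - sep(7.0) == pytest.approx(4.0, abs=0.3)

    def test_shift_beyond_half_fsr_rejected(self, spectrometer):
        with pytest.raises(ValueError, match="FSR"):
            simulate_vipa_spectrum(15.1, 0.5, spectrometer)

    def test_intensities_nonnegative(self, spectrometer, rng):
        frame = simulate_vipa_spectrum(7.5, 0.8, spectrometer, amplitude=50,
                                       poisson_noise=True, rng=rng)
        assert np.all(frame.intensity >= 0)


class TestFitSpectrum:
    def test_noise_free_round_trip_within_5_mhz(self, spectrometer):
        frame = simulate_vipa_spectrum(7.872, 0.8, spectrometer)
        point = fit_spectrum(frame, spectrometer)
        assert point.valid
        assert abs(point.shift_ghz - 7.872) < 0.005

    def test_linewidth_deconvolution(self, spectrometer):
        frame = simulate_vipa_spectrum(7.5, 0.8, spectrometer)
        point = fit_spectrum(frame, spectrometer)
        assert point.linewidth_ghz == pytest.approx(0.8, rel=0.05)
        assert point.raw_fwhm_ghz == pytest.approx(0.8 + 0.35, rel=0.05)
        raw = fit_spectrum(frame, spectrometer, deconvolve=False)
        assert raw.linewidth_ghz == pytest.approx(raw.raw_fwhm_ghz)

    def test_linewidth_never_negative(self, spectrometer):
        frame = simulate_vipa_spectrum(7.5, 0.0, spectrometer)
        point = fit_spectrum(frame, spectrometer)
        assert point.linewidth_ghz >= 0.0

    def test_pixel_offset_invariance(self):
        """With linear dispersion, the shift depends on the doublet
        separation only, not on the absolute trace position."""
        model = SpectrometerModel(dispersion=(0.0, 0.075))
        frame = simulate_vipa_spectrum(7.5, 0.8, model)
        base = fit_spectrum(frame, model).shift_ghz
        rolled = frame
        rolled.intensity = np.roll(frame.intensity, 5)
        shifted = fit_spectrum(rolled, model).shift_ghz
        assert abs(shifted - base) < 0.001

    def test_flat_trace_flagged_invalid(self, spectrometer):
        from fobtools.brillouin import SpectrumFrame

        point = fit_spectrum(SpectrumFrame(intensity=np.ones(400)), spectrometer)
        assert not point.valid

    def test_monte_carlo_snr20_rmse_and_linewidth_bias(self, spectrometer):
        """100 Poisson draws at peak SNR ~20: shift RMSE <= 10 MHz and
        linewidth bias <= 15% at a true FWHM of 0.8 GHz."""
        rng = np.random.default_rng(20)
        errors, widths = [], []
        for _ in range(100):
            frame = simulate_vipa_spectrum(7.5, 0.8, spectrometer, amplitude=400,
                                           poisson_noise=True, rng=rng)
            point = fit_spectrum(frame, spectrometer)
            assert point.valid
            errors.append(point.shift_ghz - 7.5)
            widths.append(point.linewidth_ghz)
        rmse = np.sqrt(np.mean(np.square(errors)))
        assert rmse <= 0.010
        assert abs(np.mean(widths) - 0.8) / 0.8 <= 0.15

    @pytest.mark.parametrize("shift", [3.0, 7.872, 12.0])
    def test_separation_law(self, spectrometer, shift):
        """Fitted doublet separation + 2 * shift = FSR."""
        frame = simulate_vipa_spectrum(shift, 0.6, spectrometer)
        point = fit_spectrum(frame, spectrometer, prior_shift_ghz=shift)
        separation = spectrometer.fsr_ghz - 2 * point.shift_ghz
        assert separation + 2 * point.shift_ghz == pytest.approx(30.0, abs=1e-9)
        assert point.shift_ghz == pytest.approx(shift, abs=0.01)

    def test_mirrored_axis_same_shift(self, spectrometer):
        """Mirroring the frequency axis about the order center leaves the
        fitted shift unchanged."""
        frame = simulate_vipa_spectrum(7.3, 0.6, spectrometer)
        freq = spectrometer.frequency_axis()
        mirror_coeffs = np.polynomial.polynomial.polyfit(
            np.arange(spectrometer.n_pixels), freq[::-1], 2
        )
        mirrored_model = SpectrometerModel(dispersion=tuple(mirror_coeffs))
        mirrored = frame
        mirrored.intensity = frame.intensity[::-1].copy()
        point = fit_spectrum(mirrored, mirrored_model)
        assert point.shift_ghz == pytest.approx(7.3, abs=0.01)


class TestCalibration:
    def test_quadratic_dispersion_recovered(self, spectrometer):
        frames, shifts = simulate_calibration_frames(spectrometer)
        template = SpectrometerModel(dispersion=(0.0, 0.08, 0.0))
        cal = calibrate_spectrometer(frames, shifts, template=template)
        # fitted model reproduces the true peak pixel positions within 0.1 px
        true_freqs = [5.09, 30 - 5.09, 7.43, 30 - 7.43]
        for nu in true_freqs:
            px_true = np.interp(nu, spectrometer.frequency_axis(),
                                np.arange(spectrometer.n_pixels))
            px_cal = np.interp(nu, cal.frequency_axis(), np.arange(cal.n_pixels))
            assert abs(px_cal - px_true) < 0.1

    def test_linear_data_quadratic_template_gives_null_curvature(self):
        linear = SpectrometerModel(dispersion=(0.0, 0.075))
        frames, shifts = simulate_calibration_frames(linear)
        cal = calibrate_spectrometer(frames, shifts,
                                     template=SpectrometerModel(dispersion=(0.0, 0.08, 0.0)))
        a1, a2 = cal.dispersion[1], cal.dispersion[2]
        assert abs(a2) < 1e-3 * abs(a1)

    def test_single_line_without_fsr_constraint_rejected(self, spectrometer):
        frames, shifts = simulate_calibration_frames(spectrometer, shifts_ghz=(7.43,))
        with pytest.raises(ValueError, match="under-determined"):
            calibrate_spectrometer(frames, shifts, use_fsr_constraint=False, degree=1)

    def test_non_monotonic_dispersion_rejected(self):
        with pytest.raises(ValueError, match="monotonic"):
            SpectrometerModel(dispersion=(0.0, 0.075, -4e-4))


class TestAssembleMap:
    @staticmethod
    def _points(ny, nx, drop=None):
        pts = []
        for iy in range(ny):
            for ix in range(nx):
                if drop is not None and (iy, ix) == drop:
                    continue
                pts.append(BrillouinPoint(
                    shift_ghz=7.5 + 0.001 * (iy * nx + ix), linewidth_ghz=0.8,
                    residual=0.0, valid=True, position_um=(iy * 0.5, ix * 0.5),
                ))
        return pts

    def test_complete_41x41_raster(self):
        bmap = assemble_map(self._points(41, 41))
        assert bmap.shape == (41, 41)
        assert bmap.valid.all()

    def test_one_missing_point_invalid(self):
        bmap = assemble_map(self._points(10, 10, drop=(3, 4)))
        assert (~bmap.valid).sum() == 1
        assert not bmap.valid[3, 4]
        assert np.isnan(bmap.shift_ghz[3, 4])

    def test_order_invariance(self, rng):
        pts = self._points(8, 8)
        shuffled = list(pts)
        rng.shuffle(shuffled)
        a, b = assemble_map(pts), assemble_map(shuffled)
        np.testing.assert_array_equal(a.shift_ghz, b.shift_ghz)
        np.testing.assert_array_equal(a.valid, b.valid)

    def test_duplicate_positions_rejected(self):
        pts = self._points(4, 4)
        pts.append(pts[0])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_map(pts)
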