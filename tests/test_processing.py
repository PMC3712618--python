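"""Processing-chain tests: zero-fill, apodization, FFT conventions, phasing,
baseline correction, and processing-log replay."""

import numpy as np
import pytest

import satflux as sf
from satflux.errors import ValidationError
from satflux.processing import inverse_fourier_transform

from conftest import numerical_fwhm


def spectral_integral(spec):
    df_hz = np.diff(spec.ppm_axis).mean() * spec.spectrometer_freq_mhz
    return spec.intensities.sum() * df_hz


class TestZeroFill:
    def test_pads_with_exact_zeros(self, single_lorentzian_config):
        fid = sf.simulate_fid(single_lorentzian_config)
        out = sf.zero_fill(fid, 8000)
        assert out.n_points == 8000
        assert np.array_equal(out.points[:4000], fid.points)
        assert np.all(out.points[4000:] == 0)

    def test_target_equal_to_length_is_identity(self, single_lorentzian_config):
        fid = sf.simulate_fid(single_lorentzian_config)
        assert np.array_equal(sf.zero_fill(fid, fid.n_points).points, fid.points)

    def test_smaller_target_rejected(self, single_lorentzian_config):
        with pytest.raises(ValidationError):
            sf.zero_fill(sf.simulate_fid(single_lorentzian_config), 2000)

    def test_integral_preserved(self, single_lorentzian_config):
        fid = sf.simulate_fid(single_lorentzian_config)
        before = spectral_integral(sf.fourier_transform(fid))
        after = spectral_integral(sf.fourier_transform(sf.zero_fill(fid, 8000)))
        assert after == pytest.approx(before, rel=1e-3)


class TestApodization:
    def test_lb_zero_is_identity_and_first_point_unchanged(self, single_lorentzian_config):
        fid = sf.simulate_fid(single_lorentzian_config)
        assert np.array_equal(sf.apodize_exponential(fid, 0.0).points, fid.points)
        assert sf.apodize_exponential(fid, 30.0).points[0] == fid.points[0]

    def test_negative_lb_rejected(self, single_lorentzian_config):
        with pytest.raises(ValidationError):
            sf.apodize_exponential(sf.simulate_fid(single_lorentzian_config), -1.0)

    def test_lorentzian_widths_add(self, single_lorentzian_config):
        fid = sf.simulate_fid(single_lorentzian_config)  # FWHM 20 Hz
        spec = sf.fourier_transform(sf.apodize_exponential(fid, 30.0))
        w = numerical_fwhm(spec.ppm_axis, spec.intensities, spec.spectrometer_freq_mhz)
        assert w == pytest.approx(50.0, rel=0.02)


class TestFourierTransform:
    def test_pure_exponential_gives_single_bin_maximum(self):
        n, dwell = 1024, 1e-4
        f0 = 75.0 / (n * dwell)  # exactly on the frequency grid
        t = np.arange(n) * dwell
        fid = sf.FID(np.exp(2j * np.pi * f0 * t), dwell, 162.1)
        spec = sf.fourier_transform(fid)
        freqs = spec.ppm_axis * 162.1
        assert freqs[np.argmax(np.abs(spec.values))] == pytest.approx(f0, abs=1e-6)

    def test_round_trip_recovers_fid(self, muscle_config):
        fid = sf.simulate_fid(muscle_config)
        back = inverse_fourier_transform(sf.fourier_transform(fid))
        assert np.allclose(back.points, fid.points, rtol=1e-10, atol=1e-12)

    def test_parseval_identity(self, muscle_config):
        fid = sf.simulate_fid(muscle_config)
        spec = sf.fourier_transform(fid)
        data = fid.points.copy()
        data[0] *= 0.5
        lhs = np.sum(np.abs(data) ** 2) * fid.dwell_time
        df = 1.0 / (fid.n_points * fid.dwell_time)
        rhs = np.sum(np.abs(spec.values) ** 2) * df
        assert rhs == pytest.approx(lhs, rel=1e-9)

    def test_simulated_pi_peak_lands_at_its_shift(self, muscle_config):
        spec = sf.fourier_transform(sf.simulate_fid(muscle_config))
        sel = np.abs(spec.ppm_axis - 4.9) < 1.0
        peak_ppm = spec.ppm_axis[sel][np.argmax(spec.intensities[sel])]
        assert peak_ppm == pytest.approx(4.9, abs=np.diff(spec.ppm_axis).mean())


class TestPhasing:
    def test_zero_angles_are_identity(self, muscle_config):
        spec = sf.fourier_transform(sf.simulate_fid(muscle_config))
        out = sf.phase_correct(spec, 0.0, 0.0)
        assert np.array_equal(out.values, spec.values)

    def test_magnitude_preserved_exactly(self, muscle_config):
        spec = sf.fourier_transform(sf.simulate_fid(muscle_config))
        out = sf.phase_correct(spec, 123.0, 4.5, pivot_ppm=1.0)
        assert np.allclose(np.abs(out.values), np.abs(spec.values), rtol=1e-12)

    def test_auto_phase_recovers_known_rotation(self, muscle_config):
        spec = sf.fourier_transform(
            sf.apodize_exponential(sf.simulate_fid(muscle_config), 10.0)
        )
        rotated = sf.phase_correct(spec, 37.0)
        _, phi0, _ = sf.auto_phase(rotated)
        assert phi0 == pytest.approx(-37.0, abs=1.0)


class TestBaseline:
    WINDOWS = [(c - 1.2, c + 1.2) for c in sf.DEFAULT_SHIFTS_PPM.values()]

    def test_flat_offset_removed(self, muscle_config):
        spec = sf.fourier_transform(sf.simulate_fid(muscle_config))
        c = 5.0
        shifted = spec.copy()
        shifted.values = shifted.values + c
        out = sf.baseline_correct(shifted, self.WINDOWS)
        signal_free = np.ones(spec.ppm_axis.size, bool)
        for lo, hi in self.WINDOWS:
            signal_free &= ~((spec.ppm_axis >= lo) & (spec.ppm_axis <= hi))
        assert np.abs(
            out.intensities[signal_free] - spec.intensities[signal_free]
        ).max() < 0.01 * c

    def test_zero_baseline_input_unchanged(self, muscle_config):
        spec = sf.fourier_transform(sf.simulate_fid(muscle_config))
        out = sf.baseline_correct(spec, self.WINDOWS)
        assert np.abs(out.intensities - spec.intensities).max() < 2e-3 * np.max(
            spec.intensities
        )

    def test_windows_covering_axis_rejected(self, muscle_config):
        spec = sf.fourier_transform(sf.simulate_fid(muscle_config))
        with pytest.raises(ValidationError):
            sf.baseline_correct(spec, [(spec.ppm_axis.min(), spec.ppm_axis.max())])

    def test_slow_sinusoid_baseline_leaves_peak_areas_intact(self, muscle_config):
        from satflux.fitting import fit_peaks, initial_guesses

        spec = sf.fourier_transform(
            sf.apodize_exponential(sf.simulate_fid(muscle_config), 10.0)
        )
        dirty = spec.copy()
        dirty.values = dirty.values + 0.3 * np.sin(
            2 * np.pi * dirty.ppm_axis / 80.0
        )
        cleaned = sf.baseline_correct(dirty, self.WINDOWS, degree=6)
        fit = fit_peaks(cleaned, initial_guesses(cleaned, default_fwhm_hz=25.0))
        for p in muscle_config.peaks:
            truth = sf.peak_area(
                sf.PeakModel(
                    p.label,
                    p.center_ppm,
                    p.amplitude * p.fwhm_hz / (p.fwhm_hz + 10.0),
                    p.fwhm_hz + 10.0,
                )
            )
            assert fit.area(p.label) == pytest.approx(truth, rel=0.02)


class TestProcessingLog:
    def test_replay_reproduces_spectrum_bit_for_bit(self, muscle_config):
        fid = sf.simulate_fid(muscle_config)
        spec = sf.process_fid(
            fid,
            zerofill_points=8000,
            line_broadening_hz=30.0,
            phase_mode="auto",
            baseline_windows=TestBaseline.WINDOWS,
        )
        replayed = sf.replay_log(fid, spec.processing_log)
        assert np.array_equal(replayed.values, spec.values)
        assert np.array_equal(replayed.ppm_axis, spec.ppm_axis)

    def test_zero_fill_and_apodize_commute(self, muscle_config):
        fid = sf.simulate_fid(muscle_config)
        a = sf.apodize_exponential(sf.zero_fill(fid, 8000), 30.0)
        b = sf.zero_fill(sf.apodize_exponential(fid, 30.0), 8000)
        assert np.allclose(a.points, b.points, rtol=1e-12, atol=1e-300)
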