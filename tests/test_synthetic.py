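"""Generator tests: lineshapes, exchange steady state, inversion recovery,
expression truth, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import satflux as sf
from satflux.errors import ConfigurationError, ValidationError

from conftest import numerical_fwhm


class TestFidSimulation:
    def test_single_peak_transform_peaks_at_center(self, single_lorentzian_config):
        spec = sf.fourier_transform(sf.simulate_fid(single_lorentzian_config))
        assert spec.ppm_axis[np.argmax(spec.intensities)] == pytest.approx(
            4.9, abs=np.diff(spec.ppm_axis).mean()
        )

    def test_same_seed_is_bit_identical(self, control_exchange_config):
        import dataclasses

        cfg = dataclasses.replace(control_exchange_config, noise_sd=0.3, seed=7)
        a1, s1 = sf.simulate_saturation_pair(cfg)
        a2, s2 = sf.simulate_saturation_pair(cfg)
        assert np.array_equal(a1.points, a2.points)
        assert np.array_equal(s1.points, s2.points)
        assert not np.array_equal(
            a1.points, sf.simulate_saturation_pair(dataclasses.replace(cfg, seed=8))[0].points
        )

    def test_lorentzian_width_matches_config(self, single_lorentzian_config):
        # zero-fill for a fine frequency grid before measuring the width
        fid = sf.zero_fill(sf.simulate_fid(single_lorentzian_config), 16000)
        spec = sf.fourier_transform(fid)
        w = numerical_fwhm(spec.ppm_axis, spec.intensities, spec.spectrometer_freq_mhz)
        assert w == pytest.approx(20.0, rel=0.01)

    def test_spectral_integral_conserves_configured_areas(self, muscle_config):
        spec = sf.fourier_transform(sf.simulate_fid(muscle_config))
        df_hz = np.diff(spec.ppm_axis).mean() * spec.spectrometer_freq_mhz
        integral = spec.intensities.sum() * df_hz
        expected = sum(
            sf.peak_area(sf.PeakModel(p.label, p.center_ppm, p.amplitude, p.fwhm_hz, p.gauss_fraction))
            for p in muscle_config.peaks
        )
        assert integral == pytest.approx(expected, rel=0.005)

    def test_invalid_config_names_offending_field(self):
        with pytest.raises(ValidationError, match="fwhm_hz"):
            sf.PeakSpec("Pi", 4.9, 1.0, -3.0)
        with pytest.raises(ValidationError, match="n_points"):
            sf.SimulationConfig(n_points=1)
        with pytest.raises(ValidationError, match="labels"):
            sf.SimulationConfig(
                peaks=(sf.PeakSpec("Pi", 4.9, 1.0, 10.0), sf.PeakSpec("Pi", 5.0, 1.0, 10.0))
            )


class TestSaturationPair:
    def test_no_exchange_means_no_effect(self):
        base = {p.label: p for p in sf.default_muscle_peaks()}
        cfg = sf.SimulationConfig(
            exchange={"Pi": sf.ExchangeSpec(m0=base["Pi"].amplitude, t1_intrinsic=2.0, kf=0.0)}
        )
        control, saturated = sf.simulate_saturation_pair(cfg)
        from satflux.fitting import fit_peaks, initial_guesses

        c = sf.process_fid(control, None, 0.0, phase_mode="none")
        s = sf.process_fid(saturated, None, 0.0, phase_mode="none")
        cf = fit_peaks(c, initial_guesses(c, default_fwhm_hz=20.0))
        sfit = fit_peaks(s, initial_guesses(s, default_fwhm_hz=20.0))
        assert sf.compute_dm_over_m0(cf, sfit, "Pi") == pytest.approx(0.0, abs=1e-4)

    def test_two_site_steady_state_value(self):
        ex = sf.ExchangeSpec(m0=1.0, t1_intrinsic=2.0, kf=0.2)
        assert ex.dm_over_m0 == pytest.approx(0.2 / (0.5 + 0.2), abs=1e-12)

    def test_saturated_amplitude_is_steady_state_and_gamma_removed(self):
        base = {p.label: p for p in sf.default_muscle_peaks()}
        ex = sf.ExchangeSpec.from_observed(m0=base["Pi"].amplitude, t1obs=1.59, kf=0.304)
        cfg = sf.SimulationConfig(exchange={"Pi": ex})
        control, saturated = sf.simulate_saturation_pair(cfg)
        c, s = sf.fourier_transform(control), sf.fourier_transform(saturated)
        pi = np.abs(c.ppm_axis - 4.9) < 0.3
        gamma = np.abs(c.ppm_axis + 2.4) < 0.3
        ratio = np.max(s.intensities[pi]) / np.max(c.intensities[pi])
        assert ratio == pytest.approx(1.0 - ex.dm_over_m0, rel=1e-3)
        assert np.max(s.intensities[gamma]) < 0.02 * np.max(c.intensities[gamma])

    def test_missing_exchange_is_configuration_error(self, muscle_config):
        with pytest.raises(ConfigurationError):
            sf.simulate_saturation_pair(muscle_config)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        kf=st.floats(0.0, 5.0, allow_nan=False),
        t1=st.floats(0.05, 10.0, allow_nan=False),
    )
    def test_dm_over_m0_closed_form_and_range(self, kf, t1):
        ex = sf.ExchangeSpec(m0=1.0, t1_intrinsic=t1, kf=kf)
        assert ex.dm_over_m0 == pytest.approx(kf / (kf + 1.0 / t1), rel=1e-12)
        assert 0.0 <= ex.dm_over_m0 < 1.0


class TestInversionRecovery:
    def test_long_time_limit_is_a1_and_null_point(self, control_exchange_config):
        ex = control_exchange_config.exchange["Pi"]
        t_null = ex.t1obs * np.log(2.0)
        series = sf.simulate_inversion_recovery(
            control_exchange_config, [t_null, 2 * t_null, 3 * t_null, 60.0]
        )["Pi"]
        a1 = ex.m0 * ex.saturation_factor
        assert series.magnetizations[-1] == pytest.approx(a1, rel=1e-9)
        assert abs(series.magnetizations[0]) < 1e-9 * a1

    def test_empty_or_invalid_times_rejected(self, control_exchange_config):
        with pytest.raises(ValidationError):
            sf.simulate_inversion_recovery(control_exchange_config, [])
        with pytest.raises(ValidationError):
            sf.simulate_inversion_recovery(control_exchange_config, [0.0, 1.0, 2.0, 3.0])


class TestExpressionSimulation:
    def test_shapes_truth_and_determinism(self):
        spec = sf.ExpressionSimSpec(seed=11)
        a = sf.simulate_expression_dataset(spec)
        b = sf.simulate_expression_dataset(spec)
        assert a.matrix.values.shape == (spec.n_probesets, 2 * spec.samples_per_group)
        assert (a.matrix.values.to_numpy() > 0).all()
        assert a.matrix.values.equals(b.matrix.values)
        assert len(a.truth["planted_genes"]) == round(spec.planted_fraction * spec.n_genes)
        ranks1 = a.annotation[a.annotation.three_prime_rank == 1]
        assert len(ranks1) == spec.n_genes

    def test_null_simulation_yields_no_discoveries(self):
        spec = sf.ExpressionSimSpec(planted_fraction=0.0, seed=5)
        sim = sf.simulate_expression_dataset(spec)
        collapsed = sf.collapse_to_gene(sim.matrix, sim.annotation)
        de = sf.differential_expression(collapsed)
        frac = np.mean([r.fdr_adjusted_p <= 0.05 for r in de])
        assert frac <= 0.05

    def test_unknown_gene_in_categories_rejected(self):
        spec = sf.ExpressionSimSpec(
            n_probesets=12, n_genes=10, categories={"nope": ["CATX"]}, seed=0
        )
        with pytest.raises(ValidationError, match="unknown gene"):
            sf.simulate_expression_dataset(spec)
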