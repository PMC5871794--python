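"""Generator calibration, determinism and noiseless round-trips."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from spectrokin import synthetic
from spectrokin.bands import band_area_trapezoid, fit_bands, segmented_linear_fit
from spectrokin.dielectric import (fit_loss_spectrum, hn_loss,
                                   tau_max_from_hn)
from spectrokin.kinetics import fit_first_order


class TestPaperScenarioCalibration:
    def test_vft_parameters_solve_the_two_constraints(self, paper_config):
        v = paper_config.alpha_vft
        # derived by solving ln(tau/tau_inf) = D*T0/(T-T0) at the two
        # anchor points (293 K, 100 s) and (365 K, 1e-9 s)
        assert v.T0 == pytest.approx(260.3, abs=0.1)
        assert v.D_T == pytest.approx(4.63, abs=0.01)
        assert float(v.tau(293.0)) == pytest.approx(100.0, rel=1e-12)
        assert float(np.log10(v.tau(365.0))) == pytest.approx(-9.0,
                                                              abs=1e-12)

    def test_gamma_prefactor(self, paper_config):
        # tau_inf = 1e-9 / exp(45600/(8.314*365)) ~ 3.0e-16 s
        g = paper_config.gamma_arrhenius
        assert g.tau_inf == pytest.approx(3.0e-16, rel=0.01)
        assert float(np.log10(g.tau(365.0))) == pytest.approx(-9.0,
                                                              abs=1e-12)

    def test_kinetics_branches_continuous_at_crossover(self, paper_config):
        kin = paper_config.kinetics
        assert kin.ea_below_kj_mol == 57.5
        assert kin.ea_above_kj_mol == 184.5
        below = kin.k_at_Tc * np.exp(
            -57_500.0 / 8.314 * (1 / 364.999999 - 1 / 365.0))
        assert float(kin.k(364.999999)) == pytest.approx(below, rel=1e-9)
        assert float(kin.k(365.0)) == pytest.approx(kin.k_at_Tc, rel=1e-12)

    def test_manifest_records_truth(self, paper_config):
        m = synthetic.scenario_manifest(paper_config)
        assert m["Tg_K"] == pytest.approx(293.0, abs=0.01)
        assert m["Tc_dielectric_K"] == pytest.approx(365.0, abs=0.01)
        assert m["log10_tau_at_Tc"] == pytest.approx(-9.0, abs=0.01)
        assert m["Ea_gamma_kj_mol"] == 45.6


class TestDielectricGenerator:
    def test_determinism_bitwise(self, paper_config):
        a, _ = synthetic.generate_dielectric_series(paper_config)
        b, _ = synthetic.generate_dielectric_series(paper_config)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.loss, sb.loss)

    def test_noiseless_output_equals_forward_model(self, noiseless_config):
        spectra, _ = synthetic.generate_dielectric_series(noiseless_config)
        s = spectra[0]
        model, _ = synthetic.dielectric_truth_model(noiseless_config,
                                                    s.temperature)
        np.testing.assert_array_equal(s.loss, hn_loss(s.frequency, model))

    def test_loss_positive_and_finite(self, dielectric_spectra):
        for s in dielectric_spectra[0]:
            assert np.all(np.isfinite(s.loss)) and np.all(s.loss > 0)

    def test_unobservable_temperatures_warned_not_silent(self,
                                                         dielectric_spectra):
        spectra, warns = dielectric_spectra
        emitted = {s.temperature for s in spectra}
        rejected = {w.temperature for w in warns
                    if "rejected" in w.message}
        assert rejected == {423.0, 433.0, 443.0, 453.0}
        assert rejected.isdisjoint(emitted)

    def test_debye_configuration_peaks_at_one_hertz(self, noiseless_config):
        # at the temperature where tau_alpha = 1/(2 pi), a Debye-shaped
        # alpha process peaks at exactly 1 Hz
        v = noiseless_config.alpha_vft
        T_star = brentq(lambda T: float(v.tau(T)) - 1 / (2 * np.pi),
                        280.0, 320.0)
        cfg = dataclasses.replace(
            noiseless_config, hn_shapes_alpha=(1.0, 1.0),
            delta_eps_gamma=1e-12, dc_conductivity={},
            dielectric_temps=(T_star,))
        spectra, _ = synthetic.generate_dielectric_series(cfg)
        s = spectra[0]
        f_peak = s.frequency[np.argmax(s.loss)]
        assert f_peak == pytest.approx(1.0, rel=0.15)   # grid resolution

    def test_noiseless_roundtrip_tau_recovery(self, noiseless_config):
        spectra, _ = synthetic.generate_dielectric_series(noiseless_config)
        glassy = [s for s in spectra if s.temperature == 233.0][0]
        fit = fit_loss_spectrum(glassy, n_processes=1, with_dc=False, rng=0)
        truth = float(noiseless_config.tau_gamma(233.0))
        assert tau_max_from_hn(fit.processes[0]) == pytest.approx(truth,
                                                                  rel=1e-4)


class TestVibrationalGenerator:
    def test_degenerate_kink_yields_single_line(self, noiseless_config):
        spec = dataclasses.replace(
            noiseless_config.band_table[0], slope_above=-0.05,
            intensity_slope_above=-0.002)
        cfg = dataclasses.replace(noiseless_config, band_table=[spec])
        spectra = synthetic.generate_vibrational_temperature_series(cfg)
        temps = [s.metadata["temperature_K"] for s in spectra]
        centers = [spec.center(T) for T in temps]
        fit = segmented_linear_fit(temps, centers)
        assert not fit.significant

    def test_oh_band_upshift_above_crossover(self, noiseless_config):
        oh = [b for b in noiseless_config.band_table
              if b.name == "oh_3375"][0]
        # piecewise trend: continuous at the kink, steeper above
        assert oh.center(365.0) == pytest.approx(
            3375.0 + 0.4 * (365.0 - 313.0))
        net = oh.center(453.0) - oh.center(313.0)
        assert net == pytest.approx(100.0, abs=1.0)
        spectra = synthetic.generate_vibrational_temperature_series(
            noiseless_config)
        hot = spectra[-1]
        mask = hot.wavenumber > 3000.0
        peak = hot.wavenumber[mask][np.argmax(hot.intensity[mask])]
        assert peak == pytest.approx(oh.center(453.0), abs=2.0)

    def test_generated_band_area_matches_configuration(self,
                                                       noiseless_config):
        spec = dataclasses.replace(noiseless_config.band_table[0],
                                   lorentz_width=1e-6)   # compact support
        cfg = dataclasses.replace(noiseless_config, band_table=[spec])
        spectra = synthetic.generate_vibrational_temperature_series(cfg)
        s = spectra[0]
        T = s.metadata["temperature_K"]
        got = band_area_trapezoid(s, (spec.center(T) - 40.0,
                                      spec.center(T) + 40.0))
        assert got == pytest.approx(spec.area(T), rel=1e-3)

    def test_band_outside_grid_rejected(self, noiseless_config):
        spec = dataclasses.replace(noiseless_config.band_table[0],
                                   center_at_Tref=100.0)
        cfg = dataclasses.replace(noiseless_config, band_table=[spec])
        with pytest.raises(ValueError, match="outside"):
            synthetic.generate_vibrational_temperature_series(cfg)


class TestMutarotationGenerator:
    def test_initial_marker_area_is_amplitude_plus_offset(
            self, noiseless_config):
        kin = noiseless_config.kinetics
        # by construction the marker area at t = 0 is exactly A + C
        assert float(kin.beta_area(0.0, 360.0)) == kin.A0 + kin.C0
        # deconvolving it back out of the generated spectrum carries a
        # small systematic from the neighbouring alpha-marker tail
        series = synthetic.generate_mutarotation_series(noiseless_config,
                                                        360.0)
        fit = fit_bands(series[0], window=(785.0, 845.0), n_bands=1,
                        centers_init=[kin.beta_center], rng=0)
        assert fit.bands[0].area == pytest.approx(kin.A0 + kin.C0, rel=0.01)

    def test_plateau_reached_after_five_characteristic_times(
            self, noiseless_config):
        kin = noiseless_config.kinetics
        k = float(kin.k(360.0))
        # residual decay e^-5 ~ 0.7% of the amplitude
        assert abs(float(kin.beta_area(5.0 / k, 360.0)) - kin.C0) \
            <= 0.01 * kin.A0

    def test_marker_areas_sum_conserved(self, noiseless_config):
        kin = noiseless_config.kinetics
        t = kin.times(350.0)
        total = kin.beta_area(t, 350.0) + kin.alpha_area(t, 350.0)
        np.testing.assert_allclose(total, total[0], rtol=1e-12)

    def test_out_of_range_temperature_rejected(self, noiseless_config):
        with pytest.raises(ValueError):
            synthetic.generate_mutarotation_series(noiseless_config, 400.0)

    def test_trace_generator_matches_spectral_route(self, noiseless_config):
        kin = noiseless_config.kinetics
        traces = synthetic.generate_kinetics_traces(noiseless_config,
                                                    temps=[355.0])
        np.testing.assert_allclose(traces[0].intensity,
                                   kin.beta_area(traces[0].time, 355.0),
                                   rtol=1e-12)

    def test_noiseless_roundtrip_rate_recovery(self, noiseless_config):
        traces = synthetic.generate_kinetics_traces(noiseless_config,
                                                    temps=[345.0])
        fit = fit_first_order(traces[0])
        truth = float(noiseless_config.kinetics.k(345.0))
        assert fit.k == pytest.approx(truth, rel=1e-4)

    def test_trace_determinism(self, paper_config):
        a = synthetic.generate_kinetics_traces(paper_config)
        b = synthetic.generate_kinetics_traces(paper_config)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.intensity, tb.intensity)


class TestNoiseSpec:
    def test_zero_sigma_is_identity(self):
        spec = synthetic.NoiseSpec(sigma_rel=0.0)
        y = np.linspace(1.0, 5.0, 10)
        out = spec.apply(y, np.random.default_rng(0))
        np.testing.assert_array_equal(out, y)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            synthetic.NoiseSpec(model="poisson")

    def test_additive_mode_scales_with_maximum(self):
        spec = synthetic.NoiseSpec(model="additive", sigma_rel=0.1)
        y = np.full(10_000, 10.0)
        out = spec.apply(y, np.random.default_rng(1))
        assert np.std(out - y) == pytest.approx(1.0, rel=0.05)
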