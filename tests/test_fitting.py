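"""TCMT parameter inversion, detuning response, calibration and LOD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seirakit.fitting import (CalibrationCurve, CalibrationFit, TcmtFitter,
                              calibration_fit, detuning_response, fit_tcmt,
                              lod_3sigma)
from seirakit.fitting import AmbiguityError
from seirakit.synthetic import default_grid
from seirakit.tcmt import (CoupledSystem, MolecularOscillator, Resonator,
                           Spectrum, absorption_spectrum, system_from_ratios)

TRUE = dict(omega0=1730.0, gamma_r=400.0, gamma_a=40.0,
            omega_m=1730.0, gamma_m=10.0, mu=25.0)


def _rel_errors(result):
    r, o = result.resonator, result.oscillators[0]
    got = dict(omega0=r.omega0, gamma_r=r.gamma_r, gamma_a=r.gamma_a,
               omega_m=o.omega_m, gamma_m=o.gamma_m, mu=o.mu)
    return {k: abs(got[k] - TRUE[k]) / TRUE[k] for k in TRUE}


@pytest.fixture
def generating_system():
    return CoupledSystem(
        Resonator(TRUE["omega0"], TRUE["gamma_r"], TRUE["gamma_a"]),
        (MolecularOscillator(TRUE["omega_m"], TRUE["gamma_m"], TRUE["mu"]),))


class TestTcmtInversion:
    def test_noiseless_recovery(self, generating_system, ftir_grid):
        spec = absorption_spectrum(generating_system, ftir_grid)
        result = fit_tcmt(spec, 1, "OC", seed=0, line_hints=(1730.0,))
        assert max(_rel_errors(result).values()) < 1e-3
        assert result.regime == "OC"
        assert result.coupling_label == "strong"   # xi = 2.5 here

    def test_noisy_recovery_single_seed(self, generating_system, ftir_grid):
        rng = np.random.default_rng(0)
        clean = absorption_spectrum(generating_system, ftir_grid)
        noisy = Spectrum(ftir_grid,
                         np.clip(clean.values + rng.normal(0.0, 0.005,
                                                           ftir_grid.size),
                                 0.0, 1.0), "absorbance")
        result = fit_tcmt(noisy, 1, "OC", seed=0, line_hints=(1730.0,))
        assert max(_rel_errors(result).values()) < 0.05

    def test_median_recovery_over_noise_realizations(self, generating_system,
                                                     ftir_grid):
        """Median relative error of every parameter < 5% over 20 seeded noise
        realizations at sigma = 0.005; the regime is never misclassified."""
        clean = absorption_spectrum(generating_system, ftir_grid).values
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = Spectrum(ftir_grid,
                             np.clip(clean + rng.normal(0.0, 0.005,
                                                        ftir_grid.size),
                                     0.0, 1.0), "absorbance")
            result = fit_tcmt(noisy, 1, "OC", seed=seed, line_hints=(1730.0,),
                              n_starts=2)
            errors.append(_rel_errors(result))
            assert result.regime == "OC"
        medians = {k: np.median([e[k] for e in errors]) for k in TRUE}
        assert max(medians.values()) < 0.05, medians

    def test_bare_swap_degeneracy(self, ftir_grid):
        """Amplitude-only bare spectra cannot distinguish f from 1/f: the OC
        and UC priors return swapped losses with identical residuals."""
        spec = absorption_spectrum(
            CoupledSystem(Resonator(1730.0, 400.0, 40.0)), ftir_grid)
        oc = fit_tcmt(spec, 0, "OC", seed=0)
        uc = fit_tcmt(spec, 0, "UC", seed=0)
        assert oc.resonator.gamma_r == pytest.approx(uc.resonator.gamma_a,
                                                     rel=1e-6)
        assert oc.resonator.gamma_a == pytest.approx(uc.resonator.gamma_r,
                                                     rel=1e-6)
        assert oc.residual_rms == pytest.approx(uc.residual_rms, abs=1e-9)

    def test_coupled_line_breaks_degeneracy(self, generating_system,
                                            ftir_grid):
        """With a coupled oscillator the swapped-loss fit is strictly worse."""
        spec = absorption_spectrum(generating_system, ftir_grid)
        good = fit_tcmt(spec, 1, "OC", seed=0, line_hints=(1730.0,))
        swapped = CoupledSystem(
            Resonator(TRUE["omega0"], TRUE["gamma_a"], TRUE["gamma_r"]),
            generating_system.oscillators)
        from seirakit.tcmt import absorption_values
        swapped_rms = float(np.sqrt(np.mean(
            (absorption_values(swapped, ftir_grid) - spec.values) ** 2)))
        assert swapped_rms > 100 * max(good.residual_rms, 1e-12)

    def test_auto_mode_requires_line(self, ftir_grid):
        spec = absorption_spectrum(
            CoupledSystem(Resonator(1730.0, 400.0, 40.0)), ftir_grid)
        with pytest.raises(AmbiguityError):
            fit_tcmt(spec, 0, "auto", seed=0)

    def test_auto_mode_resolves_undercoupled(self, ftir_grid):
        sys_ = CoupledSystem(Resonator(1730.0, 40.0, 100.0),
                             (MolecularOscillator(1730.0, 10.0, 25.0),))
        spec = absorption_spectrum(sys_, ftir_grid)
        result = fit_tcmt(spec, 1, "auto", seed=0, line_hints=(1730.0,))
        assert result.regime == "UC"

    def test_predict_consistent_with_residual(self, generating_system,
                                              ftir_grid):
        spec = absorption_spectrum(generating_system, ftir_grid)
        fitter = TcmtFitter(1, "OC", line_hints=(1730.0,), seed=0)
        fitter.fit(ftir_grid, spec.values)
        pred = fitter.predict(ftir_grid)
        rms = float(np.sqrt(np.mean((pred - spec.values) ** 2)))
        assert rms == pytest.approx(fitter.result_.residual_rms, abs=1e-15)

    def test_estimator_params_roundtrip(self):
        fitter = TcmtFitter()
        fitter.set_params(n_oscillators=2, seed=7)
        assert fitter.get_params()["n_oscillators"] == 2
        with pytest.raises(ValueError):
            fitter.set_params(nope=1)


class TestDetuningResponse:
    def test_theory_curve_peaks_at_matched_frequency(self):
        table = detuning_response([], theory=(10.0, 1.0))
        curve = table.attrs["theory_curve"]
        dgrid = table.attrs["theory_detuning"]
        assert abs(dgrid[int(np.argmax(np.abs(curve)))]) <= dgrid[1] - dgrid[0]

    def test_curve_even_in_detuning(self):
        dgrid = np.linspace(-20.0, 20.0, 401)
        table = detuning_response([], theory=(10.0, 1.5), detuning_grid=dgrid)
        curve = table.attrs["theory_curve"]
        np.testing.assert_allclose(curve, curve[::-1], atol=1e-14)

    def test_zero_coupling_flat_zero(self):
        table = detuning_response([], theory=(10.0, 0.0))
        np.testing.assert_allclose(table.attrs["theory_curve"], 0.0,
                                   atol=1e-15)

    def test_observed_points_from_systems(self):
        systems = [system_from_ratios(10.0, 1.0, dw) for dw in (-5.0, 0.0, 5.0)]
        table = detuning_response(systems)
        assert len(table) == 3
        assert table.I_SEIRA.abs().idxmax() == 1   # matched entry wins


class TestCalibration:
    def test_exact_linear(self):
        c = np.array([0.0, 10.0, 20.0, 50.0, 100.0])
        fit = calibration_fit(pd.DataFrame({"concentration": c,
                                            "signal": 0.01 * c}))
        assert fit.parameters["slope"] == pytest.approx(0.01, rel=1e-12)
        assert fit.parameters["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_langmuir_self_consistency(self):
        c = np.array([1.0, 3.0, 10.0, 30.0, 60.0, 100.0, 200.0, 400.0])
        kc = 0.02 * c
        y = 10.0 * kc / (1.0 + kc)
        est = CalibrationCurve(model="langmuir_ext")
        est.fit(c, y)
        assert est.result_.parameters["I_max"] == pytest.approx(10.0, rel=1e-3)
        assert est.result_.parameters["K"] == pytest.approx(0.02, rel=1e-3)

    def test_single_concentration_rank_error(self):
        with pytest.raises(ValueError):
            CalibrationCurve().fit([5.0, 5.0, 5.0], [1.0, 1.1, 0.9])

    def test_langmuir_slope_at_origin(self):
        fit = CalibrationFit("langmuir_ext",
                             {"I_max": 10.0, "K": 0.02, "exponent": 1.0},
                             residuals=np.empty(0))
        assert fit.slope_at_origin == pytest.approx(0.2)


class TestLod:
    @pytest.mark.parametrize("sigma,slope,expected", [
        (0.3, 0.01, 90.0), (0.0, 0.01, 0.0), (0.15, 0.0005, 900.0)])
    def test_three_sigma_formula(self, sigma, slope, expected):
        fit = CalibrationFit("linear", {"slope": slope, "intercept": 0.0},
                             residuals=np.empty(0))
        assert lod_3sigma(fit, sigma).lod == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(sigma=st.floats(1e-6, 10.0), slope=st.floats(1e-6, 10.0))
    def test_homogeneity(self, sigma, slope):
        """Doubling sigma doubles the LOD; doubling the slope halves it."""
        fit = CalibrationFit("linear", {"slope": slope, "intercept": 0.0},
                             residuals=np.empty(0))
        fit2 = CalibrationFit("linear", {"slope": 2 * slope, "intercept": 0.0},
                              residuals=np.empty(0))
        base = lod_3sigma(fit, sigma).lod
        assert lod_3sigma(fit, 2 * sigma).lod == pytest.approx(2 * base,
                                                               rel=1e-12)
        assert lod_3sigma(fit2, sigma).lod == pytest.approx(base / 2,
                                                            rel=1e-12)

    def test_zero_slope_rejected(self):
        fit = CalibrationFit("linear", {"slope": 0.0, "intercept": 0.0},
                             residuals=np.empty(0))
        with pytest.raises(ValueError):
            lod_3sigma(fit, 0.1)
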