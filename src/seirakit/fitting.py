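"""TCMT parameter inversion, detuning-response curves, calibration fits and LOD.

Inverting the coupled-mode absorbance model against a measured spectrum
recovers the device rates (omega0, gamma_r, gamma_a) and per-line molecular
parameters (omega_m, gamma_m, mu).  A bare (no-oscillator) absorbance spectrum
only determines omega0, gamma_r + gamma_a and gamma_r * gamma_a — the
amplitude Lorentzian 4*gr*ga/((gr+ga)^2 + x^2) is symmetric under gr <-> ga —
so the loss assignment must come from a regime prior (the device geometry in
practice).  A coupled molecular line breaks the degeneracy through the sign of
the enhanced signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .atlas import seira_sensitivity_reduced
from .loops import loop_report
from .tcmt import (CoupledSystem, MolecularOscillator, Resonator, Spectrum,
                   absorption_values, classify_regime, delta_values,
                   seira_sensitivity)

__all__ = [
    "TcmtFitResult",
    "TcmtFitter",
    "fit_tcmt",
    "FitError",
    "detuning_response",
    "CalibrationCurve",
    "CalibrationFit",
    "calibration_fit",
    "LodReport",
    "lod_3sigma",
]


class FitError(RuntimeError):
    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


class AmbiguityError(ValueError):
    pass


@dataclass
class TcmtFitResult:
    """Inverted TCMT parameters.

    ``omega01`` is the loaded-device resonance: the absorbance maximum of the
    fitted coupled system, red-shifted from the fitted bare omega0 by the
    molecular back-action.
    """

    resonator: Resonator
    oscillators: tuple[MolecularOscillator, ...]
    omega01: float
    residual_rms: float
    regime: str
    coupling_label: str
    uncertainties: dict = field(default_factory=dict)
    n_starts_used: int = 1

    @property
    def system(self) -> CoupledSystem:
        return CoupledSystem(self.resonator, self.oscillators)


def _unpack(theta: np.ndarray) -> CoupledSystem:
    res = Resonator(theta[0], theta[1], theta[2])
    oscs = tuple(MolecularOscillator(*theta[3 + 3 * k: 6 + 3 * k])
                 for k in range((len(theta) - 3) // 3))
    return CoupledSystem(res, oscs)


def _param_names(n_osc: int) -> list[str]:
    names = ["omega0", "gamma_r", "gamma_a"]
    for k in range(n_osc):
        names += [f"omega_m{k}", f"gamma_m{k}", f"mu{k}"]
    return names


class TcmtFitter:
    """Nonlinear least-squares inversion of the TCMT absorbance model.

    sklearn-style estimator: ``fit(omega, absorbance)`` then ``predict(omega)``.

    Parameters
    ----------
    n_oscillators : number of molecular lines to fit (0 = bare absorber).
    regime_prior : 'OC', 'UC' or 'auto'.  Resolves the gamma_r <-> gamma_a
        swap of bare spectra; 'auto' requires at least one coupled line and
        uses the sign of the enhanced signal at the strongest line.
    line_hints : optional starting positions (cm^-1) for the molecular lines,
        e.g. known fingerprint frequencies.
    n_starts : multi-start count guarding against local minima.
    seed : seeds the start perturbations.
    """

    def __init__(self, n_oscillators: int = 1, regime_prior: str = "OC",
                 line_hints: tuple[float, ...] | None = None,
                 n_starts: int = 5, seed: int | None = None,
                 max_nfev: int = 4000):
        self.n_oscillators = n_oscillators
        self.regime_prior = regime_prior
        self.line_hints = line_hints
        self.n_starts = n_starts
        self.seed = seed
        self.max_nfev = max_nfev

    def get_params(self, deep: bool = True) -> dict:
        return {"n_oscillators": self.n_oscillators,
                "regime_prior": self.regime_prior,
                "line_hints": self.line_hints, "n_starts": self.n_starts,
                "seed": self.seed, "max_nfev": self.max_nfev}

    def set_params(self, **params) -> "TcmtFitter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def _detect_regime(self, w: np.ndarray, y: np.ndarray) -> str:
        """Decide the loss regime from the sign of the baseline-extracted
        molecular feature: enhanced peaks ride above the smooth envelope in
        overcoupled devices and dip below it in undercoupled ones (moderate
        coupling assumed)."""
        from .spectral import AslsBaseline

        delta = AslsBaseline(asymmetry=0.5).transform(y[None, :])[0]
        peak = delta[int(np.argmax(np.abs(delta)))]
        if abs(peak) < 0.005:
            raise AmbiguityError(
                "no molecular feature detectable above the baseline: the "
                "loss assignment is ambiguous; pass regime_prior='OC' or 'UC'")
        return "OC" if peak > 0 else "UC"

    def _initial_systems(self, w: np.ndarray, y: np.ndarray, prior: str,
                         rng: np.random.Generator) -> list[np.ndarray]:
        """Seed from the spectrum: peak position -> omega0, FWHM/2 -> gr+ga,
        peak height -> gr*ga; molecular lines at the hints (or spread across
        the band)."""
        ipk = int(np.argmax(y))
        w0 = w[ipk]
        apk = float(np.clip(y[ipk], 1e-3, 1.0))
        half = apk / 2.0
        above = y >= half
        wsel = w[above]
        fwhm = max(float(wsel[-1] - wsel[0]), 4.0 * float(np.mean(np.diff(w))))
        gtot = fwhm / 2.0
        # apk = 4 gr ga/(gr+ga)^2 -> gr,ga = gtot/2 (1 +/- sqrt(1-apk))
        disc = np.sqrt(max(0.0, 1.0 - apk))
        g_hi = 0.5 * gtot * (1.0 + disc)
        g_lo = max(0.5 * gtot * (1.0 - disc), 1e-6 * gtot)
        assignments = [(g_lo, g_hi)] if prior == "UC" else [(g_hi, g_lo)]
        hints = list(self.line_hints or [])
        while len(hints) < self.n_oscillators:
            k = len(hints)
            hints.append(w0 + (k - (self.n_oscillators - 1) / 2) * fwhm / 4.0)
        # two line-seed styles: a narrow vibrational-linewidth guess (right
        # for fingerprint lines on wide absorbers) and a broad strong-coupling
        # guess scaled to the absorber width
        line_seeds = [(min(10.0, gtot / 4.0), min(10.0, gtot / 4.0) / 2.0),
                      (gtot / 20.0, gtot / 10.0)]
        starts = []
        for gr0, ga0 in assignments:
            for gm0, mu0 in line_seeds:
                base = [w0, gr0, ga0]
                for h in hints[: self.n_oscillators]:
                    base += [h, gm0, mu0]
                starts.append(np.array(base))
            base = starts[-1]
            for _ in range(max(self.n_starts - 2, 0)):
                jitter = rng.uniform(0.7, 1.4, size=len(base))
                cand = np.array(base) * jitter
                cand[0] = base[0] + rng.normal(0.0, 0.05 * fwhm)
                for k in range(self.n_oscillators):
                    cand[3 + 3 * k] = base[3 + 3 * k] + \
                        rng.normal(0.0, 0.02 * fwhm)
                starts.append(cand)
        return starts

    def fit(self, omega, absorbance) -> "TcmtFitter":
        w = np.asarray(omega, dtype=float)
        y = np.asarray(absorbance, dtype=float)
        if isinstance(omega, Spectrum):
            raise TypeError("pass grid and values separately, or use fit_tcmt")
        if w.shape != y.shape or w.ndim != 1:
            raise ValueError("omega and absorbance must be equal-length 1-D")
        if self.n_oscillators < 0:
            raise ValueError("n_oscillators must be >= 0")
        if self.regime_prior not in ("OC", "UC", "auto"):
            raise ValueError("regime_prior must be 'OC', 'UC' or 'auto'")
        if self.regime_prior == "auto" and self.n_oscillators == 0:
            raise AmbiguityError(
                "bare spectra cannot determine the loss assignment: the "
                "amplitude model is symmetric under gamma_r <-> gamma_a; "
                "pass regime_prior='OC' or 'UC'")

        prior = self.regime_prior
        if prior == "auto":
            prior = self._detect_regime(w, y)
        rng = np.random.default_rng(self.seed)
        span = w[-1] - w[0]
        npar = 3 + 3 * self.n_oscillators
        lo = np.full(npar, 1e-9)
        hi = np.full(npar, np.inf)
        lo[0], hi[0] = w[0] - span, w[-1] + span
        for k in range(self.n_oscillators):
            if self.line_hints is not None and k < len(self.line_hints):
                # hints are declared fingerprint positions: keep each line in
                # a window around its hint so weak lines cannot wander
                h = self.line_hints[k]
                lo[3 + 3 * k], hi[3 + 3 * k] = h - 100.0, h + 100.0
            else:
                lo[3 + 3 * k], hi[3 + 3 * k] = w[0] - span, w[-1] + span
            lo[5 + 3 * k] = 0.0  # mu may vanish

        def residuals(theta):
            return absorption_values(_unpack(theta), w) - y

        best = None
        used = 0
        for start in self._initial_systems(w, y, prior, rng):
            used += 1
            try:
                sol = least_squares(residuals, np.clip(start, lo + 1e-12, None),
                                    bounds=(lo, hi), max_nfev=self.max_nfev)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.cost < 1e-20 * w.size:
                break
        if best is None:
            raise FitError("all optimization starts failed")
        if not best.success and best.cost > 1e-6 * w.size:
            raise FitError(
                f"TCMT fit did not converge (status {best.status}); best "
                f"candidate attached", best=_unpack(best.x))

        system = _unpack(best.x)
        self._finalize(system, best, w, y, used)
        return self

    def _finalize(self, system: CoupledSystem, sol, w, y, used) -> None:
        resid = absorption_values(system, w) - y
        rms = float(np.sqrt(np.mean(resid**2)))
        # asymptotic standard errors from the Jacobian at the solution
        names = _param_names(len(system.oscillators))
        errs: dict[str, float] = {}
        try:
            J = sol.jac
            dof = max(w.size - J.shape[1], 1)
            s2 = 2.0 * sol.cost / dof
            cov = s2 * np.linalg.pinv(J.T @ J)
            errs = {n: float(np.sqrt(max(c, 0.0)))
                    for n, c in zip(names, np.diag(cov))}
        except Exception:
            pass
        if system.oscillators:
            dense = np.linspace(w[0], w[-1], max(4 * w.size, 2000))
            omega01 = float(dense[int(np.argmax(absorption_values(system, dense)))])
            label = loop_report(system, locate=False).coupling_label
        else:
            omega01 = system.resonator.omega0
            label = "weak"
        self.system_ = system
        self.result_ = TcmtFitResult(
            resonator=system.resonator, oscillators=system.oscillators,
            omega01=omega01, residual_rms=rms,
            regime=classify_regime(system.resonator, tol=1e-6),
            coupling_label=label, uncertainties=errs, n_starts_used=used)
        self.n_features_in_ = w.size

    def predict(self, omega) -> np.ndarray:
        return absorption_values(self.system_, np.asarray(omega, dtype=float))


def fit_tcmt(spectrum: Spectrum, n_oscillators: int = 1,
             regime_prior: str = "OC", seed: int | None = None,
             line_hints: tuple[float, ...] | None = None,
             n_starts: int = 5) -> TcmtFitResult:
    """Invert Eq.-of-motion parameters from an absorbance spectrum."""
    if spectrum.kind != "absorbance":
        raise ValueError("fit_tcmt expects an absorbance spectrum")
    fitter = TcmtFitter(n_oscillators=n_oscillators, regime_prior=regime_prior,
                        line_hints=line_hints, n_starts=n_starts, seed=seed)
    fitter.fit(spectrum.grid, spectrum.values)
    return fitter.result_


# ------------------------------------------------------------- detuning curve

def detuning_response(entries, oscillator_index: int = 0, *,
                      theory: tuple[float, float] | None = None,
                      detuning_grid: np.ndarray | None = None) -> pd.DataFrame:
    """I_SEIRA versus detuning dw = omega_m - omega01 for a series of systems.

    ``entries`` is an iterable of CoupledSystem or TcmtFitResult.  Returns a
    table with observed sensitivities; when ``theory=(f, xi)`` is given, a
    theoretical column evaluated from the coupled-mode model on
    ``detuning_grid`` (gamma_m units) is attached as DataFrame attrs
    ('theory_detuning', 'theory_curve').
    """
    rows = []
    for e in entries:
        system = e.system if isinstance(e, TcmtFitResult) else e
        osc = system.oscillators[oscillator_index]
        if isinstance(e, TcmtFitResult):
            w01 = e.omega01
        else:
            dense_half = 10 * (system.resonator.gamma_total)
            dense = np.linspace(system.resonator.omega0 - dense_half,
                                system.resonator.omega0 + dense_half, 4001)
            w01 = float(dense[int(np.argmax(absorption_values(system, dense)))])
        rows.append({
            "detuning_cm1": osc.omega_m - w01,
            "I_SEIRA": seira_sensitivity(system, oscillator_index),
            "f": system.resonator.f, "xi": osc.xi,
        })
    out = pd.DataFrame(rows, columns=["detuning_cm1", "I_SEIRA", "f", "xi"])
    out = out.sort_values("detuning_cm1").reset_index(drop=True)
    if theory is not None:
        f, xi = theory
        if detuning_grid is None:
            detuning_grid = np.linspace(-25.0, 25.0, 501)
        out.attrs["theory_detuning"] = np.asarray(detuning_grid, dtype=float)
        out.attrs["theory_curve"] = seira_sensitivity_reduced(
            f, xi, out.attrs["theory_detuning"])
    return out


# ---------------------------------------------------------------- calibration

@dataclass
class CalibrationFit:
    """Concentration-response fit: linear or extended Langmuir."""

    model: str                       # 'linear' | 'langmuir_ext'
    parameters: dict
    residuals: np.ndarray
    concentration_unit: str = "ng/uL"

    @property
    def slope_at_origin(self) -> float:
        if self.model == "linear":
            return self.parameters["slope"]
        p = self.parameters
        if p["exponent"] != 1.0:
            raise ValueError("slope at origin undefined for exponent != 1")
        return p["I_max"] * p["K"]

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.model == "linear":
            return self.parameters["slope"] * c + self.parameters["intercept"]
        p = self.parameters
        kc = (p["K"] * c) ** p["exponent"]
        return p["I_max"] * kc / (1.0 + kc)


class CalibrationCurve:
    """sklearn-style calibration estimator: fit(concentration, signal).

    model='linear': signal = a*c + b (exact least squares).
    model='langmuir_ext': signal = I_max*(K*c)^n/(1 + (K*c)^n), n fixed
    (default 1, the Langmuir isotherm); I_max, K > 0 enforced by bounds.
    """

    def __init__(self, model: str = "linear", exponent: float = 1.0,
                 weights=None):
        self.model = model
        self.exponent = exponent
        self.weights = weights

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "exponent": self.exponent,
                "weights": self.weights}

    def set_params(self, **params) -> "CalibrationCurve":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, concentration, signal) -> "CalibrationCurve":
        c = np.asarray(concentration, dtype=float)
        y = np.asarray(signal, dtype=float)
        if c.size != y.size or c.size < 3:
            raise ValueError("need >= 3 matched (concentration, signal) points")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.ptp(c) == 0:
            raise ValueError("design is rank-deficient: all concentrations equal")
        wts = np.ones_like(c) if self.weights is None else np.asarray(self.weights)
        if self.model == "linear":
            A = np.column_stack([c, np.ones_like(c)]) * np.sqrt(wts)[:, None]
            coef, *_ = np.linalg.lstsq(A, y * np.sqrt(wts), rcond=None)
            params = {"slope": float(coef[0]), "intercept": float(coef[1])}
        elif self.model == "langmuir_ext":
            n = self.exponent
            i0 = max(float(y.max()), 1e-12)
            pos = c[c > 0]
            k0 = 1.0 / float(np.median(pos)) if pos.size else 1.0

            def res(p):
                kc = np.clip(p[1] * c, 0.0, None) ** n
                return np.sqrt(wts) * (p[0] * kc / (1.0 + kc) - y)

            sol = least_squares(res, [i0, k0], bounds=([1e-12, 1e-12],
                                                       [np.inf, np.inf]))
            if not sol.success:
                raise FitError("Langmuir calibration failed to converge")
            params = {"I_max": float(sol.x[0]), "K": float(sol.x[1]),
                      "exponent": float(n)}
            if params["I_max"] <= 0:
                raise FitError("fitted I_max is non-positive")
        else:
            raise ValueError("model must be 'linear' or 'langmuir_ext'")
        self.result_ = CalibrationFit(self.model, params,
                                      residuals=np.empty(0))
        self.result_.residuals = y - self.result_.predict(c)
        return self

    def predict(self, concentration) -> np.ndarray:
        return self.result_.predict(concentration)


def calibration_fit(series: pd.DataFrame, model: str = "linear",
                    concentration_col: str = "concentration",
                    signal_col: str = "signal", **kwargs) -> CalibrationFit:
    est = CalibrationCurve(model=model, **kwargs)
    est.fit(series[concentration_col].to_numpy(),
            series[signal_col].to_numpy())
    return est.result_


@dataclass
class LodReport:
    """3-sigma limit of detection: lod = 3*sigma_blank / slope_at_origin."""

    sigma_blank: float
    slope_at_origin: float
    lod: float


def lod_3sigma(calibration: CalibrationFit, sigma_blank: float) -> LodReport:
    """Concentration whose expected signal equals 3x the blank noise sd."""
    if sigma_blank < 0:
        raise ValueError("sigma_blank must be non-negative")
    slope = calibration.slope_at_origin
    if slope <= 0:
        raise ValueError(f"slope at origin must be positive, got {slope}")
    return LodReport(sigma_blank, slope, 3.0 * sigma_blank / slope)
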