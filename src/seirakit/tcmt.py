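"""Temporal coupled-mode theory (TCMT) forward model for a metamaterial absorber.

A metal-insulator-metal (MIM) absorber has zero transmission, so absorbance is
``A = 1 - |r|**2`` with ``r`` the complex Fresnel reflection.  The absorber is a
single resonant mode with radiative loss rate ``gamma_r`` (coupling to the
incident beam, input coupling ``kappa**2 = 2*gamma_r``) and internal
(absorptive) loss ``gamma_a``.  Molecular vibrations are dark Lorentzian
oscillators coupled to the bright mode with coefficient ``mu``; each adds a term
``mu**2 / (1j*(w - w_m) + gamma_m)`` to the denominator of the response.

All frequencies and rates live on the wavenumber axis (cm^-1); the gammas are
HWHM-type rates, so the bare absorber's absorption FWHM is ``2*(gamma_r +
gamma_a)``.

Reduced coordinates used throughout the package:

- ``f  = gamma_r / gamma_a``  — loss ratio; f > 1 is overcoupled (OC),
  f < 1 undercoupled (UC), f = 1 critical coupling (perfect absorption
  on resonance).
- ``xi = mu / gamma_m``       — resonator-oscillator coupling ratio; xi > 1
  drives the coupled system into the strong-coupling regime.
- ``dw = omega0 - omega_m``   — spectral detuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Resonator",
    "MolecularOscillator",
    "CoupledSystem",
    "Spectrum",
    "reflection_values",
    "reflection",
    "absorption_values",
    "absorption_spectrum",
    "delta_values",
    "delta_spectrum",
    "seira_sensitivity",
    "classify_regime",
    "resonator_fwhm",
    "zero_detuning_absorbance",
]


class ParameterDomainError(ValueError):
    """A rate or frequency lies outside the physical parameter domain."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterDomainError(msg)


@dataclass(frozen=True)
class Resonator:
    """Bright resonant mode of the metamaterial absorber.

    Parameters
    ----------
    omega0 : float
        Bare resonance position, cm^-1.
    gamma_r : float
        Radiative loss rate (HWHM-type), cm^-1.
    gamma_a : float
        Absorptive (internal) loss rate, cm^-1.
    """

    omega0: float
    gamma_r: float
    gamma_a: float

    def __post_init__(self) -> None:
        _require(self.omega0 > 0, f"omega0 must be positive, got {self.omega0}")
        _require(self.gamma_r > 0, f"gamma_r must be positive, got {self.gamma_r}")
        _require(self.gamma_a > 0, f"gamma_a must be positive, got {self.gamma_a}")

    @property
    def f(self) -> float:
        """Loss ratio gamma_r/gamma_a; >1 overcoupled, <1 undercoupled."""
        return self.gamma_r / self.gamma_a

    @property
    def kappa(self) -> float:
        """Input coupling coefficient, kappa = sqrt(2*gamma_r)."""
        return float(np.sqrt(2.0 * self.gamma_r))

    @property
    def gamma_total(self) -> float:
        return self.gamma_r + self.gamma_a


@dataclass(frozen=True)
class MolecularOscillator:
    """Dark Lorentzian molecular oscillator coupled to the absorber.

    gamma_m = 0 is rejected: it puts a pole of the molecular response on the
    real frequency axis.
    """

    omega_m: float
    gamma_m: float
    mu: float

    def __post_init__(self) -> None:
        _require(self.omega_m > 0, f"omega_m must be positive, got {self.omega_m}")
        _require(self.gamma_m > 0, f"gamma_m must be positive, got {self.gamma_m}")
        _require(self.mu >= 0, f"mu must be non-negative, got {self.mu}")

    @property
    def xi(self) -> float:
        """Coupling ratio mu/gamma_m; >1 marks strong coupling at zero detuning."""
        return self.mu / self.gamma_m


@dataclass(frozen=True)
class CoupledSystem:
    """Absorber plus zero or more molecular oscillators.

    An empty oscillator collection reproduces the bare absorber (mu = 0 limit).
    """

    resonator: Resonator
    oscillators: tuple[MolecularOscillator, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "oscillators", tuple(self.oscillators))

    def bare(self) -> "CoupledSystem":
        """The same resonator with all couplings removed (mu = 0 reference)."""
        return CoupledSystem(self.resonator, ())

    def with_detuning(self, dw: float) -> "CoupledSystem":
        """Shift the resonator so omega0 = omega_m(first oscillator) + dw."""
        if not self.oscillators:
            raise ParameterDomainError("with_detuning needs at least one oscillator")
        res = replace(self.resonator, omega0=self.oscillators[0].omega_m + dw)
        return CoupledSystem(res, self.oscillators)


@dataclass
class Spectrum:
    """A sampled spectrum on a strictly increasing wavenumber grid (cm^-1).

    ``kind`` is one of {"absorbance", "difference", "baseline",
    "derivative1", "derivative2"}; values are dimensionless (absorbance
    fraction, its difference, or its derivative per cm^-1 / cm^-2).
    """

    grid: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"
    meta: dict = field(default_factory=dict)

    KINDS = ("absorbance", "difference", "baseline", "derivative1", "derivative2")

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        if self.values.shape != self.grid.shape:
            raise ValueError("grid and values must have equal length")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")

    def __len__(self) -> int:
        return self.grid.size

    @property
    def spacing(self) -> float:
        """Mean grid step, cm^-1."""
        return float(np.mean(np.diff(self.grid)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.grid)
        return bool(np.all(np.abs(d - d.mean()) <= rtol * d.mean()))

    def copy_with(self, values: np.ndarray, kind: str | None = None, **meta) -> "Spectrum":
        m = dict(self.meta)
        m.update(meta)
        return Spectrum(self.grid.copy(), np.asarray(values, dtype=float),
                        kind or self.kind, m)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ParameterDomainError("grid must be 1-D with >= 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ParameterDomainError("grid must be strictly increasing")
    return grid


def _denominator(system: CoupledSystem, omega: np.ndarray) -> np.ndarray:
    res = system.resonator
    d = 1j * (omega - res.omega0) + (res.gamma_r + res.gamma_a)
    for osc in system.oscillators:
        d = d + osc.mu**2 / (1j * (omega - osc.omega_m) + osc.gamma_m)
    return d


def reflection_values(system: CoupledSystem, omega) -> np.ndarray:
    """Complex reflection r(w) = kappa^2/D(w) - 1.

    ``D(w) = j(w - w0) + (gamma_r + gamma_a) + sum_i mu_i^2/(j(w - w_mi) + gamma_mi)``.
    Accepts scalars or arrays; no grid monotonicity requirement.
    """
    omega = np.asarray(omega, dtype=float)
    return system.resonator.kappa**2 / _denominator(system, omega) - 1.0


def reflection(system: CoupledSystem, grid):
    """Sample r(w) on a strictly increasing grid -> ComplexTrajectory."""
    from .loops import ComplexTrajectory  # local import: loops depends on tcmt

    grid = _check_grid(grid)
    return ComplexTrajectory(grid, reflection_values(system, grid))


def absorption_values(system: CoupledSystem, omega) -> np.ndarray:
    """Absorbance A(w) = 1 - |r(w)|^2 (zero transmission, A = 1 - R)."""
    r = reflection_values(system, omega)
    return 1.0 - np.abs(r) ** 2


def absorption_spectrum(system: CoupledSystem, grid) -> Spectrum:
    grid = _check_grid(grid)
    return Spectrum(grid, absorption_values(system, grid), "absorbance",
                    {"model": "tcmt", "system": system})


def delta_values(system: CoupledSystem, omega) -> np.ndarray:
    """Enhanced-signal spectrum dA(w) = A(w) - A(w)|mu=0."""
    return absorption_values(system, omega) - absorption_values(system.bare(), omega)


def delta_spectrum(system: CoupledSystem, grid) -> Spectrum:
    if not system.oscillators:
        raise ParameterDomainError("delta_spectrum needs at least one oscillator")
    grid = _check_grid(grid)
    return Spectrum(grid, delta_values(system, grid), "difference",
                    {"model": "tcmt", "system": system})


def seira_sensitivity(system: CoupledSystem, oscillator_index: int = 0) -> float:
    """Signed SEIRA sensitivity: dA evaluated at the selected line position.

    Positive in overcoupled devices (molecular peak rides up on the absorber
    background), negative in undercoupled ones, at zero detuning and small
    coupling.
    """
    try:
        osc = system.oscillators[oscillator_index]
    except IndexError:
        raise IndexError(
            f"oscillator_index {oscillator_index} out of range for "
            f"{len(system.oscillators)} oscillator(s)") from None
    return float(delta_values(system, osc.omega_m))


def classify_regime(resonator: Resonator, tol: float = 1e-9) -> str:
    """Label the loss regime: 'OC' if f > 1+tol, 'UC' if f < 1-tol, else 'critical'."""
    if tol < 0:
        raise ValueError("tol must be non-negative")
    f = resonator.f
    if f > 1.0 + tol:
        return "OC"
    if f < 1.0 - tol:
        return "UC"
    return "critical"


def resonator_fwhm(resonator: Resonator) -> float:
    """FWHM of the bare absorption Lorentzian, 2*(gamma_r + gamma_a)."""
    return 2.0 * (resonator.gamma_r + resonator.gamma_a)


def zero_detuning_absorbance(gamma_r: float, gamma_eff: float) -> float:
    """On-resonance absorbance 4*gamma_r*gamma_eff/(gamma_r + gamma_eff)^2.

    ``gamma_eff = gamma_a + sum_i mu_i^2/gamma_mi`` for co-resonant
    oscillators: the molecular channels act as extra internal loss at line
    centre.  Closed-form oracle for the numeric model.
    """
    return 4.0 * gamma_r * gamma_eff / (gamma_r + gamma_eff) ** 2


def system_from_ratios(f: float, xi: float, dw: float = 0.0, *,
                       gamma_a_ref: float = 1.0, gamma_m_ref: float = 1.0,
                       omega_m: float | None = None) -> CoupledSystem:
    """Build a single-oscillator system from reduced coordinates (f, xi, dw).

    gamma_a = gamma_a_ref, gamma_r = f*gamma_a, gamma_m = gamma_m_ref,
    mu = xi*gamma_m, omega0 = omega_m + dw.  ``omega_m`` defaults to a value
    large enough that every frequency stays positive on typical grids.
    """
    if omega_m is None:
        omega_m = 1000.0 * max(gamma_a_ref * (1.0 + abs(f)), gamma_m_ref, 1.0)
    res = Resonator(omega0=omega_m + dw, gamma_r=f * gamma_a_ref, gamma_a=gamma_a_ref)
    osc = MolecularOscillator(omega_m=omega_m, gamma_m=gamma_m_ref,
                              mu=xi * gamma_m_ref)
    return CoupledSystem(res, (osc,))
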