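"""Sensitivity cartography over the three coupling channels.

The SEIRA sensitivity I_SEIRA = dA(omega_m) is controlled by three channels:
the radiation-loss channel f = gamma_r/gamma_a, the resonator-oscillator
coupling channel xi = mu/gamma_m, and the spectral-detuning channel
dw = omega0 - omega_m.  This module maps I_SEIRA over planes of two channels
with the third fixed, and runs the anticrossing diagnostic that separates
Fano-distorting undercoupled devices from distortion-immune overcoupled ones.

With the reference scales gamma_a_ref = gamma_m_ref = 1 the reduced
coordinates fully determine the system; at omega = omega_m the molecular term
collapses to mu^2/gamma_m, giving a closed-form map kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .tcmt import delta_values, system_from_ratios

__all__ = [
    "ChannelGrid",
    "SensitivityMap",
    "AnticrossingTrace",
    "seira_sensitivity_reduced",
    "sensitivity_map",
    "optimal_detuning",
    "enhancement_bandwidth",
    "anticrossing_diagnostic",
]

CHANNELS = ("f", "xi", "detuning")


@dataclass
class ChannelGrid:
    """Grids over the three channels plus the reference scales that close the
    parametrization (gamma_a = gamma_a_ref, gamma_r = f*gamma_a,
    gamma_m = gamma_m_ref, mu = xi*gamma_m).

    Defaults mirror the standard atlas: f log-spaced over [0.1, 20] (200 pts),
    xi in {0.5, 1, 1.5, 2, 2.5, 3}, detuning +/-25 gamma_m units (501 pts).
    """

    f_values: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.1, 20.0, 200))
    xi_values: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0]))
    detuning_values: np.ndarray = field(
        default_factory=lambda: np.linspace(-25.0, 25.0, 501))
    gamma_a_ref: float = 1.0
    gamma_m_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f_values", "xi_values", "detuning_values"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D grid")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, arr)
        if np.any(self.f_values < 0) or np.any(self.xi_values < 0):
            raise ValueError("f and xi grids must be non-negative")
        if self.gamma_a_ref <= 0 or self.gamma_m_ref <= 0:
            raise ValueError("reference rates must be positive")

    def axis(self, channel: str) -> np.ndarray:
        if channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        return {"f": self.f_values, "xi": self.xi_values,
                "detuning": self.detuning_values}[channel]


@dataclass
class SensitivityMap:
    """I_SEIRA (signed) over a plane of two channels with the third fixed."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    fixed_channel: str
    fixed_value: float
    values: np.ndarray  # shape (len(axis1), len(axis2))
    gamma_a_ref: float = 1.0
    gamma_m_ref: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame({self.axis1_name: a1.ravel(),
                             self.axis2_name: a2.ravel(),
                             "I_SEIRA": self.values.ravel()})


def seira_sensitivity_reduced(f, xi, detuning, *, gamma_a_ref: float = 1.0,
                              gamma_m_ref: float = 1.0) -> np.ndarray:
    """Closed-form I_SEIRA in reduced coordinates (broadcasting).

    At omega = omega_m the oscillator term is exactly mu^2/gamma_m, so
    I_SEIRA = A(D) - A(D0) with D = -j*dw + gamma_r + gamma_a + mu^2/gamma_m,
    D0 = -j*dw + gamma_r + gamma_a and A(D) = 1 - |2 gamma_r / D - 1|^2.
    Detuning dw = omega0 - omega_m is in absolute rate units (cm^-1 when the
    references are cm^-1 rates).
    """
    f = np.asarray(f, dtype=float)
    xi = np.asarray(xi, dtype=float)
    dw = np.asarray(detuning, dtype=float)
    ga = gamma_a_ref
    gr = f * ga
    gm = gamma_m_ref
    mu2_over_gm = (xi * gm) ** 2 / gm
    gtot = gr + ga

    def absorb(extra_loss):
        d = -1j * dw + gtot + extra_loss
        return 1.0 - np.abs(2.0 * gr / d - 1.0) ** 2

    out = absorb(mu2_over_gm) - absorb(0.0)
    return float(out) if out.ndim == 0 else out


def sensitivity_map(grid: ChannelGrid, fixed_channel: str,
                    fixed_value: float) -> SensitivityMap:
    """Map I_SEIRA over the two free channels at a fixed third channel."""
    if fixed_channel not in CHANNELS:
        raise ValueError(f"fixed_channel must be one of {CHANNELS}")
    free = [c for c in CHANNELS if c != fixed_channel]
    a1, a2 = grid.axis(free[0]), grid.axis(free[1])
    coords = {fixed_channel: fixed_value,
              free[0]: a1[:, None], free[1]: a2[None, :]}
    values = seira_sensitivity_reduced(
        coords["f"], coords["xi"], coords["detuning"],
        gamma_a_ref=grid.gamma_a_ref, gamma_m_ref=grid.gamma_m_ref)
    values = np.broadcast_to(values, (a1.size, a2.size)).copy()
    return SensitivityMap(free[0], a1, free[1], a2, fixed_channel,
                          float(fixed_value), values,
                          grid.gamma_a_ref, grid.gamma_m_ref)


def optimal_detuning(map_: SensitivityMap, f: float | None = None,
                     xi: float | None = None) -> float:
    """Detuning maximizing |I_SEIRA| at given (f, xi); ties break toward 0.

    The map must contain a detuning axis; the other axis is sliced at the
    nearest grid value to the requested f or xi.
    """
    names = (map_.axis1_name, map_.axis2_name)
    if "detuning" not in names:
        raise ValueError("map has no detuning axis")
    d_axis_idx = names.index("detuning")
    other_name = names[1 - d_axis_idx]
    other_value = {"f": f, "xi": xi}[other_name]
    if other_value is None:
        raise ValueError(f"must supply {other_name} to slice the map")
    other_axis = (map_.axis1, map_.axis2)[1 - d_axis_idx]
    k = int(np.argmin(np.abs(other_axis - other_value)))
    line = map_.values[k, :] if d_axis_idx == 1 else map_.values[:, k]
    dgrid = (map_.axis1, map_.axis2)[d_axis_idx]
    mag = np.abs(line)
    top = mag.max()
    if top <= 0 or np.allclose(mag, mag[0]):
        raise ValueError("flat sensitivity line: argmax over detuning degenerate")
    winners = dgrid[np.isclose(mag, top, rtol=1e-12, atol=0.0)]
    return float(winners[np.argmin(np.abs(winners))] if winners.size > 1
                 else winners[0])


def enhancement_bandwidth(f: float, xi: float, floor_fraction: float = 0.1, *,
                          detuning_grid: np.ndarray | None = None,
                          gamma_a_ref: float = 1.0, gamma_m_ref: float = 1.0
                          ) -> tuple[float, float]:
    """Contiguous detuning interval where |I_SEIRA| >= floor * max|I_SEIRA|.

    Returns (dw_lo, dw_hi); empty coupling (xi = 0) gives a zero-width
    (nan, nan) interval.  The default detuning grid spans +/-30 resonator
    linewidths so overcoupled bandwidths are not clipped.
    """
    if not 0.0 < floor_fraction < 1.0:
        raise ValueError("floor_fraction must lie in (0, 1)")
    if xi == 0.0:
        return (float("nan"), float("nan"))
    if detuning_grid is None:
        half = 30.0 * (1.0 + f) * gamma_a_ref
        detuning_grid = np.linspace(-half, half, 4001)
    line = seira_sensitivity_reduced(f, xi, detuning_grid,
                                     gamma_a_ref=gamma_a_ref,
                                     gamma_m_ref=gamma_m_ref)
    mag = np.abs(line)
    peak = int(np.argmax(mag))
    floor = floor_fraction * mag[peak]
    lo = peak
    while lo > 0 and mag[lo - 1] >= floor:
        lo -= 1
    hi = peak
    while hi < mag.size - 1 and mag[hi + 1] >= floor:
        hi += 1
    return (float(detuning_grid[lo]), float(detuning_grid[hi]))


def bandwidth_width(f: float, xi: float, floor_fraction: float = 0.1,
                    **kwargs) -> float:
    lo, hi = enhancement_bandwidth(f, xi, floor_fraction, **kwargs)
    return 0.0 if np.isnan(lo) else hi - lo


@dataclass
class AnticrossingTrace:
    """dA-extrema branches as the resonator is swept through the line.

    ``max_dominant_deviation`` is the largest excursion of the dominant
    |dA| extremum from the molecular line over the sweep: well below the
    molecular linewidth in overcoupled devices (no anticrossing, the feature
    is pinned at omega_m), comparable to the Rabi splitting in undercoupled
    strong-coupled ones (the feature follows the avoided-crossing branches).
    """

    sweep: np.ndarray                  # omega0 values, cm^-1
    branch_positions: list[np.ndarray]  # extremum locations per sweep point
    dominant_positions: np.ndarray     # location of the global |dA| max
    min_branch_separation: float       # smallest gap between coexisting branches
    omega_m: float = float("nan")
    max_dominant_deviation: float = float("nan")


class ResolutionError(ValueError):
    pass


def anticrossing_diagnostic(f: float, xi: float,
                            sweep_range: tuple[float, float] = (-15.0, 15.0),
                            n_sweep: int = 61, *,
                            gamma_a_ref: float = 1.0, gamma_m_ref: float = 1.0,
                            n_grid: int = 4001,
                            min_prominence_fraction: float = 0.01
                            ) -> AnticrossingTrace:
    """Trace dA extrema while sweeping omega0 through omega_m.

    Undercoupled strong-coupled devices show two branches that avoid crossing
    (min_branch_separation > 0); in overcoupled devices the dominant feature
    tracks the molecular line — no anticrossing, i.e. no Fano distortion.
    Sweep range and evaluation grid are in gamma_m units around the line.
    """
    lo, hi = sweep_range
    if not lo < 0 < hi:
        raise ValueError("sweep_range must straddle the molecular line (0)")
    base = system_from_ratios(f, xi, 0.0, gamma_a_ref=gamma_a_ref,
                              gamma_m_ref=gamma_m_ref)
    omega_m = base.oscillators[0].omega_m
    sweep = omega_m + np.linspace(lo, hi, n_sweep) * gamma_m_ref
    span = max(4.0 * (1.0 + f) * gamma_a_ref,
               abs(lo) * gamma_m_ref, abs(hi) * gamma_m_ref) + 10.0 * gamma_m_ref
    grid = np.linspace(omega_m - span, omega_m + span, n_grid)

    branches: list[np.ndarray] = []
    dominant = np.empty(sweep.size)
    min_sep = np.inf
    for i, w0 in enumerate(sweep):
        system = base.with_detuning(w0 - omega_m)
        da = delta_values(system, grid)
        mag = np.abs(da)
        top = mag.max()
        if top == 0:
            branches.append(np.array([]))
            dominant[i] = np.nan
            continue
        idx, _ = _scipy_find_peaks(mag, prominence=min_prominence_fraction * top)
        if idx.size == 0:
            raise ResolutionError("no dA extrema resolved; refine the grid")
        pos = np.sort(grid[idx])
        branches.append(pos)
        dominant[i] = grid[int(np.argmax(mag))]
        if pos.size >= 2:
            min_sep = min(min_sep, float(np.min(np.diff(pos))))
    if not np.isfinite(min_sep):
        min_sep = 0.0
    finite = np.abs(dominant[np.isfinite(dominant)] - omega_m)
    deviation = float(finite.max()) if finite.size else float("nan")
    return AnticrossingTrace(sweep, branches, dominant, min_sep, omega_m,
                             deviation)
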