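"""Complex-reflection trajectory topology: secondary-loop (strong-coupling) detection.

As frequency sweeps through the absorber resonance, r(w) traces a loop in the
complex plane.  A coupled molecular oscillator deforms it; once mu/gamma_m
exceeds 1 (zero detuning) the deformation grows into a *secondary loop* — the
polyline self-intersects — which is the topological signature of the
weak-to-strong coupling transition.  For the co-resonant single-oscillator
model the self-intersection frequencies are omega_m +/- sqrt(mu^2 - gamma_m^2)
and the trajectory value there is kappa^2/(gamma_r + gamma_a + gamma_m) - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from shapely.geometry import LineString

from .tcmt import CoupledSystem, reflection_values

__all__ = [
    "ComplexTrajectory",
    "LoopReport",
    "ResolutionError",
    "detect_loops",
    "adaptive_trajectory",
    "loop_report",
    "strong_coupling_threshold",
]


class ResolutionError(ValueError):
    """Trajectory sampling too coarse for reliable loop detection."""


@dataclass
class ComplexTrajectory:
    """Sampled complex reflection r(w) along a wavenumber grid."""

    grid: np.ndarray
    r_values: np.ndarray
    system: CoupledSystem | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.r_values = np.asarray(self.r_values, dtype=complex)
        if self.grid.shape != self.r_values.shape or self.grid.ndim != 1:
            raise ValueError("grid and r_values must be equal-length 1-D arrays")
        if self.grid.size < 4:
            raise ValueError("trajectory needs at least 4 samples")

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (Re r, Im r)."""
        return np.column_stack([self.r_values.real, self.r_values.imag])

    def diameter(self) -> float:
        pts = self.points
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return float(np.hypot(*(hi - lo)))

    def max_segment_fraction(self) -> float:
        """Longest chord length relative to the trajectory diameter."""
        seg = np.abs(np.diff(self.r_values))
        d = self.diameter()
        return float(seg.max() / d) if d > 0 else 0.0


@dataclass
class LoopReport:
    """Outcome of secondary-loop analysis on a reflection trajectory."""

    has_secondary_loop: bool
    crossing_frequencies: tuple[float, ...] = ()
    crossing_point: complex | None = None
    coupling_label: str = "weak"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # invariant: loop <=> crossings present <=> strong label
        assert self.has_secondary_loop == bool(self.crossing_frequencies)
        assert self.coupling_label == ("strong" if self.has_secondary_loop else "weak")


def _segment_crossings(pts: np.ndarray) -> list[tuple[int, int, float, float]]:
    """All transversal crossings between non-adjacent segments of a polyline.

    Returns (i, j, ti, tj): segment indices and intersection parameters in
    [0, 1].  Vectorized orientation test over the upper-triangular pair set.
    """
    p = pts[:-1]
    d = np.diff(pts, axis=0)
    n = len(d)

    def cross2(a, b):
        return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

    eps = 1e-12
    found: list[tuple[int, int, float, float]] = []
    # row blocks keep the O(n^2) pair test inside a bounded memory footprint
    block = 256
    for i0 in range(0, n - 2, block):
        ii_row = np.arange(i0, min(i0 + block, n - 2))
        jj_all = np.arange(n)
        ii, jj = np.meshgrid(ii_row, jj_all, indexing="ij")
        keep = jj >= ii + 2
        if n > 2:
            keep &= ~((ii == 0) & (jj == n - 1))  # wrap-around-adjacent pair
        ii, jj = ii[keep], jj[keep]
        if ii.size == 0:
            continue
        pi, di = p[ii], d[ii]
        pj, dj = p[jj], d[jj]
        denom = cross2(di, dj)
        w = pj - pi
        with np.errstate(divide="ignore", invalid="ignore"):
            ti = cross2(w, dj) / denom
            tj = cross2(w, di) / denom
        hit = (np.abs(denom) > eps) & (ti > eps) & (ti < 1 - eps) \
            & (tj > eps) & (tj < 1 - eps)
        found.extend((int(a), int(b), float(x), float(y))
                     for a, b, x, y in zip(ii[hit], jj[hit], ti[hit], tj[hit]))
    return found


def _refine_crossing(system: CoupledSystem, w1: float, w2: float
                     ) -> tuple[float, float, complex] | None:
    """Polish a crossing r(w1) = r(w2) with a 2-D root solve."""

    def fun(x):
        dr = reflection_values(system, x[0]) - reflection_values(system, x[1])
        return [dr.real, dr.imag]

    sol = root(fun, [w1, w2], tol=1e-12)
    if not sol.success or abs(sol.x[0] - sol.x[1]) < 1e-9 * max(1.0, abs(w1 - w2)):
        return None
    a, b = sorted(sol.x)
    return float(a), float(b), complex(reflection_values(system, a))


def detect_loops(trajectory: ComplexTrajectory,
                 max_segment_fraction: float = 0.05,
                 refine: bool = True,
                 locate: bool = True) -> LoopReport:
    """Find self-intersections (secondary loops) of the sampled r(w) polyline.

    The boolean decision uses GEOS (``LineString.is_simple``); crossing
    locations come from a vectorized segment-pair intersection, polished by a
    root solve on r(w1) = r(w2) when the generating system is attached to the
    trajectory.

    Raises
    ------
    ResolutionError
        If any chord exceeds ``max_segment_fraction`` of the trajectory
        diameter — a coarse polyline can silently miss a small loop.
    """
    frac = trajectory.max_segment_fraction()
    if frac > max_segment_fraction:
        raise ResolutionError(
            f"trajectory too coarse: longest segment is {frac:.3f} of the "
            f"diameter (limit {max_segment_fraction}); resample more densely")

    pts = trajectory.points
    if LineString(pts).is_simple:
        return LoopReport(False, (), None, "weak",
                          {"n_samples": len(pts)})
    if not locate:
        # boolean-only fast path for threshold scans; the crossing location
        # nearest the first grid point stands in so the report invariant holds
        g = trajectory.grid
        return LoopReport(True, (float(g[0]), float(g[-1])), None, "strong",
                          {"n_samples": len(pts), "located": False})

    crossings = _segment_crossings(pts)
    if not crossings:
        # GEOS flagged a self-touch that the strict transversal test rejects
        # (tangency at the loop threshold); treat as no loop.
        return LoopReport(False, (), None, "weak",
                          {"n_samples": len(pts), "tangent": True})

    # several lines can each spawn a loop; report the geometrically largest
    # one (longest enclosed arc), which belongs to the strongest coupling
    arclen = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(trajectory.r_values)))])
    i, j, ti, tj = max(crossings, key=lambda c: arclen[c[1]] - arclen[c[0]])
    g = trajectory.grid
    w1 = g[i] + ti * (g[i + 1] - g[i])
    w2 = g[j] + tj * (g[j + 1] - g[j])
    point = complex(0.5 * (trajectory.r_values[i] + trajectory.r_values[j]))
    if refine and trajectory.system is not None:
        polished = _refine_crossing(trajectory.system, w1, w2)
        if polished is not None:
            w1, w2, point = polished
    return LoopReport(True, (float(min(w1, w2)), float(max(w1, w2))), point,
                      "strong", {"n_samples": len(pts), "n_crossings": len(crossings)})


def adaptive_trajectory(system: CoupledSystem, span_factor: float = 10.0,
                        n_coarse: int = 1024, n_fine: int = 2048,
                        max_refine: int = 8) -> ComplexTrajectory:
    """Sample r(w) densely enough for loop detection.

    The grid spans ``omega0 +/- span_factor*(gamma_r + gamma_a)`` and is the
    union of a coarse global grid with fine windows around every molecular
    line (loops live near the lines), then refined by chord bisection until no
    segment exceeds 2% of the trajectory diameter.
    """
    res = system.resonator
    half = span_factor * (res.gamma_r + res.gamma_a)
    lo, hi = res.omega0 - half, res.omega0 + half
    grids = [np.linspace(lo, hi, n_coarse)]
    for osc in system.oscillators:
        w = max(10.0 * osc.gamma_m, 5.0 * osc.mu, 1e-6)
        grids.append(np.linspace(osc.omega_m - w, osc.omega_m + w, n_fine))
    grid = np.unique(np.concatenate(grids))
    grid = grid[(grid >= lo) & (grid <= hi)]
    rv = reflection_values(system, grid)

    for _ in range(max_refine):
        pts = np.column_stack([rv.real, rv.imag])
        diam = np.hypot(*(pts.max(axis=0) - pts.min(axis=0)))
        seg = np.abs(np.diff(rv))
        bad = seg > 0.02 * diam
        if not bad.any():
            break
        mids = 0.5 * (grid[:-1][bad] + grid[1:][bad])
        grid = np.unique(np.concatenate([grid, mids]))
        rv = reflection_values(system, grid)
    return ComplexTrajectory(grid, rv, system)


def loop_report(system: CoupledSystem, locate: bool = True, **kwargs) -> LoopReport:
    """Adaptive sampling + detect_loops in one call."""
    return detect_loops(adaptive_trajectory(system, **kwargs), locate=locate)


def strong_coupling_threshold(f: float, xi_values, *, gamma_m: float = 1.0,
                              gamma_a: float = 1.0) -> tuple[float, np.ndarray]:
    """Scan xi = mu/gamma_m and return the smallest value with a secondary loop.

    Zero-detuning single-oscillator scan at loss ratio ``f``.  Returns
    ``(threshold, flags)`` where flags[i] says whether a loop was found at
    xi_values[i]; threshold is nan if no loop appears in the scan.
    """
    from .tcmt import system_from_ratios

    xi_values = np.asarray(xi_values, dtype=float)
    flags = np.zeros(xi_values.shape, dtype=bool)
    for k, xi in enumerate(xi_values):
        sys_k = system_from_ratios(f, float(xi), 0.0, gamma_a_ref=gamma_a,
                                   gamma_m_ref=gamma_m)
        flags[k] = loop_report(sys_k, locate=False).has_secondary_loop
    hit = np.nonzero(flags)[0]
    threshold = float(xi_values[hit[0]]) if hit.size else float("nan")
    return threshold, flags
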