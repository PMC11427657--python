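"""Spectrum utilities: unit conversion, AsLS baseline extraction, derivatives,
peak finding and file I/O.

The central measurement-side operation is asymmetric least squares smoothing
(AsLS, Eilers-Boelens): the broad absorber resonance is the baseline, the
narrow molecular vibrations are the features riding on it, and subtracting the
estimated baseline recovers the enhanced-signal difference spectrum dA from a
single measured absorbance spectrum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import savgol_filter

from .tcmt import Spectrum

__all__ = [
    "wavelength_to_wavenumber",
    "wavenumber_to_wavelength",
    "unit_sensitivity",
    "AslsConfig",
    "AslsBaseline",
    "asls_baseline",
    "extract_difference",
    "DerivativeConfig",
    "SavgolDerivative",
    "derivative_spectrum",
    "find_peaks",
    "read_spectrum",
    "write_spectrum",
]


# ---------------------------------------------------------------- conversions

def wavelength_to_wavenumber(wavelength_um):
    """Convert wavelength (um) to wavenumber (cm^-1): wn = 10000/wl."""
    wl = np.asarray(wavelength_um, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    out = 10000.0 / wl
    return float(out) if out.ndim == 0 else out


def wavenumber_to_wavelength(wavenumber_cm):
    """Inverse of :func:`wavelength_to_wavenumber` (the map is an involution)."""
    return wavelength_to_wavenumber(wavenumber_cm)


def unit_sensitivity(contrast_percent: float, thickness_nm: float) -> float:
    """Per-thickness sensitivity, % per nm: peak dA contrast / film thickness.

    E.g. a 58% C=O contrast over an 8 nm film gives 7.25 % nm^-1.
    """
    if thickness_nm <= 0:
        raise ValueError("thickness must be positive")
    return contrast_percent / thickness_nm


# ------------------------------------------------------------------ baseline

@dataclass
class AslsConfig:
    """AsLS settings.

    smoothness : penalty weight lambda on squared second differences (> 0).
        Default 1e4 on 4 cm^-1-class grids: stiff enough to ride over
        molecular lines (FWHM ~ 20 cm^-1) yet compliant enough to follow the
        absorber envelope (FWHM ~ hundreds of cm^-1) to well under 1%.
    asymmetry : weight p in (0, 1) given to points above the baseline.
        Small p treats upward excursions as features (overcoupled devices,
        molecular peaks point up); use 1-p for undercoupled devices where the
        signatures are dips.
    """

    smoothness: float = 1e4
    asymmetry: float = 0.01
    max_iterations: int = 30
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.smoothness > 0:
            raise ValueError("smoothness (lambda) must be > 0")
        if not 0.0 < self.asymmetry < 1.0:
            raise ValueError("asymmetry (p) must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class ConvergenceError(RuntimeError):
    def __init__(self, msg, baseline=None, history=None):
        super().__init__(msg)
        self.baseline = baseline
        self.history = history


class AslsBaseline:
    """Asymmetric-least-squares baseline estimator (Eilers-Boelens scheme).

    sklearn-style transformer over spectra: ``fit`` estimates the baseline of
    each row of X (or of a single 1-D signal), ``transform`` subtracts it.
    The baseline z minimizes sum_i w_i (y_i - z_i)^2 + lam * sum (D2 z)^2 with
    w_i = p where y_i > z_i else 1-p, iterated to convergence.

    Parameters mirror :class:`AslsConfig`.
    """

    def __init__(self, smoothness: float = 1e4, asymmetry: float = 0.01,
                 max_iterations: int = 30, convergence_tol: float = 1e-6):
        self.smoothness = smoothness
        self.asymmetry = asymmetry
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"smoothness": self.smoothness, "asymmetry": self.asymmetry,
                "max_iterations": self.max_iterations,
                "convergence_tol": self.convergence_tol}

    def set_params(self, **params) -> "AslsBaseline":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core ---------------------------------------------------------------
    def _solve_one(self, y: np.ndarray) -> np.ndarray:
        cfg = AslsConfig(self.smoothness, self.asymmetry,
                         self.max_iterations, self.convergence_tol)
        n = y.size
        if n < 4:
            raise ValueError("signal too short for second-difference penalty")
        d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
        penalty = (cfg.smoothness * (d2.T @ d2)).tocsc()
        # banded (pentadiagonal) Cholesky solve; upper form for solveh_banded
        pen_banded = np.zeros((3, n))
        dense = penalty.todia()
        for off, row in zip(dense.offsets, dense.data):
            if off >= 0:
                pen_banded[2 - off] = row
        w = np.ones(n)
        z = y.copy()
        history = []
        for _ in range(cfg.max_iterations):
            ab = pen_banded.copy()
            ab[2] += w
            z_new = solveh_banded(ab, w * y, lower=False)
            change = np.linalg.norm(z_new - z) / max(np.linalg.norm(z), 1e-300)
            history.append(change)
            z = z_new
            w = np.where(y > z, cfg.asymmetry, 1.0 - cfg.asymmetry)
            if change < cfg.convergence_tol:
                return z
        if history and history[-1] < 100 * cfg.convergence_tol:
            # weight flips on a few noise points keep the iteration jittering
            # without moving the baseline; accept the last iterate
            return z
        raise ConvergenceError(
            f"AsLS did not converge in {cfg.max_iterations} iterations "
            f"(last relative change {history[-1]:.2e})", baseline=z,
            history=history)

    def fit(self, X, y=None) -> "AslsBaseline":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.baseline_ = np.vstack([self._solve_one(row) for row in X])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        # nothing is learned from training data: the baseline is re-estimated
        # per spectrum, so transform works on unseen rows too
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X - np.vstack([self._solve_one(row) for row in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return np.atleast_2d(np.asarray(X, dtype=float)) - self.baseline_


def asls_baseline(spectrum: Spectrum, config: AslsConfig | None = None) -> Spectrum:
    """Estimate the smooth baseline of an absorbance spectrum (kind='baseline')."""
    if spectrum.kind != "absorbance":
        raise ValueError(f"asls_baseline expects an absorbance spectrum, "
                         f"got kind={spectrum.kind!r}")
    cfg = config or AslsConfig()
    est = AslsBaseline(cfg.smoothness, cfg.asymmetry, cfg.max_iterations,
                       cfg.convergence_tol)
    est.fit(spectrum.values[None, :])
    return spectrum.copy_with(est.baseline_[0], "baseline",
                              asls=dict(smoothness=cfg.smoothness,
                                        asymmetry=cfg.asymmetry))


def extract_difference(spectrum: Spectrum, config: AslsConfig | None = None,
                       regime: str = "OC") -> Spectrum:
    """Baseline-subtract a measured absorbance spectrum -> difference spectrum dA.

    In overcoupled (OC) devices molecular signatures are upward peaks, so the
    baseline hugs the spectrum from below (small p); undercoupled (UC) devices
    produce dips, handled by flipping the asymmetry weight.
    """
    cfg = config or AslsConfig()
    if regime == "UC":
        cfg = AslsConfig(cfg.smoothness, 1.0 - cfg.asymmetry,
                         cfg.max_iterations, cfg.convergence_tol)
    elif regime not in ("OC", "critical"):
        raise ValueError("regime must be 'OC', 'UC' or 'critical'")
    base = asls_baseline(spectrum, cfg)
    return spectrum.copy_with(spectrum.values - base.values, "difference",
                              baseline="asls", regime=regime)


# --------------------------------------------------------------- derivatives

@dataclass
class DerivativeConfig:
    """Savitzky-Golay derivative settings: default 11-point cubic window,
    matched to 4 cm^-1-class FTIR grids."""

    window_points: int = 11
    poly_order: int = 3
    order: int = 1

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0:
            raise ValueError("window_points must be odd")
        if self.order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        if self.order > self.poly_order:
            raise ValueError("order must not exceed poly_order")
        if self.window_points < self.poly_order + 2:
            raise ValueError("window_points must be >= poly_order + 2")


class SavgolDerivative:
    """Savitzky-Golay derivative as an sklearn-style stateless transformer."""

    def __init__(self, window_points: int = 11, poly_order: int = 3,
                 order: int = 1, delta: float = 1.0):
        self.window_points = window_points
        self.poly_order = poly_order
        self.order = order
        self.delta = delta

    def get_params(self, deep: bool = True) -> dict:
        return {"window_points": self.window_points,
                "poly_order": self.poly_order, "order": self.order,
                "delta": self.delta}

    def set_params(self, **params) -> "SavgolDerivative":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "SavgolDerivative":
        DerivativeConfig(self.window_points, self.poly_order, self.order)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.window_points > X.shape[1]:
            raise ValueError("window larger than spectrum")
        return savgol_filter(X, self.window_points, self.poly_order,
                             deriv=self.order, delta=self.delta, axis=1)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def derivative_spectrum(spectrum: Spectrum,
                        config: DerivativeConfig | None = None) -> Spectrum:
    """Savitzky-Golay derivative of a spectrum (uniform grid required).

    Non-uniform grids are linearly resampled onto a uniform grid of the same
    length first.
    """
    cfg = config or DerivativeConfig()
    spec = spectrum
    if not spectrum.is_uniform():
        uni = np.linspace(spectrum.grid[0], spectrum.grid[-1], len(spectrum))
        spec = Spectrum(uni, np.interp(uni, spectrum.grid, spectrum.values),
                        spectrum.kind, {**spectrum.meta, "resampled": True})
    t = SavgolDerivative(cfg.window_points, cfg.poly_order, cfg.order,
                         delta=spec.spacing)
    vals = t.fit_transform(spec.values[None, :])[0]
    return spec.copy_with(vals, f"derivative{cfg.order}",
                          savgol=dict(window=cfg.window_points,
                                      poly=cfg.poly_order))


# ------------------------------------------------------------------ peaks

def find_peaks(spectrum: Spectrum, min_prominence: float = 0.0) -> pd.DataFrame:
    """Local maxima above a prominence floor, with 3-point parabolic refinement.

    Returns a DataFrame with columns position_cm1, height, prominence (possibly
    empty).
    """
    y = spectrum.values
    idx, props = _scipy_find_peaks(y, prominence=min_prominence or None)
    rows = []
    for k, i in enumerate(idx):
        pos = spectrum.grid[i]
        height = y[i]
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom != 0:
                shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
                if abs(shift) <= 1:
                    pos = np.interp(i + shift, np.arange(len(y)), spectrum.grid)
                    height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * shift
        prom = props["prominences"][k] if "prominences" in props else np.nan
        rows.append((float(pos), float(height), float(prom)))
    return pd.DataFrame(rows, columns=["position_cm1", "height", "prominence"])


# ---------------------------------------------------------------------- I/O

_HEADER = "wavenumber_cm-1"


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Two-column CSV (wavenumber_cm-1, value) with a '#'-comment header."""
    with open(path, "w") as fh:
        fh.write(f"# kind={spectrum.kind}\n")
        for key, val in spectrum.meta.items():
            if isinstance(val, (str, int, float, bool)):
                fh.write(f"# {key}={val}\n")
        fh.write(f"{_HEADER},value\n")
        for w, v in zip(spectrum.grid, spectrum.values):
            fh.write(f"{w:.10g},{v:.12g}\n")


def _read_csv_spectrum(path) -> Spectrum:
    kind = "absorbance"
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    header_seen = False
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = re.match(r"#\s*(\w[\w.-]*)=(.*)", s)
            if m:
                key, val = m.group(1), m.group(2).strip()
                if key == "kind":
                    kind = val
                else:
                    meta[key] = val
            continue
        if not header_seen:
            cols = [c.strip() for c in s.split(",")]
            if cols[0] != _HEADER or len(cols) < 2:
                raise ValueError(
                    f"malformed header {s!r}: expected '{_HEADER},value'")
            header_seen = True
            continue
        data_lines.append(s)
    if not header_seen:
        raise ValueError(f"no '{_HEADER},value' header found in {path}")
    rows = [tuple(float(x) for x in ln.split(",")[:2]) for ln in data_lines]
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected two numeric columns")
    return _ordered_spectrum(arr[:, 0], arr[:, 1], kind, meta)


def _ordered_spectrum(grid, values, kind, meta) -> Spectrum:
    order = np.argsort(grid)
    grid, values = np.asarray(grid)[order], np.asarray(values)[order]
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavenumber grid has duplicate points")
    return Spectrum(grid, values, kind, meta)


def _read_jcamp_spectrum(path) -> Spectrum:
    """Minimal JCAMP-DX reader for the ##XYDATA=(X++(Y..Y)) form.

    Each data line carries a leading X value followed by equally spaced Y
    values at the declared DELTAX; YFACTOR/XFACTOR scaling is honoured.
    Descending X is reordered ascending.
    """
    meta: dict = {}
    xfac = yfac = 1.0
    deltax = None
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XYDATA":
                    if "X++(Y..Y)" not in val:
                        raise ValueError(f"unsupported XYDATA form {val!r}")
                    in_data = True
                    continue
                in_data = False
                if key == "XFACTOR":
                    xfac = float(val)
                elif key == "YFACTOR":
                    yfac = float(val)
                elif key == "DELTAX":
                    deltax = float(val)
                elif key == "END":
                    break
                else:
                    meta[key.lower()] = val
                continue
            if in_data:
                toks = re.split(r"[,\s]+", line)
                nums = [float(t) for t in toks if t]
                if len(nums) < 2:
                    raise ValueError(f"malformed JCAMP data line {line!r}")
                x0 = nums[0] * xfac
                yvals = [n * yfac for n in nums[1:]]
                if deltax is None:
                    raise ValueError("##DELTAX missing before data block")
                for k, yv in enumerate(yvals):
                    xs.append(x0 + k * deltax * xfac)
                    ys.append(yv)
    if not xs:
        raise ValueError(f"no XYDATA block found in {path}")
    return _ordered_spectrum(np.array(xs), np.array(ys), "absorbance", meta)


def read_spectrum(path, dialect: str = "auto") -> Spectrum:
    """Read a spectrum from two-column CSV or a JCAMP-DX subset.

    dialect: 'csv', 'jcamp' or 'auto' (sniff: JCAMP files start with '##').
    """
    if dialect == "auto":
        with open(path) as fh:
            first = fh.readline()
        dialect = "jcamp" if first.startswith("##") else "csv"
    if dialect == "csv":
        return _read_csv_spectrum(path)
    if dialect == "jcamp":
        return _read_jcamp_spectrum(path)
    raise ValueError(f"unknown dialect {dialect!r}")
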