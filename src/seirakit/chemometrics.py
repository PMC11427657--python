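"""Multivariate analysis of enhanced-signal spectra.

PCA for visual separation, a linear-kernel SVM (C = 1.0, one-vs-rest,
seeded 80/20 split) for molecule identification, non-negative least squares
for mixture unmixing/spectral reconstruction, a small dense network (3 x 64
rectified-linear hidden layers, two linear outputs, squared-error objective)
for two-component concentration regression with a deterministic NNLS linear
backend, and Amide-I second-derivative band integration for protein
secondary-structure summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC

from .synthetic import SpectraMatrix
from .tcmt import Spectrum

__all__ = [
    "pca_scores",
    "SpectrumClassifier",
    "train_classifier",
    "UnmixResult",
    "nnls_unmix",
    "ConcentrationRegressor",
    "regress_concentrations",
    "AMIDE_I_BANDS",
    "secondary_structure",
    "StructureSummary",
]


# ------------------------------------------------------------------------ PCA

def pca_scores(matrix: SpectraMatrix, n_components: int = 2):
    """Mean-centred PCA of the spectra rows.

    Returns (scores, loadings, explained_variance); scores are orthogonal and
    the variances are non-increasing.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components exceeds min(rows - 1, columns)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.components_, pca.explained_variance_


# --------------------------------------------------------------- classifier

class SpectrumClassifier:
    """Linear max-margin molecule classifier over spectra rows.

    One-vs-rest linear-kernel SVM with regularization C (default 1.0); the
    train/test split (default 80/20, stratified) is seeded.
    """

    def __init__(self, split_fraction: float = 0.8,
                 regularization_c: float = 1.0, seed: int = 0):
        self.split_fraction = split_fraction
        self.regularization_c = regularization_c
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"split_fraction": self.split_fraction,
                "regularization_c": self.regularization_c, "seed": self.seed}

    def set_params(self, **params) -> "SpectrumClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "SpectrumClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=self.split_fraction, stratify=y,
            random_state=self.seed)
        self.model_ = OneVsRestClassifier(
            SVC(kernel="linear", C=self.regularization_c))
        self.model_.fit(Xtr, ytr)
        self.classes_ = self.model_.classes_
        self.test_accuracy_ = float(np.mean(self.model_.predict(Xte) == yte))
        self.train_indices_ = None  # split is by sample, no row reuse
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=float))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_classifier(matrix: SpectraMatrix, split_fraction: float = 0.8,
                     regularization_c: float = 1.0, seed: int = 0,
                     label_column: str | None = None
                     ) -> tuple[SpectrumClassifier, float]:
    """Train the molecule classifier on a labelled SpectraMatrix.

    Returns (fitted classifier, held-out accuracy).
    """
    col = label_column or matrix.labels.columns[0]
    clf = SpectrumClassifier(split_fraction, regularization_c, seed)
    clf.fit(matrix.values, matrix.labels[col].to_numpy())
    return clf, clf.test_accuracy_


# ------------------------------------------------------------------ unmixing

@dataclass
class UnmixResult:
    """Non-negative decomposition of a mixture spectrum onto references."""

    weights: np.ndarray
    reconstructed: Spectrum
    mse: float
    reference_names: tuple[str, ...] = ()


def nnls_unmix(mixture: Spectrum, references: SpectraMatrix) -> UnmixResult:
    """Non-negative least squares: mixture ~= sum_i w_i * reference_i.

    The references must share the mixture grid exactly; mse is the mean
    squared residual of the reconstruction.
    """
    if len(references) < 1:
        raise ValueError("need at least one reference spectrum")
    if references.grid.shape != mixture.grid.shape or \
            not np.allclose(references.grid, mixture.grid):
        raise ValueError("references and mixture are on different grids")
    A = references.values.T
    w, _ = _nnls(A, mixture.values)
    recon = A @ w
    mse = float(np.mean((mixture.values - recon) ** 2))
    names = tuple(str(v) for v in references.labels.iloc[:, 0]) \
        if len(references.labels.columns) else ()
    return UnmixResult(w, mixture.copy_with(recon, mixture.kind,
                                            reconstruction="nnls"),
                       mse, names)


# -------------------------------------------------------------- regression

class ConcentrationRegressor:
    """Two-output concentration regression over spectra rows.

    backend='mlp': dense network, hidden layers (64, 64, 64) with rectified
    linear units, linear outputs, adam on squared error — fully seeded.
    backend='linear': deterministic NNLS against reference (pure-component)
    spectra; exact on noiseless linear mixtures.

    Reported error is the mean over held-out samples of the L1 concentration
    error divided by the true total, in percent.
    """

    def __init__(self, backend: str = "mlp",
                 hidden_layer_sizes: tuple[int, ...] = (64, 64, 64),
                 epochs: int = 200, batch_size: int = 16,
                 learning_rate: float = 1e-3, split_fraction: float = 0.8,
                 seed: int = 0):
        self.backend = backend
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.split_fraction = split_fraction
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"backend": self.backend,
                "hidden_layer_sizes": self.hidden_layer_sizes,
                "epochs": self.epochs, "batch_size": self.batch_size,
                "learning_rate": self.learning_rate,
                "split_fraction": self.split_fraction, "seed": self.seed}

    def set_params(self, **params) -> "ConcentrationRegressor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _fit_linear(self, X, y):
        # reference responses: least-squares solution of X ~ y @ R maps
        # concentrations to spectra; prediction inverts it per sample by NNLS
        coef, *_ = np.linalg.lstsq(y, X, rcond=None)
        self.reference_responses_ = coef  # (n_outputs, n_points)

    def _predict_linear(self, X):
        A = self.reference_responses_.T
        return np.vstack([_nnls(A, row)[0] for row in X])

    def fit(self, X, y) -> "ConcentrationRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ValueError("y must be (n_samples, n_outputs) concentrations")
        if np.any(~np.isfinite(y)):
            raise ValueError("labels contain missing values")
        rng_state = self.seed
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=self.split_fraction, random_state=rng_state)
        if self.backend == "mlp":
            self.model_ = MLPRegressor(
                hidden_layer_sizes=self.hidden_layer_sizes,
                activation="relu", solver="adam",
                learning_rate_init=self.learning_rate,
                batch_size=self.batch_size, max_iter=self.epochs,
                random_state=rng_state, tol=0.0, n_iter_no_change=self.epochs)
            self.model_.fit(Xtr, ytr)
        elif self.backend == "linear":
            self._fit_linear(Xtr, ytr)
        else:
            raise ValueError("backend must be 'mlp' or 'linear'")
        pred = self.predict(Xte)
        denom = np.clip(np.abs(yte).sum(axis=1), 1e-12, None)
        self.test_error_percent_ = float(
            100.0 * np.mean(np.abs(pred - yte).sum(axis=1) / denom))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.backend == "mlp":
            return self.model_.predict(X)
        return self._predict_linear(X)


def regress_concentrations(matrix: SpectraMatrix, backend: str = "mlp",
                           seed: int = 0, **kwargs
                           ) -> tuple[ConcentrationRegressor, float]:
    """Fit a two-output concentration regressor on a titration SpectraMatrix.

    Labels are taken from all label columns (concentration pairs).  Returns
    (fitted regressor, held-out mean percentage error).
    """
    y = matrix.labels.to_numpy(dtype=float)
    reg = ConcentrationRegressor(backend=backend, seed=seed, **kwargs)
    reg.fit(matrix.values, y)
    return reg, reg.test_error_percent_


# ----------------------------------------------------- secondary structure

# Amide I sub-band windows (cm^-1); alpha-helix centred on 1657, beta-sheet
# the low- and high-frequency flanks; remainder of 1600-1700 is "other"
AMIDE_I_BANDS: dict[str, tuple[tuple[float, float], ...]] = {
    "alpha_helix": ((1648.0, 1660.0),),
    "beta_sheet": ((1620.0, 1640.0), (1670.0, 1690.0)),
}


@dataclass
class StructureSummary:
    """Relative Amide-I band areas; fractions sum to 1."""

    band_fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.band_fractions.values())
        assert abs(total - 1.0) < 1e-9 or total == 0.0


def secondary_structure(second_derivative: Spectrum,
                        band_table: dict | None = None) -> StructureSummary:
    """Integrate |negative lobes| of the Amide-I second derivative per band.

    Second-derivative minima mark sub-band positions; the magnitude of the
    negative lobe within each window is a standard proxy for the secondary-
    structure content.  Windows outside 1600-1700 cm^-1 are ignored; the
    unassigned remainder of the Amide-I region is reported as 'other'.
    """
    if second_derivative.kind != "derivative2":
        raise ValueError("secondary_structure expects a derivative2 spectrum")
    g = second_derivative.grid
    if g[0] > 1600.0 or g[-1] < 1700.0:
        raise ValueError("grid does not cover the Amide I region "
                         "(1600-1700 cm^-1)")
    bands = band_table or AMIDE_I_BANDS
    lobe = np.clip(-second_derivative.values, 0.0, None)
    region = (g >= 1600.0) & (g <= 1700.0)
    total = float(np.trapezoid(lobe[region], g[region]))
    if total <= 0:
        return StructureSummary({**{k: 0.0 for k in bands}, "other": 0.0})
    areas = {}
    assigned = 0.0
    for name, windows in bands.items():
        a = 0.0
        for lo, hi in windows:
            m = region & (g >= lo) & (g <= hi)
            if m.sum() >= 2:
                a += float(np.trapezoid(lobe[m], g[m]))
        areas[name] = a
        assigned += a
    areas["other"] = max(total - assigned, 0.0)
    norm = sum(areas.values())
    return StructureSummary({k: v / norm for k, v in areas.items()})
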