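"""PCA, classification, unmixing, concentration regression, secondary structure."""

import numpy as np
import pandas as pd
import pytest

from seirakit.chemometrics import (ConcentrationRegressor, SpectrumClassifier,
                                   nnls_unmix, pca_scores,
                                   regress_concentrations, secondary_structure,
                                   train_classifier)
from seirakit.spectral import (AslsBaseline, DerivativeConfig,
                               derivative_spectrum, extract_difference)
from seirakit.synthetic import (NoiseModel, SpectraMatrix, make_system,
                                simulate_classification_dataset,
                                simulate_measurement,
                                simulate_titration_dataset)
from seirakit.tcmt import Spectrum


def _matrix(grid, rows, labels=None):
    lab = pd.DataFrame({"label": labels if labels is not None
                        else [""] * len(rows)})
    return SpectraMatrix(grid, np.vstack(rows), lab)


class TestPca:
    def test_identical_rows_zero_variance(self, rng):
        grid = np.linspace(1000.0, 2000.0, 200)
        row = rng.uniform(size=200)
        scores, _, var = pca_scores(_matrix(grid, [row] * 5), 2)
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)
        np.testing.assert_allclose(var, 0.0, atol=1e-12)

    def test_disjoint_fingerprints_separate_on_first_component(self, rng):
        grid = np.linspace(1000.0, 2000.0, 500)
        a = np.exp(-0.5 * ((grid - 1200.0) / 20.0) ** 2)
        b = np.exp(-0.5 * ((grid - 1800.0) / 20.0) ** 2)
        rows = [a + 0.01 * rng.normal(size=500) for _ in range(10)] + \
               [b + 0.01 * rng.normal(size=500) for _ in range(10)]
        scores, _, _ = pca_scores(_matrix(grid, rows), 2)
        signs = np.sign(scores[:, 0])
        assert len(set(signs[:10])) == 1 and len(set(signs[10:])) == 1
        assert signs[0] != signs[-1]

    def test_full_rank_reconstruction_and_variance_sum(self, rng):
        grid = np.linspace(0.0, 10.0, 40) + 1.0
        X = rng.normal(size=(6, 40))
        scores, loadings, var = pca_scores(_matrix(grid, X), 5)
        recon = scores @ loadings + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-10)
        total = np.var(X, axis=0, ddof=1).sum()
        assert var.sum() == pytest.approx(total, rel=1e-10)

    def test_too_few_rows(self):
        grid = np.linspace(0.0, 10.0, 20) + 1.0
        with pytest.raises(ValueError):
            pca_scores(_matrix(grid, [np.zeros(20)]), 1)


class TestClassifier:
    def test_synthetic_five_molecules_perfect_heldout(self):
        """Five molecule classes, 50 spectra each at sigma = 0.01: the linear
        one-vs-rest SVM identifies every held-out spectrum."""
        ds = simulate_classification_dataset(
            noise=NoiseModel(sigma=0.01, seed=0))
        assert ds.values.shape == (250, 1687)
        clf, accuracy = train_classifier(ds, seed=0)
        assert accuracy == 1.0

    def test_separable_toy_training_accuracy(self):
        grid = np.linspace(0.0, 10.0, 50) + 1.0
        a = np.zeros(50); a[10] = 1.0
        b = np.zeros(50); b[40] = 1.0
        X = np.vstack([a] * 5 + [b] * 5)
        y = np.array(["A"] * 5 + ["B"] * 5)
        clf = SpectrumClassifier(seed=0).fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((4, 10))
        with pytest.raises(ValueError):
            SpectrumClassifier().fit(X, np.array(["A"] * 4))

    def test_seeded_split_reproducible(self):
        ds = simulate_classification_dataset(
            n_per_class=10, noise=NoiseModel(sigma=0.02, seed=1))
        acc1 = train_classifier(ds, seed=3)[1]
        acc2 = train_classifier(ds, seed=3)[1]
        assert acc1 == acc2


class TestUnmixing:
    @pytest.fixture
    def references(self, rng):
        grid = np.linspace(1500.0, 1800.0, 300)
        r1 = np.exp(-0.5 * ((grid - 1657.0) / 15.0) ** 2)
        r2 = np.exp(-0.5 * ((grid - 1632.0) / 15.0) ** 2)
        return grid, r1, r2

    def test_pure_reference_exact(self, references):
        grid, r1, r2 = references
        refs = _matrix(grid, [r1, r2], ["BSA", "BLG"])
        res = nnls_unmix(Spectrum(grid, r1, "difference"), refs)
        np.testing.assert_allclose(res.weights, [1.0, 0.0], atol=1e-12)
        assert res.mse == pytest.approx(0.0, abs=1e-24)

    def test_four_to_one_mixture_exact(self, references):
        grid, r1, r2 = references
        refs = _matrix(grid, [r1, r2], ["BSA", "BLG"])
        mixture = Spectrum(grid, 0.8 * r1 + 0.2 * r2, "difference")
        res = nnls_unmix(mixture, refs)
        np.testing.assert_allclose(res.weights, [0.800, 0.200], atol=1e-12)
        np.testing.assert_allclose(res.reconstructed.values, mixture.values,
                                   atol=1e-12)

    def test_constant_offset_mse(self, references):
        """A constant 0.01 offset the references cannot represent leaves a
        mean squared residual of ~1e-4."""
        grid, _, _ = references
        n = grid.size
        r1 = np.zeros(n); r1[50] = 1.0     # spike references: the offset is
        r2 = np.zeros(n); r2[250] = 1.0    # representable at 2 of n points
        refs = _matrix(grid, [r1, r2], ["a", "b"])
        mixture = Spectrum(grid, 0.8 * r1 + 0.2 * r2 + 0.01, "difference")
        res = nnls_unmix(mixture, refs)
        assert res.mse == pytest.approx(1e-4 * (n - 2) / n, rel=1e-9)
        np.testing.assert_allclose(res.weights, [0.81, 0.21], atol=1e-12)

    def test_scale_equivariance(self, references, rng):
        grid, r1, r2 = references
        refs = _matrix(grid, [r1, r2], ["a", "b"])
        mix = 0.3 * r1 + 0.6 * r2 + 0.005 * rng.normal(size=grid.size)
        w1 = nnls_unmix(Spectrum(grid, mix, "difference"), refs).weights
        w5 = nnls_unmix(Spectrum(grid, 5.0 * mix, "difference"), refs).weights
        np.testing.assert_allclose(w5, 5.0 * w1, rtol=1e-9)

    def test_grid_mismatch_rejected(self, references):
        grid, r1, r2 = references
        refs = _matrix(grid, [r1, r2], ["a", "b"])
        other = np.linspace(1400.0, 1700.0, 300)
        with pytest.raises(ValueError):
            nnls_unmix(Spectrum(other, r1, "difference"), refs)

    def test_pipeline_recovers_titration_weights(self):
        """End to end: noisy mixtures (sigma = 0.01, scan-averaged) are
        baseline-extracted and unmixed against a high-SNR pure-protein
        reference library, recovering the mixing weights within +/-0.02."""
        library = simulate_titration_dataset(
            ratios=((100, 0), (0, 100)), n_per_ratio=1,
            noise=NoiseModel(sigma=0.0))
        refs_delta = [
            extract_difference(Spectrum(library.grid, row, "absorbance")).values
            for row in library.values]
        refs = _matrix(library.grid, refs_delta, ["BSA", "BLG"])

        data = simulate_titration_dataset(
            ratios=((60, 40),), n_per_ratio=10,
            noise=NoiseModel(sigma=0.01, seed=0))
        avg = data.values.mean(axis=0)
        mix_delta = extract_difference(
            Spectrum(data.grid, avg, "absorbance"))
        res = nnls_unmix(mix_delta, refs)
        np.testing.assert_allclose(res.weights, [0.6, 0.4], atol=0.02)


class TestRegression:
    def test_linear_backend_exact_on_noiseless_mixtures(self, rng):
        grid = np.linspace(1000.0, 2000.0, 300)
        r1 = np.exp(-0.5 * ((grid - 1657.0) / 15.0) ** 2)
        r2 = np.exp(-0.5 * ((grid - 1632.0) / 15.0) ** 2)
        y = rng.uniform(0.0, 100.0, size=(30, 2))
        X = np.outer(y[:, 0], r1) + np.outer(y[:, 1], r2)
        reg = ConcentrationRegressor(backend="linear", seed=0).fit(X, y)
        assert reg.test_error_percent_ == pytest.approx(0.0, abs=1e-8)

    def test_mlp_backend_on_titration_pipeline(self):
        """Difference-spectrum inputs: held-out mean percentage error of the
        seeded network stays within 10% on the 7-ratio titration set."""
        data = simulate_titration_dataset(noise=NoiseModel(sigma=0.01, seed=0))
        delta = AslsBaseline().transform(data.values)
        matrix = SpectraMatrix(data.grid, delta, data.labels)
        _, err = regress_concentrations(matrix, backend="mlp", seed=0)
        assert err <= 10.0

    def test_seeded_determinism(self):
        data = simulate_titration_dataset(
            ratios=((80, 20), (20, 80)), n_per_ratio=10,
            noise=NoiseModel(sigma=0.01, seed=2))
        _, e1 = regress_concentrations(data, backend="mlp", seed=5, epochs=20)
        _, e2 = regress_concentrations(data, backend="mlp", seed=5, epochs=20)
        assert e1 == e2

    def test_missing_labels_rejected(self):
        X = np.zeros((10, 20))
        y = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            ConcentrationRegressor(backend="linear").fit(X, y)


class TestSecondaryStructure:
    def _d2(self, grid, y):
        return derivative_spectrum(Spectrum(grid, y, "difference"),
                                   DerivativeConfig(order=2))

    def test_single_helix_band(self):
        grid = np.linspace(1580.0, 1720.0, 701)
        y = np.exp(-0.5 * ((grid - 1655.0) / 4.0) ** 2)
        summary = secondary_structure(self._d2(grid, y))
        assert summary.band_fractions["alpha_helix"] > 0.9

    def test_two_equal_bands_split_evenly(self):
        grid = np.linspace(1580.0, 1720.0, 1401)
        y = (np.exp(-0.5 * ((grid - 1655.0) / 4.0) ** 2)
             + np.exp(-0.5 * ((grid - 1630.0) / 4.0) ** 2))
        f = secondary_structure(self._d2(grid, y)).band_fractions
        ratio = f["alpha_helix"] / (f["alpha_helix"] + f["beta_sheet"])
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_bsa_preset_helix_dominated(self, ftir_grid):
        spec = simulate_measurement(make_system("OC-Hmu", "BSA", 1.0),
                                    ftir_grid, NoiseModel(sigma=0.0))
        d2 = derivative_spectrum(extract_difference(spec),
                                 DerivativeConfig(order=2))
        f = secondary_structure(d2).band_fractions
        assert f["alpha_helix"] == max(f.values())

    def test_requires_amide_window(self):
        grid = np.linspace(1000.0, 1500.0, 200)
        with pytest.raises(ValueError):
            secondary_structure(Spectrum(grid, np.zeros(200), "derivative2"))

    def test_requires_second_derivative_kind(self):
        grid = np.linspace(1500.0, 1750.0, 200)
        with pytest.raises(ValueError):
            secondary_structure(Spectrum(grid, np.zeros(200), "difference"))
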