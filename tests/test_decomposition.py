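"""pLSA aspect model, PCA, matrix-component exclusion, RGB score overlay."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from strokemsi.decomposition import (
    exclude_matrix_components,
    pca_fit,
    plsa_components_report,
    plsa_fit,
    rgb_overlay,
)
from strokemsi.lipids import adduct_mz
from strokemsi.preprocess import FeatureMatrix, PeakWindow


def feature_matrix(values, coords=None):
    values = np.asarray(values, dtype=float)
    if coords is None:
        coords = np.column_stack([np.arange(len(values)), np.zeros(len(values), int)])
    windows = [PeakWindow(500.0 + j) for j in range(values.shape[1])]
    return FeatureMatrix(coords=coords, windows=windows, values=values)


def rank2_matrix():
    """Exact rank-2 nonnegative matrix from two known aspects."""
    rng = np.random.default_rng(42)
    phi = np.array([
        [0.5, 0.3, 0.1, 0.05, 0.05, 0.0],
        [0.0, 0.05, 0.05, 0.1, 0.3, 0.5],
    ])
    theta = rng.dirichlet([1.0, 1.0], size=120)
    totals = rng.uniform(50, 150, size=120)
    return totals[:, None] * (theta @ phi), phi, theta


class TestPlsaFit:
    def test_single_component_closed_form(self):
        matrix = feature_matrix(np.random.default_rng(0).random((30, 5)) + 0.1)
        model = plsa_fit(matrix, n_components=1, seed=0)
        expected = matrix.values.sum(axis=0) / matrix.values.sum()
        np.testing.assert_allclose(model.component_spectra[0], expected, rtol=1e-8)
        np.testing.assert_allclose(model.pixel_weights[:, 0], 1.0)

    def test_rank2_aspects_recovered(self):
        V, phi_true, _ = rank2_matrix()
        model = plsa_fit(feature_matrix(V), n_components=2, seed=0, tol=1e-12,
                         max_iter=2000)
        cos = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                a, b = phi_true[i], model.component_spectra[j]
                cos[i, j] = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        rows, cols = linear_sum_assignment(-cos)
        assert np.all(cos[rows, cols] >= 0.99)

    def test_rank2_reconstruction_error_tiny(self):
        V, _, _ = rank2_matrix()
        # tol=0 disables the relative-likelihood stop; EM runs to its
        # float64 fixed point within the iteration budget
        model = plsa_fit(feature_matrix(V), n_components=2, seed=0, tol=0.0,
                         max_iter=20000)
        rel = np.linalg.norm(model.reconstruct() - V) / np.linalg.norm(V)
        assert rel < 1e-6

    def test_log_likelihood_monotone(self):
        matrix = feature_matrix(np.random.default_rng(3).random((50, 8)))
        model = plsa_fit(matrix, n_components=3, seed=1)
        assert np.all(np.diff(model.log_likelihood) >= -1e-7)

    def test_probability_normalizations(self):
        matrix = feature_matrix(np.random.default_rng(4).random((40, 6)))
        model = plsa_fit(matrix, n_components=3, seed=2)
        np.testing.assert_allclose(model.pixel_weights.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.component_spectra.sum(axis=1), 1.0, atol=1e-9)
        assert model.pixel_weights.min() >= 0 and model.component_spectra.min() >= 0

    def test_deterministic_given_seed(self):
        matrix = feature_matrix(np.random.default_rng(5).random((30, 6)))
        a = plsa_fit(matrix, 2, seed=9)
        b = plsa_fit(matrix, 2, seed=9)
        np.testing.assert_array_equal(a.pixel_weights, b.pixel_weights)

    def test_negative_entries_rejected(self):
        matrix = feature_matrix(np.ones((5, 3)))
        matrix.values[0, 0] = -0.5
        with pytest.raises(ValueError, match="nonnegative"):
            plsa_fit(matrix, 2)
        with pytest.raises(ValueError, match="n_components"):
            plsa_fit(feature_matrix(np.ones((5, 3))), 4)


class TestPlsaReport:
    def test_top_n_capped_at_columns(self):
        matrix = feature_matrix(np.random.default_rng(1).random((20, 4)))
        model = plsa_fit(matrix, 2, seed=0)
        report = plsa_components_report(model, top_n=100)
        assert (report["loadings"].groupby("component").size() == 4).all()

    def test_rank2_top_peak_matches_generator(self):
        V, phi_true, _ = rank2_matrix()
        model = plsa_fit(feature_matrix(V), n_components=2, seed=0, tol=1e-12,
                         max_iter=2000)
        report = plsa_components_report(model, top_n=1)["loadings"]
        got_tops = {round(mz - 500.0) for mz in report["mz"]}
        true_tops = {int(np.argmax(phi_true[0])), int(np.argmax(phi_true[1]))}
        assert got_tops == true_tops

    def test_penumbra_component_carries_pip_in_top3(self, neg_features):
        """The component dominant over penumbra pixels loads PIP(38:4)."""
        matrix, truth = neg_features
        model = plsa_fit(matrix, min(7, len(matrix.windows)), seed=0)
        pen_rows = matrix.pixel_rows(truth.region_pixels("penumbra"))
        z = int(np.argmax(model.pixel_weights[pen_rows].mean(axis=0)))
        top3 = plsa_components_report(model, top_n=3, keep=[z])["loadings"]["mz"]
        pip_mz = adduct_mz("C47H84O16P2", "-H")
        assert any(abs(mz - pip_mz) < 0.3 for mz in top3)


class TestExcludeMatrixComponents:
    def _model(self, weights, coords):
        matrix = feature_matrix(np.ones((len(coords), 3)), coords=coords)
        model = plsa_fit(matrix, weights.shape[1], seed=0, max_iter=1)
        model.pixel_weights = weights
        return model

    def test_offtissue_component_flagged_and_tissue_component_kept(self):
        coords = np.column_stack([np.arange(6), np.zeros(6, int)])
        off = {(0, 0), (1, 0)}
        weights = np.array([
            [1.0, 0.0], [1.0, 0.0],  # off-tissue pixels: all weight on comp 0
            [0.0, 1.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0],
        ])
        result = exclude_matrix_components(self._model(weights, coords), off)
        assert result["flagged"] == [0]
        assert result["kept"] == [1]

    def test_empty_offtissue_warns_noop(self):
        coords = np.column_stack([np.arange(4), np.zeros(4, int)])
        model = self._model(np.full((4, 2), 0.5), coords)
        with pytest.warns(UserWarning, match="empty off-tissue"):
            result = exclude_matrix_components(model, set())
        assert result["flagged"] == []

    def test_matrix_peak_component_flagged_on_phantom(self, pos_features):
        matrix, truth = pos_features
        model = plsa_fit(matrix, 10, seed=0)
        off = {(int(x), int(y)) for x, y in truth.coords} - truth.tissue_pixels()
        flagged = exclude_matrix_components(model, off)["flagged"]
        assert flagged, "no matrix component detected"
        report = plsa_components_report(model, top_n=1)["loadings"]
        matrix_mzs = {550.2, 716.1}
        top1 = {int(c): mz for c, mz in zip(report["component"], report["mz"])}
        assert any(min(abs(top1[z] - m) for m in matrix_mzs) < 0.3 for z in flagged)


class TestPcaFit:
    def test_diagonal_direction_recovered(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        X = np.abs(np.column_stack([5 + t, 5 + t]) + rng.normal(0, 0.01, (200, 2)))
        model = pca_fit(feature_matrix(X), n_components=2)
        np.testing.assert_allclose(np.abs(model.loadings[:, 0]),
                                   [1 / np.sqrt(2)] * 2, atol=0.01)
        assert model.loadings[np.argmax(np.abs(model.loadings[:, 0])), 0] > 0

    def test_explained_variance_ratios_valid(self, pos_features):
        matrix, _ = pos_features
        model = pca_fit(matrix, n_components=5)
        evr = model.explained_variance_ratio
        assert np.all(evr >= 0) and evr.sum() <= 1 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)

    def test_full_rank_reconstruction(self):
        X = np.random.default_rng(1).random((30, 5))
        model = pca_fit(feature_matrix(X), n_components=5)
        recon = model.scores @ model.loadings.T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pca_fit(feature_matrix(np.ones((10, 3))), 2)

    def test_anticorrelated_na_k_load_opposite_signs(self):
        """SIMS-like columns: Na-related and K-related intensities anti-correlate
        across pixels, so one PC carries them with opposite signs."""
        rng = np.random.default_rng(3)
        ischemia = rng.uniform(0, 1, 300)  # latent severity
        na = 10 + 5 * ischemia + rng.normal(0, 0.2, 300)
        k = 15 - 5 * ischemia + rng.normal(0, 0.2, 300)
        pc_frag = 8 + rng.normal(0, 0.2, 300)
        model = pca_fit(feature_matrix(np.column_stack([na, k, pc_frag])), 3)
        found = any(model.loadings[0, c] * model.loadings[1, c] < 0
                    for c in range(3))
        assert found


class TestRgbOverlay:
    def test_identical_channels_grayscale(self):
        img = np.random.default_rng(0).random((8, 9))
        rgb = rgb_overlay([img, img, img])
        np.testing.assert_allclose(rgb[..., 0], rgb[..., 1])
        np.testing.assert_allclose(rgb[..., 1], rgb[..., 2])

    def test_sign_flip_reverses_gradient(self):
        img = np.tile(np.arange(5.0), (4, 1))
        rgb_pos = rgb_overlay([img, img, img], signs=(1, 1, 1))
        rgb_neg = rgb_overlay([img, img, img], signs=(-1, 1, 1))
        np.testing.assert_allclose(rgb_neg[..., 0], 1 - rgb_pos[..., 0])

    def test_constant_channel_zero_with_warning(self):
        img = np.random.default_rng(0).random((4, 4))
        with pytest.warns(UserWarning, match="constant channel"):
            rgb = rgb_overlay([np.ones((4, 4)), img, img])
        assert np.all(rgb[..., 0] == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            rgb_overlay([np.ones((3, 3)), np.ones((3, 4)), np.ones((3, 3))])
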