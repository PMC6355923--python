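"""pLSA and PCA decomposition of the feature matrix.

pLSA (probabilistic latent semantic analysis) treats each pixel spectrum as
a mixture over latent components ("aspects"): the matrix is factored as

    n(d, w) ~ TIC(d) * sum_z P(z|d) P(w|z)

with P(z|d) the per-pixel component weights and P(w|z) the component
spectra. Fitting is plain EM on the aspect model with normalized intensities
used as continuous pseudo-counts; the log-likelihood is guaranteed
non-decreasing. Components dominated by off-tissue (matrix) pixels can be
flagged and excluded from downstream reports.

PCA is a centered (optionally column-standardized) SVD with a deterministic
sign convention; its score images, rendered as RGB overlays of three
components, reproduce the SIMS-style Na/K contrast visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix

_EPS = 1e-12


@dataclass
class PLSAModel:
    n_components: int
    component_spectra: np.ndarray  # (K, W), rows sum to 1
    pixel_weights: np.ndarray  # (N, K), rows sum to 1
    log_likelihood: np.ndarray  # trace over EM iterations
    seed: int
    windows: list
    coords: np.ndarray
    row_totals: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Model reconstruction: row total x mixture of component spectra."""
        return self.row_totals[:, None] * (self.pixel_weights @ self.component_spectra)


def plsa_fit(matrix: FeatureMatrix, n_components: int, seed: int = 0,
             tol: float = 1e-6, max_iter: int = 500) -> PLSAModel:
    """Fit the aspect model by EM.

    E-step responsibilities P(z|d,w) are proportional to
    ``P(z|d) P(w|z)``; the M-step re-estimates both factors from
    responsibility-weighted counts. Iteration stops when the relative
    log-likelihood change drops below ``tol`` or after ``max_iter`` rounds.
    Initialization is seeded-random, so fits are reproducible.
    """
    V = np.asarray(matrix.values, dtype=float)
    if np.any(V < 0):
        raise ValueError("pLSA requires a nonnegative matrix")
    n_pixels, n_peaks = V.shape
    if n_components < 1 or n_components > n_peaks:
        raise ValueError("n_components must be in [1, n_peaks]")
    row_totals = V.sum(axis=1)

    rng = np.random.default_rng(seed)
    theta = rng.random((n_pixels, n_components)) + 0.1  # P(z|d)
    theta /= theta.sum(axis=1, keepdims=True)
    phi = rng.random((n_components, n_peaks)) + 0.1  # P(w|z)
    phi /= phi.sum(axis=1, keepdims=True)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        recon = theta @ phi
        ll = float(np.sum(V * np.log(recon + _EPS)))
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            break
        prev = ll
        ratio = V / (recon + _EPS)
        # both M-step updates use responsibilities from the same (old) parameters
        theta_new = theta * (ratio @ phi.T)
        phi_new = phi * (theta.T @ ratio)
        theta = theta_new / (theta_new.sum(axis=1, keepdims=True) + _EPS)
        phi = phi_new / (phi_new.sum(axis=1, keepdims=True) + _EPS)

    return PLSAModel(n_components=n_components, component_spectra=phi,
                     pixel_weights=theta, log_likelihood=np.array(trace),
                     seed=seed, windows=list(matrix.windows),
                     coords=matrix.coords.copy(), row_totals=row_totals)


def plsa_components_report(model: PLSAModel, top_n: int = 10,
                           keep: list | None = None) -> dict:
    """Ranked peak loadings and score images per component.

    Loadings are ranked by component-spectrum mass, ties broken by
    ascending m/z. ``keep`` restricts the report to a component subset
    (e.g. after matrix-component exclusion).
    """
    components = list(range(model.n_components)) if keep is None else list(keep)
    centers = np.array([w.center for w in model.windows])
    rows = []
    for z in components:
        weights = model.component_spectra[z]
        order = np.lexsort((centers, -weights))[:min(top_n, len(centers))]
        for rank, j in enumerate(order, start=1):
            rows.append({"component": z, "rank": rank, "mz": float(centers[j]),
                         "loading": float(weights[j])})
    loadings = pd.DataFrame(rows, columns=["component", "rank", "mz", "loading"])

    h = int(model.coords[:, 1].max()) + 1
    w = int(model.coords[:, 0].max()) + 1
    images = {}
    for z in components:
        img = np.full((h, w), np.nan)
        img[model.coords[:, 1], model.coords[:, 0]] = model.pixel_weights[:, z]
        images[z] = img
    return {"loadings": loadings, "score_images": images}


def exclude_matrix_components(model: PLSAModel, offtissue: set,
                              ratio: float = 1.0) -> dict:
    """Flag components whose weight concentrates on off-tissue (matrix) pixels.

    A component is flagged when its mean pixel weight over off-tissue pixels
    exceeds ``ratio`` times its mean weight over tissue pixels. Returns the
    kept and flagged component index lists.
    """
    if not offtissue:
        warnings.warn("empty off-tissue set; no components flagged")
        return {"kept": list(range(model.n_components)), "flagged": []}
    wanted = {(int(x), int(y)) for x, y in offtissue}
    is_off = np.array([(int(x), int(y)) in wanted for x, y in model.coords])
    if not is_off.any() or is_off.all():
        raise ValueError("off-tissue set must be a proper subset of dataset pixels")
    flagged = []
    for z in range(model.n_components):
        mean_off = model.pixel_weights[is_off, z].mean()
        mean_tissue = model.pixel_weights[~is_off, z].mean()
        if mean_off > ratio * mean_tissue:
            flagged.append(z)
    kept = [z for z in range(model.n_components) if z not in flagged]
    return {"kept": kept, "flagged": flagged}


@dataclass
class PCAModel:
    loadings: np.ndarray  # (W, K), orthonormal columns
    scores: np.ndarray  # (N, K)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None
    coords: np.ndarray

    def score_image(self, component: int, sign: int = 1) -> np.ndarray:
        h = int(self.coords[:, 1].max()) + 1
        w = int(self.coords[:, 0].max()) + 1
        img = np.full((h, w), np.nan)
        img[self.coords[:, 1], self.coords[:, 0]] = sign * self.scores[:, component]
        return img


def pca_fit(matrix: FeatureMatrix, n_components: int,
            scaling: str = "none") -> PCAModel:
    """Centered (optionally unit-variance) PCA by singular value decomposition.

    Sign convention: each loading vector is flipped so its largest-magnitude
    entry is positive, making component orientation deterministic.
    """
    if scaling not in ("none", "unit_variance"):
        raise ValueError("scaling must be 'none' or 'unit_variance'")
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 pixels")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if scaling == "unit_variance":
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    total_var = float((Xc ** 2).sum()) / (X.shape[0] - 1)
    if total_var <= 0:
        raise ValueError("zero variance: constant matrix")
    n_components = min(n_components, min(Xc.shape))
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U * S
    evr = (S ** 2) / (X.shape[0] - 1) / total_var
    return PCAModel(loadings=Vt.T, scores=scores, explained_variance_ratio=evr,
                    mean=mean, scale=scale, coords=matrix.coords.copy())


def rgb_overlay(score_images: list, signs: tuple = (1, 1, 1)) -> np.ndarray:
    """RGB composite of three score images (e.g. PC3 / PC4 / −PC4).

    Each channel is sign-applied and min-max scaled to [0, 1] over its
    finite (tissue) pixels; NaN pixels render black. A constant channel is
    rendered as zero with a warning.
    """
    if len(score_images) != 3 or len(signs) != 3:
        raise ValueError("exactly three score images and signs required")
    shapes = {img.shape for img in score_images}
    if len(shapes) != 1:
        raise ValueError("score images must share one shape")
    channels = []
    for img, sign in zip(score_images, signs):
        chan = np.asarray(img, dtype=float) * sign
        finite = np.isfinite(chan)
        lo, hi = (np.min(chan[finite]), np.max(chan[finite])) if finite.any() else (0, 0)
        if hi > lo:
            scaled = np.where(finite, (chan - lo) / (hi - lo), 0.0)
        else:
            warnings.warn("constant channel rendered as 0")
            scaled = np.zeros_like(chan)
        channels.append(scaled)
    return np.stack(channels, axis=-1)
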