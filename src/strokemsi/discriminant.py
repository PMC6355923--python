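"""Fisher linear discriminant analysis of ROI-labeled pixel spectra.

Pixel spectra are high-dimensional relative to the class structure, so LDA
is preceded by a PCA reduction keeping the fewest components whose
cumulative explained variance reaches a retained fraction (default 80%).
Fisher's criterion is then solved as the generalized eigenproblem of the
between-class versus within-class scatter in the reduced space; the
discriminant directions are back-projected to the original peak columns as
unit-normalized "scaled loadings". Per-class score histograms of the first
discriminating function (DF1) with shared bin edges quantify how well
ischemic, border-zone and healthy tissue separate; the overlap coefficient
of two class histograms is the separability readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preprocess import FeatureMatrix
from .segmentation import ROISet

DEFAULT_CLASSES = ("healthy", "ischemic", "borderzone")


@dataclass
class LDAResult:
    class_names: list
    labels: np.ndarray  # class name per pixel used in the fit
    scores: np.ndarray  # (n_pixels, n_functions) discriminant scores
    scaled_loadings: np.ndarray  # (n_peaks, n_functions), unit-normalized
    windows: list
    variance_retained: float
    n_pca_components: int
    bin_edges: np.ndarray  # shared DF1 histogram bins
    histograms: dict  # class -> counts over bin_edges

    @property
    def n_functions(self) -> int:
        return self.scores.shape[1]

    def df1(self, class_name: str) -> np.ndarray:
        return self.scores[self.labels == class_name, 0]


def rois_to_classes(rois: ROISet) -> dict:
    """Map the four anatomical ROIs onto the three discriminant classes.

    healthy = ipsi- and contralateral healthy tissue merged, ischemic = core,
    borderzone = penumbra.
    """
    return {
        "healthy": rois["healthy_contra"] | rois["healthy_ipsi"],
        "ischemic": rois["core"],
        "borderzone": rois["penumbra"],
    }


def _freedman_diaconis_edges(scores: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(scores, [25, 75])
    h = 2 * (q3 - q1) / len(scores) ** (1 / 3)
    lo, hi = scores.min(), scores.max()
    if h <= 0 or hi <= lo:
        return np.linspace(lo - 0.5, hi + 0.5, 11)
    n_bins = max(1, int(np.ceil((hi - lo) / h)))
    return np.linspace(lo, hi, n_bins + 1)


def lda_fit(matrix: FeatureMatrix, classes: dict,
            variance_retained: float = 0.8, seed: int = 0) -> LDAResult:
    """Fisher LDA on labeled pixel sets after PCA pre-reduction.

    ``classes`` maps class name -> pixel set. The PCA step keeps the fewest
    components reaching ``variance_retained`` cumulative explained variance.
    DF1 sign is chosen so the ischemic class mean exceeds the healthy class
    mean (when both are present). ``seed`` is recorded for provenance; the
    fit itself is deterministic.
    """
    if not 0 < variance_retained <= 1:
        raise ValueError("variance_retained must be in (0, 1]")
    names = list(classes)
    if len(names) < 2:
        raise ValueError("need at least 2 classes")
    rows, labels = [], []
    for name in names:
        idx = matrix.pixel_rows(classes[name])
        if len(idx) < 2:
            raise ValueError(f"class {name!r} needs at least 2 pixels")
        rows.append(idx)
        labels.extend([name] * len(idx))
    X = np.vstack([matrix.values[idx] for idx in rows])
    labels = np.array(labels)

    # PCA pre-reduction to the retained-variance dimension
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    frac = np.cumsum(var) / var.sum()
    n_keep = int(np.searchsorted(frac, variance_retained) + 1)
    n_keep = min(n_keep, len(S))
    P = Vt[:n_keep].T  # (n_peaks, n_keep)
    Z = Xc @ P

    # scatter matrices in reduced space
    overall = Z.mean(axis=0)
    d = Z.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for name in names:
        Zi = Z[labels == name]
        mu = Zi.mean(axis=0)
        Sw += (Zi - mu).T @ (Zi - mu)
        Sb += len(Zi) * np.outer(mu - overall, mu - overall)
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        warnings.warn("singular within-class scatter; ridge 1e-6 added")
        Sw = Sw + 1e-6 * np.trace(Sw) / d * np.eye(d)
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_funcs = min(len(names) - 1, d)
    W = evecs[:, order[:n_funcs]]  # (d, n_funcs)
    scores = Z @ W

    # sign convention on each DF: ischemic mean above healthy mean
    if "ischemic" in names and "healthy" in names:
        for f in range(n_funcs):
            if (scores[labels == "ischemic", f].mean()
                    < scores[labels == "healthy", f].mean()):
                scores[:, f] = -scores[:, f]
                W[:, f] = -W[:, f]

    loadings = P @ W  # back-projection to peak columns
    norms = np.linalg.norm(loadings, axis=0)
    norms[norms == 0] = 1.0
    loadings = loadings / norms

    edges = _freedman_diaconis_edges(scores[:, 0])
    hists = {name: np.histogram(scores[labels == name, 0], bins=edges)[0]
             for name in names}
    return LDAResult(class_names=names, labels=labels, scores=scores,
                     scaled_loadings=loadings, windows=list(matrix.windows),
                     variance_retained=variance_retained, n_pca_components=n_keep,
                     bin_edges=edges, histograms=hists)


def lda_separability(result: LDAResult, class_a: str, class_b: str) -> float:
    """Overlap coefficient of two classes' DF1 histograms.

    ``sum_bins min(density_a, density_b) * bin_width`` in [0, 1]; lower
    means better separated. Scores outside the shared bin range are counted
    in the nearest edge bin so each density integrates to 1.
    """
    for name in (class_a, class_b):
        if name not in result.class_names:
            raise KeyError(f"unknown class {name!r}")
    edges = result.bin_edges
    widths = np.diff(edges)

    def density(name: str) -> np.ndarray:
        scores = np.clip(result.df1(name), edges[0], edges[-1])
        counts, _ = np.histogram(scores, bins=edges)
        return counts / counts.sum() / widths

    da, db = density(class_a), density(class_b)
    return float(np.sum(np.minimum(da, db) * widths))
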