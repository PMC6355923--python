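"""Normalization, peak picking, and reduction of spectra to a feature matrix.

The processing chain mirrors standard MSI practice: robust TIC
normalization of every pixel spectrum, peak picking on the dataset mean
spectrum, and integration of fixed m/z windows (default ±0.3 Da) over the
whole image to produce a pixels x peaks :class:`FeatureMatrix` that all
downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MSIDataset


@dataclass(frozen=True)
class PeakWindow:
    """An integration window ``center ± half_width`` (Da)."""

    center: float
    half_width: float = 0.3

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")

    def label(self) -> str:
        return f"{self.center:.4f}"


@dataclass
class FeatureMatrix:
    """Pixels x peak-window intensities after optional normalization."""

    coords: np.ndarray  # (N, 2) pixel coords, row order fixed
    windows: list  # of PeakWindow
    values: np.ndarray  # (N, K) nonnegative
    normalization: str = "raw"  # raw | tic

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.coords), len(self.windows)):
            raise ValueError("values must be (n_pixels, n_windows)")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("feature values must be finite and >= 0")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def window_index(self, window) -> int:
        center = float(getattr(window, "center", window))
        centers = np.array([w.center for w in self.windows])
        j = int(np.argmin(np.abs(centers - center)))
        if abs(centers[j] - center) > self.windows[j].half_width:
            raise KeyError(f"no window at m/z {center}")
        return j

    def column(self, window) -> np.ndarray:
        return self.values[:, self.window_index(window)]

    def pixel_rows(self, pixels: set) -> np.ndarray:
        """Row indices of a pixel set, in stored row order."""
        wanted = {(int(x), int(y)) for x, y in pixels}
        rows = [i for i, (x, y) in enumerate(self.coords) if (int(x), int(y)) in wanted]
        if len(rows) != len(wanted):
            raise KeyError("pixel set contains coordinates outside the matrix")
        return np.array(rows, dtype=int)

    def subset(self, pixels: set) -> "FeatureMatrix":
        rows = self.pixel_rows(pixels)
        return FeatureMatrix(self.coords[rows], list(self.windows),
                             self.values[rows], self.normalization)


def tic_normalize(dataset: MSIDataset, denoise: str = "weak") -> MSIDataset:
    """Scale every spectrum so its TIC equals the dataset mean TIC.

    With ``denoise="weak"`` the TIC used for scaling is a robust one: the
    sum excludes intensities below the spectrum's 5th percentile and above
    its 99.9th percentile, guarding against baseline and hot pixels. Pixels
    with zero TIC are left at zero (flagged in dataset metadata).
    """
    if denoise not in ("weak", "none"):
        raise ValueError("denoise must be 'weak' or 'none'")
    if not dataset.is_continuous:
        raise ValueError("tic_normalize requires a continuous-mode dataset")
    inten = np.asarray(dataset.intensities, dtype=float)
    if denoise == "weak":
        lo = np.percentile(inten, 5.0, axis=1, keepdims=True)
        hi = np.percentile(inten, 99.9, axis=1, keepdims=True)
        used = np.where((inten >= lo) & (inten <= hi), inten, 0.0)
        tics = used.sum(axis=1)
    else:
        tics = inten.sum(axis=1)
    positive = tics > 0
    if not np.any(positive):
        raise ValueError("all pixels have zero TIC")
    mean_tic = tics[positive].mean()
    factors = np.ones_like(tics)
    factors[positive] = mean_tic / tics[positive]
    out = dataset.copy_with((inten * factors[:, None]).astype(inten.dtype))
    out.metadata["normalization"] = f"tic/{denoise}"
    zero = np.flatnonzero(~positive)
    if zero.size:
        out.metadata["zero_tic_pixels"] = [tuple(map(int, dataset.coords[i])) for i in zero]
    return out


def mean_spectrum(dataset: MSIDataset, pixels: set | None = None) -> np.ndarray:
    """Arithmetic mean spectrum over a pixel subset (default: all pixels)."""
    if not dataset.is_continuous:
        raise ValueError("mean_spectrum requires a continuous-mode dataset")
    if pixels is None:
        return np.asarray(dataset.intensities, dtype=float).mean(axis=0)
    index = dataset.pixel_index()
    try:
        rows = [index[(int(x), int(y))] for x, y in pixels]
    except KeyError as exc:
        raise KeyError(f"pixel {exc} outside dataset") from exc
    if not rows:
        raise ValueError("empty pixel set")
    return np.asarray(dataset.intensities[np.array(rows)], dtype=float).mean(axis=0)


def noise_level(spectrum: np.ndarray) -> float:
    """Noise estimate: scaled median absolute deviation of the difference series."""
    diffs = np.diff(np.asarray(spectrum, dtype=float))
    return float(1.4826 * np.median(np.abs(diffs - np.median(diffs))))


def pick_peaks(axis_values: np.ndarray, spectrum: np.ndarray,
               snr_min: float = 3.0, half_width: float = 0.3) -> list:
    """Local maxima with baseline-corrected intensity >= snr_min x noise.

    Intensity is measured above the spectrum median (a flat-baseline guard);
    noise is the MAD-of-differences estimate. Windows closer than
    ``2 * half_width`` are merged onto the more intense center (greedy,
    intensity-descending). The rule is invariant to uniform intensity
    scaling: baseline, threshold and signal all scale together.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    axis_values = np.asarray(axis_values, dtype=float)
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("non-finite intensities in spectrum")
    if spectrum.size != axis_values.size:
        raise ValueError("spectrum and axis length mismatch")
    if spectrum.size < 3:
        return []
    sigma = noise_level(spectrum)
    threshold = snr_min * sigma
    signal = spectrum - np.median(spectrum)
    interior = spectrum[1:-1]
    is_max = (interior >= spectrum[:-2]) & (interior > spectrum[2:]) \
        & (signal[1:-1] >= threshold)
    cand = np.flatnonzero(is_max) + 1
    # greedy merge: strongest first, drop candidates within 2*half_width
    order = cand[np.lexsort((axis_values[cand], -spectrum[cand]))]
    accepted: list[float] = []
    for i in order:
        mz = axis_values[i]
        if all(abs(mz - c) >= 2 * half_width for c in accepted):
            accepted.append(float(mz))
    return [PeakWindow(c, half_width) for c in sorted(accepted)]


def integrate(dataset: MSIDataset, peaks: list) -> FeatureMatrix:
    """Sum intensities inside each peak window for every pixel."""
    if not peaks:
        raise ValueError("empty peak list")
    if not dataset.is_continuous:
        raise ValueError("integrate requires a continuous-mode dataset")
    lo, hi = dataset.axis.values[0], dataset.axis.values[-1]
    for w in peaks:
        if not (lo <= w.center <= hi):
            raise ValueError(f"peak window {w.center} outside axis range")
    inten = np.asarray(dataset.intensities, dtype=float)
    cols = [inten[:, dataset.axis.window_slice(w.center, w.half_width)].sum(axis=1)
            for w in peaks]
    tag = "tic" if str(dataset.metadata.get("normalization", "")).startswith("tic") else "raw"
    return FeatureMatrix(coords=dataset.coords.copy(), windows=list(peaks),
                         values=np.column_stack(cols), normalization=tag)


def ion_image(matrix: FeatureMatrix, window, percentile_scale: bool = False) -> np.ndarray:
    """Dense 2D image of one peak-window column; missing pixels are NaN.

    With ``percentile_scale`` the image is clipped to its 0.1–99.9 percentile
    range and scaled to [0, 1] for rendering.
    """
    j = matrix.window_index(window)
    h = int(matrix.coords[:, 1].max()) + 1
    w = int(matrix.coords[:, 0].max()) + 1
    image = np.full((h, w), np.nan)
    image[matrix.coords[:, 1], matrix.coords[:, 0]] = matrix.values[:, j]
    if percentile_scale:
        finite = image[np.isfinite(image)]
        lo, hi = np.percentile(finite, [0.1, 99.9])
        if hi > lo:
            image = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
        else:
            image = np.where(np.isfinite(image), 0.0, np.nan)
    return image
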