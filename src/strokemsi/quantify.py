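"""ROI summary statistics, bootstrap fold changes, and per-pixel ratio images.

Fold change is the mean ratio of signal intensity between an ischemic ROI
(core or penumbra) and a healthy ROI, computed on ROIs equalized to the
same pixel count, with a percentile-bootstrap 95% confidence interval over
paired pixel resamples. Quantiles use the linear-interpolation (type 7)
definition throughout. The K+/Na+ ratio image divides two peak-window
columns pixel-wise with an epsilon mask on the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import FeatureMatrix, PeakWindow


@dataclass
class BoxStats:
    """Five-number summary with 1.5 x IQR whiskers and outliers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass
class FoldChangeEstimate:
    window: PeakWindow
    roi_pair: tuple
    fold: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_pixels: int


@dataclass
class RatioImage:
    numerator: PeakWindow
    denominator: PeakWindow
    values: np.ndarray  # 2D, NaN where masked
    epsilon: float

    def masked_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


def roi_boxstats(matrix: FeatureMatrix, rois, window) -> dict:
    """Per-ROI box-plot summary of one peak-window column.

    ``rois`` is an ROISet or a plain name -> pixel-set mapping. Quartiles
    use linear interpolation; whiskers sit at the most extreme data points
    within 1.5 x IQR of the quartiles; everything beyond is an outlier.
    """
    roi_map = rois.rois if hasattr(rois, "rois") else dict(rois)
    col = matrix.column(window)
    out = {}
    for name, pixels in roi_map.items():
        if not pixels:
            raise ValueError(f"empty ROI {name!r}")
        values = col[matrix.pixel_rows(pixels)]
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = values[(values >= lo_fence) & (values <= hi_fence)]
        out[name] = BoxStats(
            n=len(values), median=float(med), q1=float(q1), q3=float(q3),
            whisker_low=float(inside.min()), whisker_high=float(inside.max()),
            outliers=np.sort(values[(values < lo_fence) | (values > hi_fence)]),
        )
    return out


def fold_change(matrix: FeatureMatrix, window, roi_ischemic: set, roi_healthy: set,
                n_boot: int = 10000, seed: int = 0) -> FoldChangeEstimate:
    """Mean-ratio fold change with a percentile-bootstrap 95% CI.

    The two ROIs must hold the same number of pixels (they are
    auto-equalized by seeded subsampling otherwise, matching the drawn-ROI
    protocol of equal pixel counts). The CI is the 2.5/97.5 percentile of
    the fold over ``n_boot`` paired within-ROI pixel resamples.
    """
    from .segmentation import ROISet, equalize_rois

    if not roi_ischemic or not roi_healthy:
        raise ValueError("both ROIs must be non-empty")
    if len(roi_ischemic) != len(roi_healthy):
        eq = equalize_rois(ROISet(rois={"a": set(roi_ischemic), "b": set(roi_healthy)}),
                           seed=seed)
        roi_ischemic, roi_healthy = eq["a"], eq["b"]
    col = matrix.column(window)
    isch = col[matrix.pixel_rows(roi_ischemic)]
    heal = col[matrix.pixel_rows(roi_healthy)]
    if heal.mean() == 0:
        raise ValueError("healthy ROI mean is zero")
    fold = float(isch.mean() / heal.mean())

    rng = np.random.default_rng(seed)
    n = len(isch)
    idx_i = rng.integers(0, n, size=(n_boot, n))
    idx_h = rng.integers(0, n, size=(n_boot, n))
    num = isch[idx_i].mean(axis=1)
    den = heal[idx_h].mean(axis=1)
    boots = num / np.where(den == 0, np.nan, den)
    ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
    window = window if isinstance(window, PeakWindow) else matrix.windows[matrix.window_index(window)]
    return FoldChangeEstimate(window=window, roi_pair=("ischemic", "healthy"),
                              fold=fold, ci_low=float(ci_low), ci_high=float(ci_high),
                              n_boot=n_boot, seed=seed, n_pixels=n)


def replicate_fold_change(matrices: list, window, rois: list,
                          n_boot: int = 10000, seed: int = 0) -> FoldChangeEstimate:
    """Fold change across replicate sections (per-replicate mean mode).

    ``matrices`` and ``rois`` are parallel lists of FeatureMatrix and
    (ischemic pixel set, healthy pixel set) pairs, one per animal/section.
    The statistic is the ratio of the averages of per-replicate ROI means,
    bootstrapped over pixels within every replicate ROI.
    """
    if len(matrices) != len(rois) or not matrices:
        raise ValueError("need one ROI pair per replicate")
    isch_vals = [m.column(window)[m.pixel_rows(r[0])] for m, r in zip(matrices, rois)]
    heal_vals = [m.column(window)[m.pixel_rows(r[1])] for m, r in zip(matrices, rois)]
    fold = float(np.mean([v.mean() for v in isch_vals])
                 / np.mean([v.mean() for v in heal_vals]))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        num = np.mean([v[rng.integers(0, len(v), len(v))].mean() for v in isch_vals])
        den = np.mean([v[rng.integers(0, len(v), len(v))].mean() for v in heal_vals])
        boots[b] = num / den if den != 0 else np.nan
    ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
    window = window if isinstance(window, PeakWindow) else matrices[0].windows[matrices[0].window_index(window)]
    return FoldChangeEstimate(window=window, roi_pair=("ischemic", "healthy"),
                              fold=fold, ci_low=float(ci_low), ci_high=float(ci_high),
                              n_boot=n_boot, seed=seed,
                              n_pixels=sum(len(v) for v in isch_vals))


def ratio_image(matrix: FeatureMatrix, num, den,
                epsilon: float | None = None) -> RatioImage:
    """Per-pixel ratio of two peak-window columns, masked at tiny denominators.

    ``epsilon`` defaults to 1e-6 x the matrix maximum; pixels whose
    denominator does not exceed it are NaN rather than infinite.
    """
    jn, jd = matrix.window_index(num), matrix.window_index(den)
    if epsilon is None:
        epsilon = 1e-6 * float(matrix.values.max())
    h = int(matrix.coords[:, 1].max()) + 1
    w = int(matrix.coords[:, 0].max()) + 1
    img = np.full((h, w), np.nan)
    numerator = matrix.values[:, jn]
    denominator = matrix.values[:, jd]
    ok = denominator > epsilon
    img[matrix.coords[ok, 1], matrix.coords[ok, 0]] = numerator[ok] / denominator[ok]
    return RatioImage(numerator=matrix.windows[jn], denominator=matrix.windows[jd],
                      values=img, epsilon=float(epsilon))


def roi_ratio_median(ratio: RatioImage, pixels: set) -> float:
    """Median ratio over a pixel set, ignoring masked pixels."""
    vals = [ratio.values[y, x] for x, y in pixels
            if 0 <= y < ratio.values.shape[0] and 0 <= x < ratio.values.shape[1]]
    vals = np.array(vals)
    return float(np.nanmedian(vals))
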