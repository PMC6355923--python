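"""Landmark co-registration and linear-transparency overlay rendering.

An ion image is registered onto a histology image through a similarity
transform (rotation, isotropic scale, translation) fitted to paired
landmarks by the closed-form least-squares (Umeyama) solution, then warped
(bilinear) into the histology frame and alpha-blended over it. The overlap
score between the supra-threshold ion mask and an annotated necrotic-border
mask turns the visual "aligns within the border" claim into a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import SimilarityTransform, warp


@dataclass
class FittedTransform:
    rotation: float  # radians
    scale: float
    translation: tuple  # (tx, ty) in target pixels
    residual_rms: float

    def to_skimage(self) -> SimilarityTransform:
        return SimilarityTransform(rotation=self.rotation, scale=self.scale,
                                   translation=self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.to_skimage()(np.asarray(points, dtype=float))


def fit_transform(landmarks_src: np.ndarray, landmarks_dst: np.ndarray) -> FittedTransform:
    """Least-squares similarity transform from >= 2 paired landmarks."""
    src = np.asarray(landmarks_src, dtype=float)
    dst = np.asarray(landmarks_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2 or len(src) < 2:
        raise ValueError("need >= 2 paired (x, y) landmarks of equal count")
    if np.allclose(src, src[0]):
        raise ValueError("coincident source landmarks")
    if hasattr(SimilarityTransform, "from_estimate"):
        tform = SimilarityTransform.from_estimate(src, dst)
        if not tform:
            raise ValueError("transform estimation failed")
    else:  # scikit-image < 0.26
        tform = SimilarityTransform()
        if not tform.estimate(src, dst):
            raise ValueError("transform estimation failed")
    mapped = tform(src)
    residual_rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    if tform.scale <= 0:
        raise ValueError("degenerate transform (non-positive scale)")
    return FittedTransform(rotation=float(tform.rotation), scale=float(tform.scale),
                           translation=tuple(map(float, tform.translation)),
                           residual_rms=residual_rms)


@dataclass
class OverlayImage:
    rgba: np.ndarray  # (H, W, 4) in [0, 1], histology dimensions
    alpha: float
    transform: FittedTransform
    colormap: str


def warp_ion_image(ion: np.ndarray, transform: FittedTransform,
                   out_shape: tuple) -> np.ndarray:
    """Warp an ion image into the histology frame (bilinear); outside -> NaN."""
    ion = np.asarray(ion, dtype=float)
    filled = np.where(np.isfinite(ion), ion, 0.0)
    tform = transform.to_skimage()
    warped = warp(filled, tform.inverse, output_shape=out_shape, order=1,
                  mode="constant", cval=np.nan, preserve_range=True)
    support = warp(np.ones_like(filled), tform.inverse, output_shape=out_shape,
                   order=1, mode="constant", cval=0.0, preserve_range=True)
    warped[support < 0.999] = np.nan
    return warped


def render_overlay(ion: np.ndarray, histology: np.ndarray,
                   transform: FittedTransform, alpha: float = 0.5,
                   threshold: float = 0.0, colormap: str = "viridis") -> OverlayImage:
    """Alpha-blend a colormapped, warped ion image over histology.

    Ion pixels below ``threshold`` x image maximum are fully transparent
    (pure histology shows through), as are pixels outside the warped
    footprint; elsewhere ``out = alpha * colormapped_ion +
    (1 - alpha) * histology``, so the blend is linear in alpha per pixel.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    ion = np.asarray(ion, dtype=float)
    if ion.size == 0 or not np.isfinite(ion).any():
        raise ValueError("empty ion image")
    hist = np.asarray(histology, dtype=float)
    if hist.ndim == 2:
        hist = np.stack([hist] * 3, axis=-1)
    if hist.max() > 1:
        hist = hist / 255.0

    warped = warp_ion_image(ion, transform, hist.shape[:2])
    finite = np.isfinite(warped)
    vmax = np.nanmax(warped) if finite.any() else 1.0
    vmin = np.nanmin(warped) if finite.any() else 0.0
    span = vmax - vmin if vmax > vmin else 1.0
    norm = np.where(finite, (warped - vmin) / span, 0.0)

    from matplotlib import colormaps

    colored = colormaps[colormap](norm)[..., :3]
    visible = finite & (warped >= threshold * vmax)
    blend = np.where(visible[..., None], alpha * colored + (1 - alpha) * hist, hist)
    rgba = np.concatenate([blend, np.ones(blend.shape[:2] + (1,))], axis=-1)
    return OverlayImage(rgba=np.clip(rgba, 0, 1), alpha=alpha,
                        transform=transform, colormap=colormap)


def mask_overlap(mask_a: np.ndarray, mask_b: np.ndarray, mode: str = "fraction") -> float:
    """Overlap of two boolean masks.

    ``fraction``: |A ∩ B| / |A| (how much of A lies within B);
    ``jaccard``: |A ∩ B| / |A ∪ B| (symmetric).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    inter = np.logical_and(a, b).sum()
    if mode == "fraction":
        return float(inter / a.sum()) if a.sum() else 0.0
    if mode == "jaccard":
        union = np.logical_or(a, b).sum()
        return float(inter / union) if union else 0.0
    raise ValueError("mode must be 'fraction' or 'jaccard'")
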