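"""Spatial segmentation of pixel spectra and named ROI construction.

Segmentation is bisecting k-means: starting from one cluster, the cluster
with the largest within-cluster scatter is repeatedly split by seeded
2-means (10 restarts, best inertia) until ``k`` clusters exist. With
``distance="correlation"`` the rows are standardized (mean removed, unit
norm) first, which makes the clustering invariant to per-pixel positive
rescaling — the correlation-distance analogue used by MSI segmentation
pipelines.

Region naming is automated: ipsilateral clusters are ranked by their mean
intensity in a marker window (default: the sodiated PC(32:0) window, which
is maximal in the infarct core); the top cluster becomes the core, the
adjacent cluster with the next-highest marker the penumbra, the remaining
ipsilateral pixels healthy tissue. Manual ROIs from mask files are
supported as an override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .dataset import AnnotationMask, MSIDataset, rasterize_mask
from .preprocess import FeatureMatrix, PeakWindow


@dataclass
class SegmentationMap:
    """Integer cluster label per pixel plus the bisecting split history."""

    coords: np.ndarray
    labels: np.ndarray  # contiguous ints starting at 0
    linkage: list  # (parent_label, new_label) split records
    params: dict

    def __post_init__(self):
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be contiguous integers starting at 0")

    def cluster_pixels(self, label: int) -> set:
        idx = np.flatnonzero(self.labels == label)
        return {(int(x), int(y)) for x, y in self.coords[idx]}


@dataclass
class ROISet:
    """Named, pairwise-disjoint pixel sets (core, penumbra, healthy...)."""

    rois: dict  # name -> set of (x, y)
    provenance: str = "manual"  # manual | from_segmentation

    def __post_init__(self):
        names = list(self.rois)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.rois[a] & self.rois[b]:
                    raise ValueError(f"ROIs {a!r} and {b!r} overlap")

    def __getitem__(self, name: str) -> set:
        return self.rois[name]

    def sizes(self) -> dict:
        return {name: len(pix) for name, pix in self.rois.items()}


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return centered / norms


def segment(matrix: FeatureMatrix, k: int, distance: str = "correlation",
            seed: int = 0, pixels: set | None = None,
            spatial_denoise: bool = False) -> SegmentationMap:
    """Bisecting k-means segmentation of the feature matrix into ``k`` clusters.

    ``pixels`` restricts clustering to a subset (e.g. tissue only);
    ``spatial_denoise`` applies a 3x3 median filter to each feature image
    before clustering (edge-preserving smoothing, off by default), followed
    by a boundary-refinement pass: each pixel may switch to a label present
    in its 3x3 neighborhood if its *unsmoothed* profile is closer to that
    cluster's centroid, which undoes the edge erosion the median filter
    causes on thin structures such as the penumbra annulus.
    """
    if distance not in ("correlation", "euclidean"):
        raise ValueError("distance must be 'correlation' or 'euclidean'")
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = matrix if pixels is None else matrix.subset(pixels)
    if k > sub.n_pixels:
        raise ValueError("k exceeds pixel count")
    raw_values = sub.values
    values = raw_values
    if spatial_denoise:
        from scipy.ndimage import median_filter

        h = int(sub.coords[:, 1].max()) + 1
        w = int(sub.coords[:, 0].max()) + 1
        smoothed = np.empty_like(values)
        for j in range(values.shape[1]):
            img = np.zeros((h, w))
            img[sub.coords[:, 1], sub.coords[:, 0]] = values[:, j]
            filt = median_filter(img, size=3)
            smoothed[:, j] = filt[sub.coords[:, 1], sub.coords[:, 0]]
        values = smoothed
    features = _standardize_rows(values) if distance == "correlation" else values

    labels = np.zeros(len(features), dtype=int)
    linkage: list[tuple[int, int]] = []
    rng = np.random.default_rng(seed)
    while labels.max() + 1 < k:
        n_clusters = labels.max() + 1
        scatter = np.full(n_clusters, -np.inf)
        for c in range(n_clusters):
            rows = features[labels == c]
            if len(rows) >= 2:
                scatter[c] = float(((rows - rows.mean(axis=0)) ** 2).sum())
        target = int(np.argmax(scatter))
        if not np.isfinite(scatter[target]):
            raise ValueError("cannot split further: all clusters are singletons")
        rows = np.flatnonzero(labels == target)
        km = KMeans(n_clusters=2, n_init=10,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        sub_labels = km.fit_predict(features[rows])
        new_label = n_clusters
        labels[rows[sub_labels == 1]] = new_label
        linkage.append((target, new_label))
    if spatial_denoise and k > 1:
        raw = _standardize_rows(raw_values) if distance == "correlation" else raw_values
        labels = _refine_boundaries(sub.coords, labels, raw, k)
    return SegmentationMap(coords=sub.coords.copy(), labels=labels, linkage=linkage,
                           params={"k": k, "distance": distance, "seed": seed,
                                   "spatial_denoise": spatial_denoise})


def _refine_boundaries(coords, labels, features, k) -> np.ndarray:
    """One constrained reassignment pass at cluster boundaries.

    A pixel may only move to a label occurring in its 3x3 neighborhood; the
    winner is the nearest cluster centroid in (unsmoothed) feature space.
    """
    position = {(int(x), int(y)): i for i, (x, y) in enumerate(coords)}
    centroids = np.stack([features[labels == c].mean(axis=0) for c in range(k)])
    refined = labels.copy()
    for i, (x, y) in enumerate(coords):
        candidates = {labels[i]}
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                j = position.get((int(x) + dx, int(y) + dy))
                if j is not None:
                    candidates.add(int(labels[j]))
        if len(candidates) > 1:
            cands = sorted(candidates)
            dist = ((features[i] - centroids[cands]) ** 2).sum(axis=1)
            refined[i] = cands[int(np.argmin(dist))]
    return refined


def _adjacent(pixels_a: set, pixels_b: set) -> bool:
    """4-connectivity adjacency between two pixel footprints."""
    for x, y in pixels_a:
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (x + dx, y + dy) in pixels_b:
                return True
    return False


def label_regions(seg: SegmentationMap, hemisphere_mask, matrix: FeatureMatrix,
                  marker_window=None) -> ROISet:
    """Name segmentation clusters as core / penumbra / healthy regions.

    ``hemisphere_mask`` gives the ipsilateral pixels (AnnotationMask or pixel
    set). Ipsilateral clusters are ranked by mean marker-window intensity;
    the highest is the core, the cluster 4-adjacent to the core with the
    next-highest marker is the penumbra, remaining ipsilateral pixels are
    healthy_ipsi, and contralateral pixels healthy_contra.
    """
    if marker_window is None:
        from .lipids import adduct_mz

        marker_window = PeakWindow(adduct_mz("C40H80NO8P", "+Na"))  # PC(32:0)+Na
    if isinstance(hemisphere_mask, AnnotationMask):
        # rasterize against the segmented pixel grid
        dummy = _grid_dataset(seg.coords)
        ipsi = rasterize_mask(hemisphere_mask, dummy)
    else:
        ipsi = {(int(x), int(y)) for x, y in hemisphere_mask}

    marker = matrix.column(marker_window)
    index = {(int(x), int(y)): i for i, (x, y) in enumerate(matrix.coords)}
    seg_pixels = [(int(x), int(y)) for x, y in seg.coords]
    rows = np.array([index[p] for p in seg_pixels])
    marker_seg = marker[rows]

    cluster_ids = np.unique(seg.labels)
    ipsi_mask = np.array([p in ipsi for p in seg_pixels])
    means = {}
    footprints = {}
    for c in cluster_ids:
        sel = (seg.labels == c) & ipsi_mask
        if np.any(sel):
            means[c] = float(marker_seg[sel].mean())
            footprints[c] = {seg_pixels[i] for i in np.flatnonzero(sel)}
    if len(means) < 3:
        raise ValueError("fewer than 3 ipsilateral clusters: increase k")
    vals = np.array(list(means.values()))
    if np.ptp(vals) <= 1e-12 * max(1.0, np.abs(vals).max()):
        raise ValueError("marker uninformative: constant across clusters")

    ranked = sorted(means, key=lambda c: means[c], reverse=True)
    core_cluster = ranked[0]
    penumbra_cluster = None
    for c in ranked[1:]:
        if _adjacent(footprints[c], footprints[core_cluster]):
            penumbra_cluster = c
            break
    if penumbra_cluster is None:
        raise ValueError("no cluster adjacent to the core: increase k")

    core = footprints[core_cluster]
    penumbra = footprints[penumbra_cluster]
    healthy_ipsi = set().union(*(footprints[c] for c in means
                                 if c not in (core_cluster, penumbra_cluster)))
    healthy_contra = {p for p in seg_pixels if p not in ipsi}
    return ROISet(rois={"healthy_contra": healthy_contra, "healthy_ipsi": healthy_ipsi,
                        "penumbra": penumbra, "core": core},
                  provenance="from_segmentation")


def _grid_dataset(coords: np.ndarray) -> MSIDataset:
    from .dataset import MassAxis

    return MSIDataset(coords=coords, axis=MassAxis(np.array([100.0])),
                      intensities=np.zeros((len(coords), 1)))


def equalize_rois(rois: ROISet, seed: int = 0) -> ROISet:
    """Subsample every ROI (seeded, without replacement) to the smallest size."""
    sizes = rois.sizes()
    if any(n == 0 for n in sizes.values()):
        raise ValueError("cannot equalize: empty ROI")
    n_min = min(sizes.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name in rois.rois:
        pixels = sorted(rois.rois[name])
        idx = rng.choice(len(pixels), size=n_min, replace=False)
        out[name] = {pixels[i] for i in idx}
    return ROISet(rois=out, provenance=rois.provenance)
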