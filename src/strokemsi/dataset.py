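"""Core MSI data model: raster of pixel spectra, imzML I/O, annotation masks.

Coordinate convention: 0-based integer raster indices, origin top-left,
``x`` = column (rightward), ``y`` = row (downward). imzML stores 1-based
coordinates; they are converted on read and write. Missing pixels
(non-rectangular tissue outlines) are allowed: all statistics downstream
operate on the pixel list, never on a dense grid.

Continuous-mode data share one mass axis and are held as a dense
``(n_pixels, n_mz)`` intensity matrix. Processed-mode data keep one
``(mz, intensity)`` pair per pixel; :func:`resample_to_axis` is the single
place where axes are unified (linear interpolation), so no resampling ever
happens silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon


@dataclass
class MassAxis:
    """Ascending m/z axis shared by the spectra of a continuous-mode dataset."""

    values: np.ndarray
    mode: str = "profile"  # "profile" | "centroid"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("mass axis must be a 1D array of length >= 1")
        if np.any(self.values <= 0):
            raise ValueError("mass axis values must be > 0")
        if self.values.size > 1 and np.any(np.diff(self.values) <= 0):
            raise ValueError("mass axis must be strictly increasing")
        if self.mode not in ("profile", "centroid"):
            raise ValueError("mode must be 'profile' or 'centroid'")

    def __len__(self):
        return self.values.size

    def window_slice(self, center: float, half_width: float) -> slice:
        """Index slice of axis points within ``center ± half_width``."""
        lo = int(np.searchsorted(self.values, center - half_width, side="left"))
        hi = int(np.searchsorted(self.values, center + half_width, side="right"))
        return slice(lo, hi)


@dataclass
class MSIDataset:
    """2D raster of mass spectra with polarity and pixel-size metadata.

    Either ``intensities`` (continuous mode, rows aligned with ``coords``)
    or ``spectra`` (processed mode, a list of ``(mz, intensity)`` arrays)
    is populated.
    """

    coords: np.ndarray  # (N, 2) int, columns (x, y)
    axis: MassAxis | None = None
    intensities: np.ndarray | None = None
    spectra: list | None = None
    polarity: str = "unknown"  # positive | negative | unknown
    pixel_size_um: float = 50.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (N, 2) array")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("duplicate pixel coordinates")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.polarity not in ("positive", "negative", "unknown"):
            raise ValueError("polarity must be positive, negative or unknown")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities)
            if self.axis is None:
                raise ValueError("continuous-mode dataset requires a shared axis")
            if self.intensities.shape != (len(self.coords), len(self.axis)):
                raise ValueError("intensities must be (n_pixels, n_mz)")
            if np.any(self.intensities < 0):
                raise ValueError("intensities must be nonnegative")
        elif self.spectra is not None:
            if len(self.spectra) != len(self.coords):
                raise ValueError("one spectrum per pixel required")
        else:
            raise ValueError("no pixels: provide intensities or spectra")
        if len(self.coords) == 0:
            raise ValueError("no pixels")

    # -- basic queries -------------------------------------------------

    @property
    def is_continuous(self) -> bool:
        return self.intensities is not None

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid, origin (0, 0)."""
        return int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1

    def pixel_index(self) -> dict:
        """Map (x, y) tuple -> row index."""
        return {(int(x), int(y)): i for i, (x, y) in enumerate(self.coords)}

    def tic(self) -> np.ndarray:
        """Total ion count per pixel."""
        if self.is_continuous:
            return self.intensities.sum(axis=1, dtype=float)
        return np.array([float(np.sum(i)) for _, i in self.spectra])

    def copy_with(self, intensities: np.ndarray) -> "MSIDataset":
        return MSIDataset(
            coords=self.coords.copy(),
            axis=self.axis,
            intensities=intensities,
            polarity=self.polarity,
            pixel_size_um=self.pixel_size_um,
            metadata=dict(self.metadata),
        )


def resample_to_axis(dataset: MSIDataset, axis_values: np.ndarray) -> MSIDataset:
    """Resample a processed-mode dataset onto a common axis (linear interpolation)."""
    axis = MassAxis(axis_values)
    if dataset.is_continuous:
        src = dataset.axis.values
        mat = np.stack([np.interp(axis.values, src, row, left=0.0, right=0.0)
                        for row in dataset.intensities])
    else:
        mat = np.stack([np.interp(axis.values, mz, inten, left=0.0, right=0.0)
                        for mz, inten in dataset.spectra])
    return MSIDataset(
        coords=dataset.coords.copy(),
        axis=axis,
        intensities=np.clip(mat, 0.0, None),
        polarity=dataset.polarity,
        pixel_size_um=dataset.pixel_size_um,
        metadata=dict(dataset.metadata),
    )


# -- imzML I/O ---------------------------------------------------------


def write_imzml(dataset: MSIDataset, path: str) -> str:
    """Write a dataset as an imzML/ibd file pair; returns the .imzML path."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    if not path.endswith(".imzML"):
        path = path + ".imzML"
    mode = "continuous" if dataset.is_continuous else "processed"
    polarity = dataset.polarity if dataset.polarity != "unknown" else None
    with ImzMLWriter(path, mode=mode, polarity=polarity,
                     intensity_dtype=np.float64) as writer:
        if dataset.is_continuous:
            mz = dataset.axis.values
            for (x, y), row in zip(dataset.coords, dataset.intensities):
                writer.addSpectrum(mz, np.asarray(row, dtype=float),
                                   (int(x) + 1, int(y) + 1, 1))
        else:
            for (x, y), (mz, inten) in zip(dataset.coords, dataset.spectra):
                writer.addSpectrum(np.asarray(mz, float), np.asarray(inten, float),
                                   (int(x) + 1, int(y) + 1, 1))
    return path


def read_imzml(path: str) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Continuous-mode files yield a shared axis; processed-mode spectra are
    stored as-is (use :func:`resample_to_axis` to unify axes on request).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise ValueError(f"malformed imzML file {path!r}: {exc}") from exc

    polarity = getattr(parser, "polarity", "") or ""
    if polarity not in ("positive", "negative"):
        warnings.warn("imzML file does not record polarity; set to 'unknown'")
        polarity = "unknown"

    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=int)
    if len(coords) == 0:
        raise ValueError("no pixels in imzML file")
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("duplicate pixel coordinates in imzML file")

    mzs, intens = [], []
    for i in range(len(parser.coordinates)):
        mz, inten = parser.getspectrum(i)
        mzs.append(np.asarray(mz, dtype=float))
        intens.append(np.clip(np.asarray(inten, dtype=float), 0.0, None))

    pixel_size = float(parser.imzmldict.get("pixel size x", 50.0) or 50.0)
    continuous = all(m.shape == mzs[0].shape and np.array_equal(m, mzs[0]) for m in mzs)
    if continuous:
        return MSIDataset(
            coords=coords,
            axis=MassAxis(mzs[0]),
            intensities=np.stack(intens),
            polarity=polarity,
            pixel_size_um=pixel_size,
        )
    return MSIDataset(
        coords=coords,
        spectra=list(zip(mzs, intens)),
        polarity=polarity,
        pixel_size_um=pixel_size,
    )


# -- annotation masks --------------------------------------------------


@dataclass
class AnnotationMask:
    """Named pixel set or polygon annotation (e.g. a necrotic-border outline).

    Polygons are in pixel coordinates; a pixel belongs to the mask when its
    center (integer coordinate) falls strictly inside the polygon.
    """

    name: str
    pixels: set | None = None
    polygon: np.ndarray | None = None

    def __post_init__(self):
        if (self.pixels is None) == (self.polygon is None):
            raise ValueError("provide exactly one of pixels or polygon")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
                raise ValueError("polygon must be an (V>=3, 2) array")
        if self.pixels is not None:
            self.pixels = {(int(x), int(y)) for x, y in self.pixels}


def rasterize_mask(mask: AnnotationMask, dataset: MSIDataset) -> set:
    """Pixels of ``dataset`` covered by ``mask``.

    Pixel-set masks pass through unchanged. Polygon masks select the grid
    pixels whose centers fall inside the polygon (even-odd rule);
    self-intersecting polygons are rejected. Vertices outside the grid
    bounding box are allowed with a warning (the selection is implicitly
    clipped to existing pixels).
    """
    if mask.pixels is not None:
        return set(mask.pixels)
    poly = Polygon(mask.polygon)
    if not poly.is_simple or not poly.is_valid:
        raise ValueError("self-intersecting polygon")
    h, w = dataset.grid_shape()
    verts = mask.polygon
    if (verts[:, 0].min() < -0.5 or verts[:, 0].max() > w - 0.5
            or verts[:, 1].min() < -0.5 or verts[:, 1].max() > h - 0.5):
        warnings.warn(f"polygon {mask.name!r} extends beyond the grid; clipping")
    xs = dataset.coords[:, 0].astype(float)
    ys = dataset.coords[:, 1].astype(float)
    inside = contains_xy(poly, xs, ys)
    return {(int(x), int(y)) for (x, y), ok in zip(dataset.coords, inside) if ok}


def read_mask(path: str, name: str = "mask") -> AnnotationMask:
    """Read a mask from a 2-column pixel CSV/TSV or a polygon text file.

    A file whose header contains ``vertex`` columns (``vx, vy``) is read as a
    polygon; otherwise rows are (x, y) pixel indices.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if "vx" in cols and "vy" in cols:
        return AnnotationMask(name=name, polygon=df[["vx", "vy"]].to_numpy(float))
    return AnnotationMask(name=name, pixels=set(map(tuple, df.iloc[:, :2].to_numpy(int))))


def write_mask(pixels: set, path: str) -> None:
    import pandas as pd

    pd.DataFrame(sorted(pixels), columns=["x", "y"]).to_csv(path, sep="\t", index=False)
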