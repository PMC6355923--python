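"""Synthetic ischemic-brain MSI phantom with known ground truth.

The phantom emulates a coronal mouse-brain section after unilateral
ischemic stroke as seen by MALDI-MSI: two hemispheres split at the midline
column, an elliptical infarct core inside the ipsilateral hemisphere, a
penumbra annulus around it, and surrounding healthy tissue. Each tissue
pixel carries a profile-mode spectrum built from Gaussian peaks of a
configurable lipid panel; off-tissue pixels carry matrix-cluster peaks only.

Three biological effects structure the signal:

* **Cation exchange** — sodiated and potassiated PC/LPC ions compete for a
  shared cationized pool of each species. The per-region Na/K field splits
  that pool as ``na/(na+k)`` vs ``k/(na+k)``, so ischemic tissue (high Na,
  low K) shows elevated [M+Na]+ and depressed [M+K]+ at unchanged [M+H]+,
  and swapping the field levels swaps the two adduct images exactly.
* **Lyso-lipid accumulation** — LPC species rise in the core over 4/8/24 h
  (membrane breakdown products of phospholipase activation).
* **Phosphoinositide turnaround** — PIP(38:4) rises in the penumbra ring at
  24 h while PIP2(38:4) falls in the core from 8 h.

Noise model: Poisson on expected counts, an additive Gaussian floor, and a
log-normal per-pixel TIC factor (making TIC normalization consequential).
Everything is deterministic given the seed, and the generator returns a
:class:`PhantomTruth` with region labels and expected intensities against
which recovery is tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import MassAxis, MSIDataset
from .lipids import adduct_mz, parse_formula

REGIONS = ("healthy_contra", "healthy_ipsi", "penumbra", "core")
TIME_POINTS = (4, 8, 24)
OFF_TISSUE = "off_tissue"
#: adduct tags drawing on the shared cationized pool
CATION_ADDUCTS = ("+Na", "+K")

#: Na/K field levels per region (arbitrary concentration units). Chosen so the
#: effective sodiated multiplier healthy→core is 2.5x and the potassiated one
#: 0.4x, with intermediate ipsilateral/penumbra levels.
DEFAULT_CATION_FIELD = {
    "healthy_contra": (2.0, 5.0),
    "healthy_ipsi": (2.8, 4.2),
    "penumbra": (3.85, 3.15),
    "core": (5.0, 2.0),
}


@dataclass
class SpeciesSpec:
    """One lipid species of the phantom panel.

    ``adducts`` maps adduct tag -> base peak amplitude (expected counts at
    the peak apex in healthy contralateral tissue up to the multiplier).
    ``region_time_multipliers`` maps adduct tag -> region -> time (h) ->
    nonnegative factor; for +Na/+K these are the *effective* multipliers
    implied by the default cation field (the generator re-derives the
    partition from the configured field at run time).
    """

    name: str
    formula: str
    adducts: dict
    region_time_multipliers: dict

    def __post_init__(self):
        if not self.adducts:
            raise ValueError(f"{self.name}: at least one adduct required")
        parse_formula(self.formula)  # validates elements
        for tag, table in self.region_time_multipliers.items():
            if tag not in self.adducts:
                raise ValueError(f"{self.name}: multipliers for unknown adduct {tag}")
            for region, by_time in table.items():
                if region not in REGIONS:
                    raise ValueError(f"{self.name}: unknown region {region}")
                for t, m in by_time.items():
                    if m < 0:
                        raise ValueError(f"{self.name}: negative multiplier at {region}/{t}h")

    def multiplier(self, adduct: str, region: str, time: int) -> float:
        return float(self.region_time_multipliers[adduct][region][time])


def cation_partition(base: float, na_level: float, k_level: float, adduct: str) -> float:
    """Share of a cationized pool taken by one adduct.

    ``+Na`` receives ``na/(na+k)`` of ``base``, ``+K`` receives ``k/(na+k)``;
    any other adduct is unaffected by the field. The two shares always sum
    to the pool, so total cationized signal is conserved.
    """
    if base < 0:
        raise ValueError("base intensity must be >= 0")
    if adduct not in CATION_ADDUCTS:
        return float(base)
    total = na_level + k_level
    if total <= 0:
        raise ValueError("na_level + k_level must be > 0")
    share = na_level / total if adduct == "+Na" else k_level / total
    return float(base * share)


def _flat(value: float = 1.0) -> dict:
    return {r: {t: value for t in TIME_POINTS} for r in REGIONS}


def _with_regions(**overrides) -> dict:
    table = _flat()
    for region, by_time in overrides.items():
        table[region] = {t: float(by_time[t]) if isinstance(by_time, dict) else float(by_time)
                         for t in TIME_POINTS}
    return table


def _cation_effective(structural: dict, field_levels: dict, adduct: str) -> dict:
    """Effective multiplier table: structural factor x 2*(field share).

    The factor 2 makes a balanced field (na == k) the unit reference, so the
    quoted healthy→core ratios (2.5x sodiated, 0.4x potassiated) read off
    directly from the table.
    """
    out = {}
    for region in REGIONS:
        na, k = field_levels[region]
        share = cation_partition(1.0, na, k, adduct)
        out[region] = {t: structural[region][t] * 2.0 * share for t in TIME_POINTS}
    return out


def default_species_table(polarity: str, cation_field: dict | None = None,
                          penumbra_amplification: float = 1.0) -> list:
    """Default lipid panel with region/time effect structure.

    Positive mode: PC(32:0), PC(34:1), PC(36:1) and LPC(16:0) with +H/+Na/+K;
    [M+H]+ is flat across regions, sodiated multipliers rise healthy→core and
    potassiated ones fall (cation exchange), and LPC rises in the core over
    4→24 h. Negative mode: PI(38:4) flat, PIP(38:4) up in the penumbra only
    at 24 h and down in the core, PIP2(38:4) down in core and penumbra from
    8 h, plus PS(40:6) and palmitate as stable background species.

    ``penumbra_amplification`` scales the penumbra deviations from unity
    (the "mutant" phantom with enhanced stroke susceptibility uses 1.5).
    """
    field_levels = dict(cation_field or DEFAULT_CATION_FIELD)
    a = float(penumbra_amplification)
    if a != 1.0:
        na, k = field_levels["penumbra"]
        ratio = (na / k) ** a
        total = na + k
        field_levels["penumbra"] = (total * ratio / (1 + ratio), total / (1 + ratio))

    def amp_pen(table: dict) -> dict:
        if a == 1.0:
            return table
        out = {r: dict(bt) for r, bt in table.items()}
        out["penumbra"] = {t: max(0.0, 1.0 + a * (m - 1.0))
                           for t, m in table["penumbra"].items()}
        return out

    def cationized(structural: dict, bases: tuple) -> tuple[dict, dict]:
        adducts = {"+H": bases[0], "+Na": bases[1], "+K": bases[2]}
        mult = {
            "+H": structural,
            "+Na": _cation_effective(structural, field_levels, "+Na"),
            "+K": _cation_effective(structural, field_levels, "+K"),
        }
        return adducts, mult

    if polarity == "positive":
        pc_flat = _flat(1.0)
        lpc = amp_pen(_with_regions(
            healthy_ipsi=1.2,
            penumbra={4: 1.2, 8: 1.5, 24: 2.0},
            core={4: 1.5, 8: 2.5, 24: 4.0},
        ))
        species = []
        for name, formula, bases in [
            ("PC(32:0)", "C40H80NO8P", (20.0, 5.5, 5.5)),
            ("PC(34:1)", "C42H82NO8P", (24.0, 6.5, 6.5)),
            ("PC(36:1)", "C44H86NO8P", (16.0, 4.5, 4.5)),
        ]:
            adducts, mult = cationized(pc_flat, bases)
            species.append(SpeciesSpec(name, formula, adducts, mult))
        adducts, mult = cationized(lpc, (8.0, 3.5, 3.5))
        species.append(SpeciesSpec("LPC(16:0)", "C24H50NO7P", adducts, mult))
        return species

    if polarity == "negative":
        pip = amp_pen(_with_regions(
            penumbra={4: 0.8, 8: 0.8, 24: 2.0},
            core={4: 0.8, 8: 0.6, 24: 0.6},
        ))
        pip2 = amp_pen(_with_regions(
            penumbra={4: 0.9, 8: 0.6, 24: 0.9},
            core={4: 0.9, 8: 0.5, 24: 0.3},
        ))
        return [
            SpeciesSpec("PI(38:4)", "C47H83O13P", {"-H": 160.0}, {"-H": _flat()}),
            SpeciesSpec("PS(40:6)", "C46H78NO10P", {"-H": 130.0}, {"-H": _flat()}),
            SpeciesSpec("PIP(38:4)", "C47H84O16P2", {"-H": 70.0}, {"-H": pip}),
            SpeciesSpec("PIP2(38:4)", "C47H85O19P3", {"-H": 55.0}, {"-H": pip2}),
        ]

    raise ValueError("polarity must be 'positive' or 'negative'")


DEFAULT_MATRIX_PEAKS = {
    "positive": [(550.2, 50.0), (716.1, 35.0)],
    "negative": [(616.2, 100.0), (666.3, 80.0)],
}


@dataclass
class PhantomConfig:
    """Geometry, panel, fields, noise and axis of one phantom section."""

    polarity: str = "positive"
    time_point: int = 24
    width: int = 80
    height: int = 60
    split_col: int = 40  # ipsilateral = x >= split_col
    tissue_center: tuple = (39.5, 29.5)
    tissue_semiaxes: tuple = (36.0, 26.0)
    core_center: tuple = (58.0, 30.0)
    core_semiaxes: tuple = (12.0, 8.0)
    annulus_width: float = 5.0
    species: list = None
    cation_field: dict = None
    peak_sigma: float = 0.1  # Da
    mz_range: tuple = None  # (min, max); default by polarity
    mz_step: float = 0.1
    poisson_noise: bool = True
    gaussian_sigma: float = 0.5  # additive counts floor
    tic_sigma: float = 0.2  # log-normal per-pixel TIC spread
    matrix_peaks: list = None
    matrix_on_tissue: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.time_point not in TIME_POINTS:
            raise ValueError(f"time_point must be one of {TIME_POINTS}")
        if self.annulus_width < 1:
            raise ValueError("annulus width must be >= 1 pixel")
        if self.peak_sigma <= 0:
            raise ValueError("peak sigma must be > 0")
        cx, _cy = self.core_center
        if cx - self.core_semiaxes[0] < self.split_col:
            raise ValueError("core ellipse must lie strictly inside the ipsilateral hemisphere")
        if self.species is None:
            self.species = default_species_table(self.polarity)
        if self.cation_field is None:
            self.cation_field = dict(DEFAULT_CATION_FIELD)
        for region in REGIONS:
            na, k = self.cation_field[region]
            if na + k <= 0 or na < 0 or k < 0:
                raise ValueError(f"invalid cation field for {region}")
        if self.mz_range is None:
            self.mz_range = (400.0, 1000.0) if self.polarity == "positive" else (600.0, 1600.0)
        if self.matrix_peaks is None:
            self.matrix_peaks = list(DEFAULT_MATRIX_PEAKS[self.polarity])

    def axis_values(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.mz_step)) + 1
        return lo + np.arange(n) * self.mz_step


def mutant_config(config: PhantomConfig, amplification: float = 1.5) -> PhantomConfig:
    """Phantom variant with amplified penumbra effects (enhanced-susceptibility genotype)."""
    species = default_species_table(config.polarity, penumbra_amplification=amplification)
    field_levels = dict(config.cation_field)
    na, k = field_levels["penumbra"]
    ratio = (na / k) ** amplification
    total = na + k
    field_levels["penumbra"] = (total * ratio / (1 + ratio), total / (1 + ratio))
    return replace(config, species=species, cation_field=field_levels)


@dataclass
class PhantomTruth:
    """Ground truth of one generated phantom: labels, expectations, config."""

    labels: np.ndarray  # region name per pixel, aligned with dataset coords
    coords: np.ndarray
    expected_spectra: dict  # region (incl. off_tissue) -> expected spectrum
    expected_ions: pd.DataFrame  # species, adduct, mz, region, amplitude
    config: PhantomConfig
    axis: MassAxis

    def region_pixels(self, region: str) -> set:
        idx = np.flatnonzero(self.labels == region)
        return {(int(x), int(y)) for x, y in self.coords[idx]}

    def tissue_pixels(self) -> set:
        idx = np.flatnonzero(self.labels != OFF_TISSUE)
        return {(int(x), int(y)) for x, y in self.coords[idx]}

    def roi_set(self):
        from .segmentation import ROISet

        return ROISet(
            rois={r: self.region_pixels(r) for r in REGIONS},
            provenance="manual",
        )

    def expected_window_intensity(self, region: str, center: float,
                                  half_width: float = 0.3) -> float:
        """Expected (noise-free, unit-TIC) integrated intensity in a window."""
        sl = self.axis.window_slice(center, half_width)
        return float(self.expected_spectra[region][sl].sum())

    def expected_fold(self, center: float, region_num: str, region_den: str,
                      half_width: float = 0.3) -> float:
        return (self.expected_window_intensity(region_num, center, half_width)
                / self.expected_window_intensity(region_den, center, half_width))

    def expected_measured_window_intensity(self, region: str, center: float,
                                           half_width: float = 0.3) -> float:
        """Expected window intensity under the full noise model.

        Accounts for the positive baseline the zero-clipped additive Gaussian
        floor contributes: per axis sample, E[max(K + G, 0)] with
        K ~ Poisson(lambda) and G ~ N(0, sigma^2), summed over the window
        (exact up to Poisson-tail truncation). Reduces to the noise-free
        expectation when the floor is off.
        """
        from scipy.stats import norm, poisson

        sl = self.axis.window_slice(center, half_width)
        lam = self.expected_spectra[region][sl]
        sigma = self.config.gaussian_sigma
        if sigma <= 0:
            return float(lam.sum())  # clipped Poisson is already nonnegative
        total = 0.0
        for lam_i in lam:
            if self.config.poisson_noise:
                k_max = int(max(20, lam_i + 10 * np.sqrt(lam_i + 1)))
                k = np.arange(k_max + 1)
                weights = poisson.pmf(k, lam_i)
                mu = k.astype(float)
            else:
                weights = np.array([1.0])
                mu = np.array([lam_i])
            clipped = mu * norm.cdf(mu / sigma) + sigma * norm.pdf(mu / sigma)
            total += float(weights @ clipped)
        return total

    def expected_measured_fold(self, center: float, region_num: str,
                               region_den: str, half_width: float = 0.3) -> float:
        """Expected fold of measured window means between two regions.

        The per-pixel log-normal TIC factor is common to both regions and
        cancels in the ratio to first order.
        """
        return (self.expected_measured_window_intensity(region_num, center, half_width)
                / self.expected_measured_window_intensity(region_den, center, half_width))

    def border_polygon(self, n_vertices: int = 72, outer: bool = True) -> np.ndarray:
        """Polygon outlining the infarct (core + penumbra if ``outer``)."""
        cfg = self.config
        a, b = cfg.core_semiaxes
        if outer:
            a, b = a + cfg.annulus_width, b + cfg.annulus_width
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        cx, cy = cfg.core_center
        return np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])


def _inside_ellipse(x, y, center, semiaxes) -> np.ndarray:
    return (((x - center[0]) / semiaxes[0]) ** 2
            + ((y - center[1]) / semiaxes[1]) ** 2) <= 1.0


def region_labels(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(coords, labels) for every pixel of the raster grid."""
    xs, ys = np.meshgrid(np.arange(config.width), np.arange(config.height))
    x, y = xs.ravel(), ys.ravel()
    coords = np.column_stack([x, y])
    tissue = _inside_ellipse(x, y, config.tissue_center, config.tissue_semiaxes)
    core = _inside_ellipse(x, y, config.core_center, config.core_semiaxes) & tissue
    outer = _inside_ellipse(
        x, y, config.core_center,
        (config.core_semiaxes[0] + config.annulus_width,
         config.core_semiaxes[1] + config.annulus_width)) & tissue
    ipsi = x >= config.split_col
    labels = np.full(len(x), OFF_TISSUE, dtype=object)
    labels[tissue & ~ipsi] = "healthy_contra"
    labels[tissue & ipsi] = "healthy_ipsi"
    labels[outer & ipsi] = "penumbra"
    labels[core] = "core"
    return coords, labels.astype(str)


def expected_amplitude(species: SpeciesSpec, adduct: str, region: str,
                       time: int, cation_field: dict) -> float:
    """Expected apex amplitude of one adduct peak in one region.

    +Na/+K draw on the shared cationized pool of the species (sum of both
    adducts' base x multiplier), split by the region's Na/K field levels;
    protonated/deprotonated adducts are base x multiplier directly.
    """
    if adduct in CATION_ADDUCTS:
        pool = sum(species.adducts[a] * species.multiplier(a, region, time)
                   for a in CATION_ADDUCTS if a in species.adducts)
        na, k = cation_field[region]
        return cation_partition(pool, na, k, adduct)
    return float(species.adducts[adduct] * species.multiplier(adduct, region, time))


def generate(config: PhantomConfig) -> tuple[MSIDataset, PhantomTruth]:
    """Generate one phantom section and its ground truth.

    Deterministic given ``config.seed``: every tissue pixel's spectrum is the
    sum over species/adducts of a Gaussian peak (sigma ``peak_sigma``) scaled
    by region-time multiplier, cation partition and a log-normal per-pixel
    TIC factor, plus matrix peaks, Poisson/Gaussian noise, clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    axis = MassAxis(config.axis_values())
    values = axis.values
    coords, labels = region_labels(config)
    t = config.time_point

    # expected ion amplitudes per region
    ion_rows = []
    for species in config.species:
        for adduct in species.adducts:
            mz = adduct_mz(species.formula, adduct)
            if not (values[0] <= mz <= values[-1]):
                warnings.warn(
                    f"{species.name} {adduct} at m/z {mz:.2f} outside axis range; dropped")
                continue
            for region in REGIONS:
                ion_rows.append({
                    "species": species.name, "adduct": adduct, "mz": mz,
                    "region": region,
                    "amplitude": expected_amplitude(species, adduct, region, t,
                                                    config.cation_field),
                })
    expected_ions = pd.DataFrame(
        ion_rows, columns=["species", "adduct", "mz", "region", "amplitude"])

    def gaussian(mz: float, amp: float, out: np.ndarray) -> None:
        sl = axis.window_slice(mz, 6 * config.peak_sigma)
        out[sl] += amp * np.exp(-0.5 * ((values[sl] - mz) / config.peak_sigma) ** 2)

    expected_spectra = {}
    matrix_spec = np.zeros(len(axis))
    for mz, amp in config.matrix_peaks:
        if values[0] <= mz <= values[-1]:
            gaussian(mz, amp, matrix_spec)
    for region in REGIONS:
        spec = config.matrix_on_tissue * matrix_spec.copy()
        sub = expected_ions[expected_ions["region"] == region]
        for rec in sub.itertuples(index=False):
            gaussian(rec.mz, rec.amplitude, spec)
        expected_spectra[region] = spec
    expected_spectra[OFF_TISSUE] = matrix_spec

    # assemble per-pixel expectations; restrict Poisson draws to active columns
    n_pixels = len(coords)
    tic_factors = (rng.lognormal(mean=0.0, sigma=config.tic_sigma, size=n_pixels)
                   if config.tic_sigma > 0 else np.ones(n_pixels))
    region_matrix = np.stack([expected_spectra[lab] for lab in labels])
    lam = region_matrix * tic_factors[:, None]
    active = np.flatnonzero(region_matrix.max(axis=0) > 1e-12)
    intensities = np.zeros((n_pixels, len(axis)))
    if config.poisson_noise:
        intensities[:, active] = rng.poisson(lam[:, active]).astype(float)
    else:
        intensities[:, active] = lam[:, active]
    if config.gaussian_sigma > 0:
        intensities += rng.normal(0.0, config.gaussian_sigma, size=intensities.shape)
    np.clip(intensities, 0.0, None, out=intensities)

    dataset = MSIDataset(
        coords=coords,
        axis=axis,
        intensities=intensities.astype(np.float32),
        polarity=config.polarity,
        pixel_size_um=50.0,
        metadata={"phantom_seed": config.seed, "time_point_h": t},
    )
    truth = PhantomTruth(labels=labels, coords=coords,
                         expected_spectra=expected_spectra,
                         expected_ions=expected_ions, config=config, axis=axis)
    return dataset, truth
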