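"""End-to-end analysis pipeline: input -> preprocess -> segment -> decompose
-> LDA -> quantify -> annotate, driven by one config with one seed.

Every stage writes plain-text artifacts (TSV/JSON) under the run directory
and the run manifest records each file with a checksum together with a full
parameter echo, so a run is reproducible and stages can be re-run
individually through the library API. Defaults that fill gaps left open by
upstream software behavior (robust-TIC denoise rule, correlation distance,
percentile-bootstrap CI) are echoed in the manifest log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import read_imzml, write_mask
from .decomposition import exclude_matrix_components, pca_fit, plsa_components_report, plsa_fit
from .discriminant import lda_fit, lda_separability, rois_to_classes
from .lipids import annotate_peaks, load_lipid_table, table_ions
from .phantom import PhantomConfig, generate
from .preprocess import integrate, mean_spectrum, pick_peaks, tic_normalize
from .quantify import fold_change
from .segmentation import ROISet, equalize_rois, label_regions, segment

logger = logging.getLogger("strokemsi")

#: pLSA component counts per polarity
DEFAULT_N_COMPONENTS = {"positive": 10, "negative": 7}


@dataclass
class PipelineConfig:
    polarity: str
    input_path: str | None = None  # imzML path; None -> phantom input
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    denoise: str = "weak"
    snr_min: float = 3.0
    half_width: float = 0.3
    k: int = 4
    distance: str = "correlation"
    spatial_denoise: bool = True
    n_components: int | None = None  # pLSA; default by polarity
    pca_components: int = 5
    variance_retained: float = 0.8
    n_boot: int = 2000
    quant_windows: list = field(default_factory=list)  # m/z centers; default from lipid table
    seed: int = 0
    out_dir: str = "strokemsi_run"

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("config must state polarity ('positive' or 'negative')")
        if self.n_components is None:
            self.n_components = DEFAULT_N_COMPONENTS[self.polarity]
        if self.n_components < 1 or self.pca_components < 1:
            raise ValueError("component counts must be >= 1")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    log_lines = []

    def note(msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")
        logger.info(msg)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- input ---------------------------------------------------------
    truth = None
    if config.input_path is None:
        pconf = PhantomConfig(polarity=config.polarity, seed=config.seed,
                              **config.phantom)
        dataset, truth = stage("phantom")(generate, pconf)
        note(f"phantom generated: {dataset.n_pixels} pixels, seed {config.seed}")
    else:
        dataset = stage("read")(read_imzml, config.input_path)
        note(f"loaded {config.input_path}: {dataset.n_pixels} pixels")

    # --- preprocess ----------------------------------------------------
    normalized = stage("tic_normalize")(tic_normalize, dataset, config.denoise)
    note(f"TIC-normalized (denoise={config.denoise}: percentile-guard robust TIC)")
    mean_spec = stage("mean_spectrum")(mean_spectrum, normalized)
    peaks = stage("pick_peaks")(pick_peaks, normalized.axis.values, mean_spec,
                                config.snr_min, config.half_width)
    if not peaks:
        raise RuntimeError("pipeline stage 'pick_peaks' failed: no peaks found")
    peaks_path = out / "peaks.tsv"
    pd.DataFrame({"center": [w.center for w in peaks],
                  "half_width": [w.half_width for w in peaks]}
                 ).to_csv(peaks_path, sep="\t", index=False)
    files.append(peaks_path)
    matrix = stage("integrate")(integrate, normalized, peaks)
    note(f"{len(peaks)} peaks integrated over {matrix.n_pixels} pixels")

    # --- segmentation --------------------------------------------------
    if truth is not None:
        tissue = truth.tissue_pixels()
        split_col = truth.config.split_col
    else:
        from skimage.filters import threshold_otsu

        tic = dataset.tic()
        mask = tic > threshold_otsu(tic)
        tissue = {(int(x), int(y)) for (x, y), m in zip(dataset.coords, mask) if m}
        split_col = int(dataset.coords[:, 0].max() + 1) // 2
    seg = stage("segment")(segment, matrix, config.k, config.distance,
                           config.seed, tissue, config.spatial_denoise)
    ipsi = {p for p in tissue if p[0] >= split_col}
    rois = stage("label_regions")(label_regions, seg, ipsi, matrix)
    seg_path = out / "segmentation.tsv"
    pd.DataFrame({"x": seg.coords[:, 0], "y": seg.coords[:, 1],
                  "label": seg.labels}).to_csv(seg_path, sep="\t", index=False)
    files.append(seg_path)
    for name, pixels in rois.rois.items():
        path = out / f"roi_{name}.tsv"
        write_mask(pixels, path)
        files.append(path)
    note(f"segmentation k={config.k}, distance={config.distance}; "
         f"ROI sizes {rois.sizes()}")

    # --- decomposition -------------------------------------------------
    n_comp = min(config.n_components, len(matrix.windows))
    if n_comp < config.n_components:
        note(f"pLSA components clamped to peak count: {n_comp}")
    model = stage("plsa")(plsa_fit, matrix, n_comp, config.seed)
    offtissue = ({(int(x), int(y)) for x, y in matrix.coords} - tissue)
    if offtissue:
        excl = exclude_matrix_components(model, offtissue)
        note(f"pLSA matrix components flagged: {excl['flagged']}")
        kept = excl["kept"]
    else:
        kept = list(range(model.n_components))
    report = plsa_components_report(model, top_n=10, keep=kept)
    plsa_path = out / "plsa_loadings.tsv"
    report["loadings"].to_csv(plsa_path, sep="\t", index=False)
    files.append(plsa_path)

    pca = stage("pca")(pca_fit, matrix, config.pca_components)
    pca_path = out / "pca_variance.tsv"
    pd.DataFrame({"component": np.arange(len(pca.explained_variance_ratio)),
                  "explained_variance_ratio": pca.explained_variance_ratio}
                 ).to_csv(pca_path, sep="\t", index=False)
    files.append(pca_path)

    # --- discriminant --------------------------------------------------
    classes = rois_to_classes(rois)
    lda = stage("lda")(lda_fit, matrix, classes, config.variance_retained, config.seed)
    lda_path = out / "lda_histograms.tsv"
    hist_rows = []
    for name, counts in lda.histograms.items():
        for edge, count in zip(lda.bin_edges[:-1], counts):
            hist_rows.append({"class": name, "bin_left": edge, "count": int(count)})
    pd.DataFrame(hist_rows).to_csv(lda_path, sep="\t", index=False)
    files.append(lda_path)
    overlap = lda_separability(lda, "borderzone", "healthy")
    note(f"LDA: {lda.n_functions} functions, {lda.n_pca_components} PCs retained; "
         f"borderzone-healthy DF1 overlap {overlap:.3f}")

    # --- quantify ------------------------------------------------------
    centers = config.quant_windows or sorted(
        table_ions(load_lipid_table(), polarity=config.polarity)["mz"])
    eq = equalize_rois(ROISet(rois={"core": rois["core"],
                                    "healthy_contra": rois["healthy_contra"]}),
                       seed=config.seed)
    fc_rows = []
    for center in centers:
        try:
            window = matrix.windows[matrix.window_index(center)]
        except KeyError:
            continue
        est = fold_change(matrix, window, eq["core"], eq["healthy_contra"],
                          n_boot=config.n_boot, seed=config.seed)
        fc_rows.append({"mz": window.center, "fold": est.fold, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "n_boot": est.n_boot,
                        "seed": est.seed, "n_pixels": est.n_pixels})
    fc_path = out / "fold_changes.tsv"
    pd.DataFrame(fc_rows, columns=["mz", "fold", "ci_low", "ci_high",
                                   "n_boot", "seed", "n_pixels"]
                 ).to_csv(fc_path, sep="\t", index=False)
    files.append(fc_path)
    note(f"fold changes (core vs healthy_contra, percentile bootstrap, "
         f"n_boot={config.n_boot}) for {len(fc_rows)} windows")

    # --- annotate ------------------------------------------------------
    ann = annotate_peaks(peaks, load_lipid_table(), tolerance=config.half_width)
    ann_path = out / "annotations.tsv"
    ann.to_csv(ann_path, sep="\t", index=False)
    files.append(ann_path)

    # the timestamped log is written but deliberately not checksummed, so two
    # runs of one config produce identical manifests
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "artifacts": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
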