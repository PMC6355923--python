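# strokemsi

Analysis of MALDI mass-spectrometry-imaging (MSI) data from experimental
ischemic stroke: distinguishing the infarct **core** from the salvageable
**penumbra** and surrounding healthy tissue by their lipid profiles, and
quantifying how those profiles evolve at 4, 8 and 24 h after arterial
occlusion. The package is aimed at MSI practitioners who want the full
chain — preprocessing, spatial segmentation, decomposition, discriminant
analysis, fold-change statistics, cation-ratio imaging, histology
overlay — as tested, scriptable code rather than point-and-click software.

The science in brief. In ischemic tissue the Na⁺/K⁺ balance collapses, so
phosphatidylcholines shift from potassiated to sodiated pseudo-molecular
ions: [M+Na]⁺ rises ~2.5× in the core while [M+K]⁺ falls to ~0.4×, with
[M+H]⁺ unchanged. Lyso-PC species (membrane breakdown products) accumulate
in the core over 24 h, and phosphatidylinositol-phosphate PIP(38:4)
(*m/z* 965.5, [M−H]⁻) rises specifically in the penumbra ring at 24 h
while PIP₂(38:4) (*m/z* 1045.5) falls in the core — a candidate signature
for whether border-zone tissue is about to die.

The package contains:

* `dataset` — MSI data model + imzML 1.1 I/O (via pyimzml), annotation
  masks, polygon rasterization;
* `phantom` — a synthetic ischemic-brain section generator with ground
  truth (region masks, expected intensities), including a
  cation-exchange model in which Na⁺ and K⁺ adducts compete for a shared
  pool, and a "mutant" variant with amplified penumbra effects;
* `preprocess` — robust TIC normalization, mean-spectrum peak picking,
  ±0.3 Da window integration;
* `segmentation` — bisecting k-means (correlation distance) with optional
  spatial denoising, automated core/penumbra/healthy labeling, ROI
  equalization;
* `decomposition` — pLSA by EM (aspect model) with matrix-component
  exclusion, PCA, RGB score overlays;
* `discriminant` — Fisher LDA with PCA pre-reduction (80% variance),
  DF1 score histograms and scaled loadings;
* `quantify` — box statistics, bootstrap fold-change CIs, K⁺/Na⁺ ratio
  images;
* `lipids` — monoisotopic adduct m/z calculator and peak annotation
  against a bundled lipid table;
* `overlay` — landmark similarity registration and linear-transparency
  overlay rendering;
* `pipeline` / `cli` — one-config end-to-end runs with checksummed
  manifests (`strokemsi run`).

## Worked example

```python
from strokemsi import (PhantomConfig, generate, tic_normalize, mean_spectrum,
                       pick_peaks, integrate, segment, label_regions,
                       equalize_rois, fold_change, adduct_mz)
from strokemsi.segmentation import ROISet

# synthetic 24 h section, positive mode, with ground truth
dataset, truth = generate(PhantomConfig(polarity="positive", time_point=24, seed=0))
norm = tic_normalize(dataset)                      # robust ("weak denoise") TIC
peaks = pick_peaks(norm.axis.values, mean_spectrum(norm))
matrix = integrate(norm, peaks)

# segment tissue into 4 classes and name the regions
tissue = truth.tissue_pixels()
seg = segment(matrix, k=4, seed=0, pixels=tissue, spatial_denoise=True)
ipsi = {p for p in tissue if p[0] >= truth.config.split_col}
rois = label_regions(seg, ipsi, matrix)
print({name: len(pix) for name, pix in rois.rois.items()})

# fold change of the sodiated lyso-PC marker, core vs healthy
mz = adduct_mz("C24H50NO7P", "+Na")                # LPC(16:0)+Na, m/z 518.32
eq = equalize_rois(ROISet(rois={"core": rois["core"],
                                "healthy": rois["healthy_contra"]}), seed=0)
est = fold_change(matrix, mz, eq["core"], eq["healthy"], n_boot=2000, seed=0)
print(f"fold {est.fold:.2f}  95% CI [{est.ci_low:.2f}, {est.ci_high:.2f}]")
```

Output:

```
{'healthy_contra': 1472, 'healthy_ipsi': 792, 'penumbra': 383, 'core': 297}
fold 8.67  95% CI [8.22, 9.16]
```

The segmentation finds the four planted tissue classes (the truth holds
1472 / 779 / 396 / 297 pixels; adjusted Rand index 0.91 at this seed).
The sodiated LPC signal is ~9× higher in the core than in contralateral
healthy tissue at 24 h — the product of the 4.0× lyso-lipid accumulation
and the 2.5× sodiation shift the phantom plants, moderated slightly by
TIC normalization and the noise floor (the model's expected measured fold
on the raw scale is 8.88; see `docs/methods.md`).

The same chain runs from the shell:

```sh
strokemsi run --polarity positive --seed 0 --out run0/
strokemsi mz --formula C47H84O16P2 --adduct -H     # 965.5162, PIP(38:4)
```

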