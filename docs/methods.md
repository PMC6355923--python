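# Methods

`strokemsi` implements the analysis chain used to map lipid changes after
experimental ischemic stroke with MALDI mass spectrometry imaging (MSI):
robust TIC normalization, mean-spectrum peak picking, window integration,
spatial segmentation into infarct core / penumbra / healthy tissue,
pLSA and PCA decomposition, Fisher LDA of ROI-labeled pixels, fold-change
quantification with bootstrap confidence intervals, cation-ratio imaging,
and landmark-based histology overlay. Because no public dataset of this
kind exists at desk scale, the package ships a synthetic ischemic-brain
phantom with full ground truth; all statistical claims the test suite makes
are claims about recovery of that known structure.

## Data model

An `MSIDataset` is a list of pixel spectra on an integer raster (0-based,
origin top-left, x = column, y = row), a polarity, and a pixel size in µm.
Continuous-mode data share a strictly increasing m/z axis and are stored as
a dense pixels × m/z matrix; processed-mode spectra are kept per pixel and
only unified through an explicit linear-interpolation resampling utility —
no silent resampling anywhere. imzML 1.1 is read and written through
pyimzml with 1-based coordinate conversion at the boundary. Missing pixels
are first-class: every statistic operates on the pixel list, never on a
dense grid.

## The phantom

The phantom emulates one coronal mouse-brain section per time point
(4, 8, 24 h after arterial occlusion) on an 80 × 60 grid of 50 µm pixels:
an elliptical tissue outline, hemispheres split at the midline column, an
ipsilateral elliptical infarct core (semi-axes 12 × 8 px) with a 5-px
penumbra annulus, surrounding ipsi- and contralateral healthy tissue, and
off-tissue pixels carrying only matrix-cluster peaks (m/z 550.2 and 716.1
in positive mode). Each tissue pixel's profile-mode spectrum is a sum of
Gaussian peaks (σ = 0.1 Da on a 0.1 Da axis; positive mode m/z 400–1000,
negative 600–1600).

Three effects structure the panel:

* **Cation exchange.** Sodiated and potassiated PC/LPC ions compete for a
  shared cationized pool per species. A per-region Na/K field splits the
  pool as `na/(na+k)` vs `k/(na+k)`. Field levels are chosen so that the
  effective sodiated multiplier rises 2.5× from contralateral healthy
  tissue to the core while the potassiated one falls to 0.4×, with
  intermediate ipsilateral and penumbral values; protonated ions are flat.
  Because the pool is symmetric in the two cations, swapping the field
  levels swaps the two adduct images *exactly* — a property the tests
  assert bit-tight on noise-free phantoms.
* **Lyso-lipid accumulation.** LPC(16:0) rises in the core over time
  (structural multipliers 1.5 / 2.5 / 4.0 at 4 / 8 / 24 h) and mildly in
  penumbra and ipsilateral tissue.
* **Phosphoinositide turnaround.** PIP(38:4) is slightly depressed early
  and rises 2.0× in the penumbra only at 24 h while staying low in the
  core; PIP2(38:4) falls in the core from 8 h (0.5×, then 0.3× at 24 h).

Noise is Poisson on expected counts plus an additive Gaussian floor
(σ = 0.5 counts, clipped at zero) and a log-normal per-pixel TIC factor
(σ = 0.2) that makes TIC normalization consequential. Peak apex amplitudes
are in the range ~3–25 counts for the positive-mode lipid panel — the
count statistics of a 50 µm reflector-TOF pixel — which deliberately places
the phantom in the regime the original images show: segmentation maps are
clean after spatial denoising, while per-pixel discriminant score
histograms of penumbra and healthy tissue overlap partially rather than
separating trivially. The generator is bit-reproducible given its seed,
and returns a `PhantomTruth` carrying region labels, the exact noise-free
expected spectrum per region, and per-ion expected amplitudes, so tests
compare estimates against *computed* ground truth rather than constants.

The "mutant" variant (a genotype with enhanced stroke susceptibility)
amplifies penumbra deviations from baseline by 1.5×: structural
multipliers via `1 + 1.5·(m − 1)` and the penumbra Na/K log-ratio by the
same factor at constant total field.

What the phantom does **not** emulate: chemical baseline and matrix
adducts beyond two generic clusters, mass-calibration drift, isotope
envelopes, section-to-section anatomy differences, washed-vs-unwashed
preparation effects, and any biophysics of infarct evolution. Passing
tests therefore demonstrate that the pipeline recovers planted effects of
realistic size under realistic counting noise — not that it would segment
an arbitrary real section without parameter adjustment.

## Preprocessing

TIC normalization scales each spectrum so its TIC equals the dataset mean
TIC. The "weak denoising" variant computes the scaling TIC robustly,
excluding intensities below the spectrum's 5th percentile and above its
99.9th percentile — a baseline/hot-pixel guard standing in for an
undocumented vendor behavior; it is an interpretation, controlled by a
flag, and idempotent. Peak picking runs on the (optionally subset) mean
spectrum: local maxima whose baseline-corrected intensity (above the
spectrum median) reaches `snr_min` (default 3) times a noise estimate
(1.4826 × MAD of the first-difference series); maxima closer than twice
the window half-width are merged onto the more intense center. The
half-width default of ±0.3 Da is the only tolerance the source imagery
used. Integration sums intensities per window and pixel, yielding the
`FeatureMatrix` all statistics consume.

## Segmentation and ROIs

Segmentation is bisecting k-means: split the cluster with the largest
within-cluster scatter by 2-means (10 restarts, seeded) until k clusters
(default k = 4: three ipsilateral classes plus contralateral). Correlation
distance is implemented as Euclidean clustering of row-standardized
profiles, making it invariant to per-pixel positive rescaling. The
pipeline enables a 3×3 median filter on each feature image before
clustering — the role spatial denoising plays in commercial MSI
segmentation — followed by a boundary-refinement pass: a pixel may switch
only to a label present in its 3×3 neighborhood, choosing the nearest
cluster centroid in *unsmoothed* feature space. The refinement exists
because median filtering alone erodes structures comparable in width to
the filter, which measurably truncated the 5-px penumbra annulus.

Region naming is automated (the original assignment was visual):
ipsilateral clusters are ranked by mean intensity in a marker window —
default the sodiated PC(32:0) window, maximal in the core — the top
cluster is the core, the 4-connected neighbor with the next-highest marker
the penumbra, the rest healthy. Manual ROIs from pixel lists or polygon
masks override this when provided. `equalize_rois` subsamples all ROIs to
the smallest size (seeded, without replacement), matching the equal-pixel
ROI protocol used for the fold-change statistics.

## Decomposition

pLSA factors the matrix as `n(d,w) ≈ TIC(d) · Σ_z P(z|d) P(w|z)` by plain
EM on the aspect model, treating normalized intensities as continuous
pseudo-counts (no rounding). Both M-step updates use responsibilities from
the same E-step, so the log-likelihood trace is non-decreasing — asserted
per iteration in the tests. Initialization is seeded-random; convergence
is a relative log-likelihood change below 1e-6 (default) or 500
iterations. Components whose mean pixel weight over off-tissue pixels
exceeds their mean weight over tissue are flagged as matrix components and
dropped from reports. Default component counts are 10 (positive mode) and
7 (negative mode), plain configuration; when the picked peak panel has
fewer columns than that, the pipeline clamps and logs it. Loading ranks
break ties by ascending m/z for determinism.

PCA is a centered (optionally column-standardized) SVD with the
largest-magnitude loading of each component forced positive. RGB overlays
of three score images (each min-max scaled over tissue pixels, with
optional sign flips for "negative" components) reproduce the SIMS-style
Na/K contrast rendering.

## Discriminant analysis

Pixel spectra are reduced by PCA to the fewest components reaching 80%
cumulative explained variance (read here as pre-reduction retained
variance — the standard pipeline for p ≫ n spectra; the alternative
reading, variance explained by DF1 itself, is not an input parameter of
any standard LDA and was rejected). Fisher directions are eigenvectors of
`Sw⁻¹ Sb` in the reduced space (generalized symmetric eigenproblem; a
1e-6 ridge is added on singularity, with a warning), giving at most
`classes − 1` functions. Classes follow the three-way scheme: healthy
(ipsi + contra merged), ischemic (core), borderzone (penumbra). DF1 sign
is fixed so the ischemic mean exceeds the healthy mean. Loadings are
back-projected to peak columns and unit-normalized ("scaled loadings").
Score histograms share Freedman–Diaconis bin edges computed on the pooled
DF1 scores; separability of two classes is the overlap coefficient
`Σ min(density_a, density_b) · bin_width` ∈ [0, 1].

## Quantification

Fold change is the ratio of ROI mean intensities on equal-sized ROIs, with
a 95% percentile-bootstrap CI over paired within-ROI pixel resamples
(default 10 000; the pipeline and validation runs use 2 000, which moves
percentile estimates by far less than the interval width). The CI method
is a choice — the source protocol states only "95% confidence
intervals" — and a replicate-level mode (`replicate_fold_change`, the
statistic being the ratio of averages of per-section ROI means across
n = 3 sections) is provided for the reading where intervals are taken over
animals rather than pixels. Quantiles are linear-interpolation (type 7)
throughout, including box-plot summaries (median, quartiles, 1.5 × IQR
whiskers, outlier lists). Ratio images divide two window columns
pixel-wise and mask denominators below 1e-6 × the matrix maximum rather
than producing infinities.

Two subtleties matter when validating fold changes against the phantom's
planted multipliers. First, TIC normalization changes region ratios
whenever a region's total signal genuinely differs (the core TIC is
elevated by LPC accumulation), so ground-truth recovery is checked on the
raw integrated matrix — the scale on which the multipliers are defined.
Second, the zero-clipped Gaussian noise floor contributes a small positive
baseline to every window (≈ σ/√2π per axis sample), which inflates weak
denominators; the generative model's implied measured fold is therefore
computed in closed form (`PhantomTruth.expected_measured_window_intensity`
sums E[max(K + G, 0)] over Poisson K and Gaussian G per sample) and used
as the coverage target. For the LPC(16:0)+Na core window this measured
fold is 8.88 versus the bare 10.0 product of multipliers; for the
strongly expressed PIP window the correction is negligible.

## Overlay

Histology co-registration replaces a manual overlay with a least-squares
similarity transform (closed form) fitted to ≥ 2 paired landmarks,
reporting the residual RMS. The ion image is warped bilinearly into the
histology frame; pixels below a threshold fraction of the warped maximum
are fully transparent and the rest blend as
`alpha · colormapped_ion + (1 − alpha) · histology`, linear in alpha per
pixel. Alignment claims are quantified as mask overlap — `|A∩B|/|A|` or
Jaccard — between the supra-threshold ion mask and an annotated border
mask.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic stage (generator, k-means restarts, pLSA init, ROI
  subsampling, bootstrap) is bit-reproducible given its seed.
* Ion masses use monoisotopic atomic masses to ≥ 6 decimals with the
  electron mass handled explicitly; `+H` and `−H` differ by exactly twice
  the proton mass by construction. Published one-decimal values that do
  not round to the monoisotopic computation (518.5, 885.6, 772.6, 496.4
  for LPC+Na, PI−H, PC(32:0)+K, LPC+H) are treated as nominal labels and
  never asserted; the bundled table keeps the computed values.
* Degenerate inputs fail loudly: empty pixel sets, constant marker
  windows, zero-TIC datasets, k exceeding the pixel count,
  self-intersecting polygons, and negative intensities all raise rather
  than propagate.
* Validation problem sizes: the default phantom (80 × 60 px, ~2 900
  tissue pixels, 14 positive- / 6 negative-mode peak windows) and 10
  seeds per stochastic claim; these sizes make the full suite a
  minutes-scale run while keeping ROI pixel counts (~300–1 500) in the
  range where the bootstrap and ARI statistics are stable.
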