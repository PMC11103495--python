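# Methods

This note documents the models, conventions and numerical choices behind
`tripodd`, and what the synthetic phantom does and does not emulate.

## The DTA model

Paired-agent imaging administers two spectrally distinct derivatives of a
drug: a *targeted* probe that binds the drug's target and an *untargeted*
probe that shares its nonspecific uptake but cannot bind. At a pixel, the
targeted channel reads specific binding plus nonspecific accumulation, the
untargeted channel nonspecific accumulation alone. The package computes
drug-target availability per pixel as

```
DTA = SF · (I_T / I_UnT) − 1,        SF = slope_UnT / slope_T
```

SF is the ratio of the two probes' titration trend-line slopes
(fluorescence per unit concentration), so `SF · I_T` and `I_UnT` are on a
common concentration-equivalent scale; subtracting 1 removes the shared
nonspecific component. Under the idealized uptake model
`I_T ∝ specific + nonspecific`, `I_UnT ∝ nonspecific`, DTA equals
specific/nonspecific — a binding-potential-style quantity proportional to
the density of *available* target sites, and proportional to `(1 − f)` when
a fraction `f` of sites is occupied by the unlabeled parent drug.

This algebraic placement of SF (on the ratio, with SF = slope_UnT/slope_T)
is the form in which the quoted slope-ratio definition of SF makes both
channels dimensionally commensurate. The mirrored convention
(`DTA = I_T/(SF·I_UnT) − 1` with the reciprocal SF) is available via
`compute_dta_map(..., sf_on_untargeted=True)` for compatibility with
scripts that define SF the other way around.

Numerical guards: DTA is undefined (invalid, NaN) wherever the untargeted
intensity is at or below a floor `floor_eps`, because autofluorescence-level
denominators make the ratio unstable. The floor defaults to the 95th
percentile of a vehicle/autofluorescence reference image when one is
supplied, else a small constant (1e-6 at the function level; the pipeline
default is 1e-3). Negative DTA values are retained, never clipped. Valid
pixels are a subset of the tissue mask, and every summary counts valid
pixels only.

## Calibration

Titration trend lines are ordinary least squares of mean image intensity on
concentration; the intercept is fitted, not forced through zero, and SF uses
slopes only (the slope ratio is the definition; intercepts absorb offsets
such as detector background). A non-positive slope in either fit raises a
calibration error. Exposure settings are assumed identical between titration
and tissue imaging for each channel, so exposure differences are absorbed
into the slopes and cancel in the DTA ratio — the same logic by which a
fixed SF works on real instruments.

## Tissue masking

The manual tissue outlining of the original workflow is replaced by Otsu
thresholding of a reference channel (typically the Cy2 tissue
autofluorescence), hole filling, and retention of the largest connected
component. Externally drawn masks can be imported and are passed through
unchanged with `provenance="imported"`.

## Registration

Rounds are aligned on DAPI, which is re-imaged every round. The default
motion model is translation-only: serial rounds of the same physical section
shift but rarely rotate. Displacements are estimated by phase
cross-correlation with correlation-peak upsampling (factor 20, i.e. a
0.05 px grid); alignment confidence is the normalized cross-correlation of
the aligned pair, and registrations scoring below 0.3 raise an error (pure
noise pairs score near 0, genuine tissue pairs above 0.9). An optional
small-angle rotation search (coarse-to-fine over ±5° by default) wraps the
translation estimate. Resampling is bilinear with zero fill; out-of-field
pixels are flagged in a validity mask.

`RigidTransform` maps coordinates as `x' = R(θ)x + t` (origin-anchored).
`register_rounds` reports the *displacement* of the moving round; the
pipeline applies the inverse to resample the round onto the reference frame.
DTA-to-marker alignment defaults to identity (the same section is imaged in
both acquisitions); `register_control_points` provides a least-squares rigid
fit (2D orthogonal Procrustes via SVD, reflections excluded) to
user-supplied point pairs when a manual correction is needed.

## Segmentation and feature extraction

Nuclei: Gaussian smoothing (σ = 1 px), Otsu threshold, hole filling,
distance-transform watershed seeded at distance peaks (minimum peak distance
5 px), removal of components under `min_area_px` (default 15 px²), and
contiguous relabeling. A blank image yields zero cells with a warning, not
an error.

Per-cell features: nuclear area and centroid from the label mask; marker
means over the nuclear mask dilated by `cell_expansion_px` (default 3 px)
for cytoplasmic capture, with contested pixels assigned to the nearest
nucleus boundary (`skimage.segmentation.expand_labels`); per-cell DTA is the
mean of *valid* DTA pixels in the expanded mask, with the valid-pixel
fraction recorded (NaN and fraction 0 when no valid pixel exists).
Coordinates are 0-based (row, col), pixel-centered. An alternative per-cell
DTA (ratio of per-cell mean intensities) was considered and rejected: the
per-pixel map is the primary artifact and treating it as one more channel
keeps cell DTA consistent with the map summaries.

## QC and normalization

Order of operations: exposure normalization → autofluorescence subtraction →
outlier filter → epithelial gate → control-anchored z-score.

- Exposure: every marker and autofluorescence mean is divided by its
  channel's exposure time (a.u./ms).
- Autofluorescence: each cell's same-wavelength AF mean is subtracted from
  each marker; negatives are retained.
- Outliers: cells strictly above the 95th quantile of Cy3 autofluorescence
  (tissue artifacts) and cells with nuclear size strictly below the 5th or
  above the 95th quantile (mis-segmentations) are removed. Thresholds are
  computed once on the input table using linear-interpolation quantiles (the
  numpy default); the filter is therefore idempotent at fixed thresholds.
  Strict-vs-inclusive comparison at the quantile is not specified by the
  protocol this reimplements; strict comparison is used and documented.
- Epithelial gate: a cell is retained iff strictly positive for both CK8 and
  E-Cadherin. The positivity threshold per marker defaults to Otsu on
  log1p-transformed values across the cohort (shifted so the minimum maps to
  0, since AF-corrected values can be negative); a fixed per-marker
  threshold is available. An empty gate is an error with the thresholds
  reported.
- Z-score: `z = (value − control_median) / control_SD` per biomarker column
  and for DTA, with the median and *sample* SD (ddof = 1) taken across all
  cells of the untreated control cohort. Population-vs-sample SD is not
  specified by the original protocol; sample SD is used and documented. A
  constant control column is an error.

## Statistics

- Relative values: per-tissue means divided by the maximum of the set.
- Pearson r with a two-sided p from the t distribution on n − 2 df, plus the
  least-squares trend line for scatter export.
- One-way ANOVA from the sums-of-squares decomposition, followed by Fisher's
  LSD: pairwise t statistics `(mean_i − mean_j) / sqrt(MSE(1/n_i + 1/n_j))`
  on the pooled residual df. LSD is *unprotected* by default (pairwise tests
  reported regardless of the omnibus F), with a `protected=True` switch; no
  additional multiple-testing correction is applied — that is the definition
  of LSD. Significance stars: * p<0.05, ** p<0.01, *** p<0.001,
  **** p<0.0001; α = 0.05 throughout. Degenerate inputs (all groups
  internally constant) report F = 0 when the means agree.
- The unit of analysis (cells vs tissues) is the caller's choice: the stats
  layer accepts any labeled value lists, and the CLI groups whichever table
  column is requested.

## The synthetic phantom

The phantom emulates a xenograft section imaged through the paired-agent +
cyCIF workflow, with full ground truth. Geometry: non-overlapping nuclear
disks (radius ~ N(6, 1) px truncated, placed by rejection sampling inside a
tissue disk of radius 0.46 × field) with a fixed 4 px cytoplasmic annulus —
xenografts are dominated by one cell type of similar size, so a simple
geometry suffices. Per cell: receptor density R ~ log-normal (median 50,
σ_log 0.4), nonspecific uptake N ~ log-normal (median 10, σ_log 0.3),
binding gain B = 1; probe channels are `slope_T(B(1−f)R + N)` and
`slope_UnT·N` over the whole cell region, with slopes 3 and 6 (true SF = 2).
True per-cell DTA is `B(1−f)R/N` (median ≈ 5 untreated). Marker channels
carry per-cell log-normal expression; CK8/E-Cadherin are high only in the
epithelial fraction (default 0.8), and CC3 is bimodal (15 % positive),
mimicking the binary viable-to-apoptotic switch. Autofluorescence is a
per-wavelength constant over the tissue disk (Cy2 2.0, Cy3 1.0, Cy5
0.5 a.u./ms); marker/AF channels are scaled by per-channel exposures, probe
channels use unit exposure (their slopes are per-unit-exposure gains, as the
titration is imaged under the same settings). Noise is additive Gaussian
truncated at zero (σ = 1 a.u. by default; Poisson available). Four rounds
(probes+Cy2-AF, two marker rounds, a residual-AF round), each the base scene
displaced by that round's rigid shift with fresh acquisition noise; DAPI is
present in every round. Everything is driven by one seed and is reproducible
bit for bit.

Where neither a protocol nor physics dictated a value (uptake distributions,
noise scale, AF levels, expression levels), the defaults were chosen once as
plausible for fluorescence microscopy of xenograft sections at moderate SNR
and are configurable.

What the phantom does **not** emulate: optics (PSF blur, illumination
shading, spectral bleed-through), tile stitching, nuclear texture and shape
irregularity, stromal/immune compartments, spatially structured
autofluorescence, probe pharmacokinetics over time, and inter-round signal
carryover. Consequently, passing phantom tests demonstrates the correctness
of the computational chain (calibration algebra, registration, label
bookkeeping, filter and z-score contracts, statistics) — not robustness to
real-tissue segmentation difficulty or optical artifacts.

## Problem sizes and determinism

The validation suite uses phantoms of 60–500 cells on 448²–1024² px fields
and 10,000 simulated null datasets for the ANOVA calibration — sizes at
which every contract the package makes is already sharply testable. All
randomness flows through `numpy.random.default_rng` seeds carried in
configs; the pipeline stamps a config hash, seed and the SF used into every
output, and two runs from the same config are byte-identical.

## Known limitations

- Translation-only registration by default; rotation is a search option, and
  deformable motion is out of scope.
- The epithelial gate assumes marker distributions are bimodal enough for
  Otsu; on a gate-unfriendly cohort, use fixed thresholds.
- DTA assumes the untargeted probe tracks the targeted probe's nonspecific
  uptake exactly; violations (e.g. dose-dependent saturation of nonspecific
  compartments) bias DTA and are not modeled.
- Whole-slide pyramidal formats and learned segmentation models are not
  supported.
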