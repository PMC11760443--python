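# Methods

`mritexture` implements gray-level co-occurrence (GLCM) texture analysis for
paired high-field/low-field T2-weighted MR slices: the question it addresses
is whether second-order texture statistics computed inside annotated regions
of interest can separate biopsy-proven cancerous prostate tissue from matched
non-suspicious tissue, and whether that separation survives the lower SNR of
low-field (< 0.1 T) imaging. Because clinical MR datasets of this kind are
private, the package ships a synthetic phantom generator that reproduces the
*statistical structure* of the study design; everything below is the
package's own account of what is computed and what the synthetic results do
and do not show.

## Analysis model

**Quantization.** Each slice is rescaled to N = 64 gray levels with the floor
rule `level = floor((v - lo)/(hi - lo) * N)` clipped to `[0, N-1]`. The
scaling range is per-slice. The pipeline default takes `lo, hi` at the 1st
and 99th intensity percentiles rather than the slice min/max: the min/max of
a Rician-noise image is an extreme-value statistic whose slice-to-slice
jitter propagates into every downstream feature and, because both ROIs of a
matched pair share the slice scaling, couples the two groups of the
comparison. Percentile scaling removes that instability; plain min/max and
explicit ranges remain available (`range_mode`). Both choices make the
features invariant to positive affine intensity changes.

**GLCM.** For an offset (Δr, Δc), every ordered pixel pair with both
endpoints inside the grid — and, for ROI analysis, both inside the ROI, so
background texture cannot bleed into lesion statistics — increments a
64×64 count matrix; counts are symmetrized by adding the transpose and
normalized to probabilities P. Four offsets are used by default: distance 1
at 0°, 45°, 90°, 135°.

**Features.** Energy `ΣP²`, Contrast `ΣP(i-j)²`, Homogeneity
`ΣP/(1+(i-j)²)`, Correlation `ΣP(i-μ)(j-μ)/σ²`, with μ, σ² the moments of
the symmetric P's marginal. Correlation of a zero-variance GLCM
(σ² < 1e-12) is undefined and reported as NaN, never 0.

**Direction combination.** Features are averaged across the four offsets
(`mean_features`, the common radiomics convention). Averaging the four
GLCMs first (`mean_glcm`) is implemented as an alternative; the two agree
exactly on isotropic inputs and differ slightly on anisotropic texture.

**Method 1 vs Method 2.** Method 1 computes the features once from the
masked within-ROI GLCMs. Method 2 computes per-pixel texture maps — for
each pixel, the features of the GLCM built over a window centered on it —
and averages the map over the ROI pixels. The default window is 9×9: small
enough to stay lesion-scale, large enough (≈ 130–160 co-occurrence pairs
per direction) that the windowed GLCM is not degenerate at 64 levels. The
window is clipped at image borders rather than padded (padding would invent
co-occurrences); windows are not re-quantized, so map values are comparable
across the image. Constant windows are invalid pixels of the Correlation
map and are excluded from ROI means. On stationary texture the two methods
converge as the window grows, which the test suite asserts as a monotone
trend over window sizes.

**Geometry.** ROIs are annotated in the high-field frame and carried to the
low-field frame through a user-supplied rigid transform `T(x) = Rx + t`
acting on physical (mm) coordinates; transforms compose in application
order. The package only applies transforms — estimating them is out of
scope (the registrations it consumes were produced manually). Circle radii
are preserved in millimetres and re-expressed in target pixels, so matched
pairs keep identical size after propagation. Resampling pulls target pixel
centers through `T⁻¹` (linear or nearest); out-of-bounds samples are
zero-filled and tracked in a validity mask that downstream GLCMs exclude.

**Statistics.** Per (feature, field, method) stratum, cancerous vs
non-suspicious values are compared with an unpaired two-sided Welch t-test —
the choice of the original study design, kept even though the ROIs are
matched; a paired test is available but not the default. (The unpaired test
is conservative in the presence of positive pair correlation.) Effect size
is Cohen's d with pooled SD. The required per-group sample size is the
smallest n for which the two-sided two-sample t-test at α = 0.05 reaches
power 0.80 under noncentrality `d·√(n/2)` (noncentral-t, not the normal
approximation); benchmarks n(d=0.5) = 64 and n(d=1.0) = 17 are asserted
against an independent solver. No multiple-testing correction is applied by
default (16 strata are reported against raw α = 0.05, mirroring the study
design); Bonferroni and Holm adjustments are available. Lesions are treated
as independent units; within-patient correlation of multiple lesions is not
modelled.

## Synthetic phantom

One "case" is a slice pair: an 80×80 high-field slice at 1 mm/px, and a
low-field slice rendered by resampling the same noiseless scene through a
known rigid offset (default 3° rotation plus ~2.5 mm translation) and then
adding acquisition noise in the low-field frame. A study is 28 cases, each
with one cancerous/non-suspicious ROI pair — the reporting shape of a
28-lesion cohort.

* **Texture.** Tissue texture is a stationary correlated Gaussian random
  field: white noise smoothed with an isotropic Gaussian kernel whose width
  is the correlation length, rescaled to a target mean/SD. Background:
  ℓ = 1.5 px, mean 100, SD 20. Lesions and background are different
  smoothings of the *same* white-noise substrate, so a lesion disc has no
  statistical seam at its boundary, and setting lesion parameters equal to
  background reproduces the background field bit-for-bit — the
  exchangeability that null (type-I-error) studies rely on.
* **Lesion texture.** ℓ = 2.0 px, SD 12, mean equal to background (intensity
  carries no signal by default; a mean-shift knob exists). A longer
  correlation length makes the quantized field more ordered — Energy and
  Homogeneity rise, Contrast falls. The lower texture SD is what drives GLCM
  Correlation *down*: acquisition noise is spatially white, so shrinking the
  correlated signal's share of the local variance lowers the neighbour
  correlation of the noisy field. Correlation length alone would push GLCM
  Correlation the wrong way (smoother fields have more correlated
  neighbours); the SD contrast is therefore part of the lesion model, not a
  tuning afterthought. These defaults put the weakest low-field channels
  (Method 1 Correlation, Method 2 Contrast) at Cohen's |d| ≈ 1.1–1.7 and the
  rest higher; the four features are mutually correlated, so they cannot all
  be placed at a single effect size.
* **Noise.** Rician by default (magnitude of complex Gaussian noise),
  Gaussian optional; σ = 2 on the high-field channel, σ = 6 on the low-field
  channel, reflecting hardware-dominated low-field noise. σ = 0 reproduces
  the noiseless image exactly. Noise is added after resampling, as it arises
  in the acquiring frame.
* **ROI placement.** The cancerous ROI coincides with the lesion disc
  (radius 8 px); the matched non-suspicious ROI has identical radius, lies
  inside the prostate disc and at least 2 px clear of every lesion, placed
  by rejection sampling from the case's own generator. All draws derive from
  a single integer seed; identical configs give bit-identical phantoms.

**What the phantom does not emulate:** MR physics (no relaxation, k-space,
bias fields or resolution difference between fields), anatomy (no prostate/
non-prostate intensity boundary, no zonal structure), lesion shape (discs
only), inter-patient variability, or reader variability in ROI placement.
Passing synthetic tests therefore shows that the *pipeline* recovers known
texture differences at realistic SNR and study size — not that real
low-field cohorts will show effects of this magnitude.

## Numerical and implementation notes

* Sliding-window maps use a vectorized interior path (windowed pair sums
  plus a sorted-run identity for Energy) and an explicit crop-based path at
  borders; both are checked against a per-pixel oracle to 1e-10.
* Simulation studies restrict map computation to ROI pixels
  (`map_roi_only`); file-based runs compute full maps for export.
* Degenerate cases: constant slices quantize to all-zero with a warning;
  ROIs too small for any co-occurrence pair are skipped with a warning
  (8 instead of 16 records for that case); zero-variance groups yield
  t = 0, p = 1 when means agree and a degenerate flag otherwise.
* Problem sizes in the test suite (28 pairs; 400 null and 50 alternative
  replicate studies; low-field channel for replicated simulations) were
  chosen to keep the Monte-Carlo standard error of rejection-rate estimates
  near 1 % while a full run of the suite stays at desk scale.

## Known limitations

* Only the four features above are implemented; the remaining Haralick
  statistics are out of scope.
* GLCMs are 2-D per slice; no volumetric (3-D offset) co-occurrence.
* The power analysis assumes the unpaired design; a paired power analysis
  is not provided.
* `as_inplane()` reduction of 3-D transforms requires slice-preserving
  rotations; oblique registrations are rejected rather than approximated.
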