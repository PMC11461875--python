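# Methods

## Pipeline model

Each analysed unit is one imaged field of a longitudinally sectioned,
immunofluorescently stained tendon: a red channel carrying one
extracellular-matrix stain (collagen 1, collagen 3, or elastin) and a blue
DAPI channel, both held as 8-bit arrays. All segmentation rules are
fraction-of-range intensity thresholds: a fraction t maps to the smallest
integer cutoff v ≥ t·255, and a pixel counts as "above threshold" when its
value is ≥ v. This makes the published fractional thresholds (0.9, 0.12,
0.7, 0.2) exact integer cutoffs (230, 31, 179, 51); a 10⁻⁹ rounding guard
absorbs binary-float artifacts. Inputs of higher bit depth are linearly
rescaled from their nominal dynamic range with round-half-up.

Coordinates are row-major with the origin top-left; angles are measured
counter-clockwise from the horizontal (+x) with y up, wrapped to [−90°,
90°), since nucleus orientation is axial (180°-periodic).

### Segmentation

* **Vessels** (collagen sections only — vessels are not visible under the
  elastin stain): red ≥ 230, dilated by a Euclidean disk of radius 8 px.
  The disk is chosen as the isotropic structuring element matching rounded
  vessel rims. No size or shape filtering is applied before dilation.
* **Dye-dot artifacts** (elastin sections): connected components of red ≥
  179, classified by the minor/major axis ratio of their moment-equivalent
  ellipse. Components with ratio ≥ 0.5 (round) are treated as unwashed-dye
  dots, dilated by a radius-5 disk, and excluded; elongated bright fibers
  are retained as genuine stain. Degenerate single-pixel components count
  as round.
* **Stain**: red ≥ 31 (collagens) or ≥ 51 (elastin) minus the relevant
  exclusion mask. Stain and exclusion masks are disjoint by construction.
* **Nuclei**: the blue channel outside the vessel mask is binarized and
  labelled with 8-connectivity (diagonal boundaries stay connected).
  The default cutoff is Otsu's method on the non-vessel pixels, floored at
  15 % of range so a nucleus-free field of dim background noise is not
  split into spurious foreground — DAPI-positive nuclei are bright, and
  without the floor Otsu always bisects whatever distribution it is given.
  A fixed fractional cutoff can be configured instead. Components below
  5 px are discarded as speckle. Vessel masking happens before labelling,
  so no labelled pixel lies inside a vessel.

### Per-section metrics

Mean stain intensity is the average red value over the stain mask on the
0–255 scale (the scale is internally consistent; only contrasts between
groups matter). An empty stain mask yields NaN with a warning — "no
stained area detected" is deliberately distinct from zero intensity.
Area fractions are true-pixel counts over total pixels. Vessel exclusion
uses the full dilated mask, so the rim contributed by dilation is excluded
from intensity averaging along with the vessel body.

Nucleus shape comes from second-order central image moments with a 1/12
px² pixel-area term (the moment-equivalent ellipse; axis length =
4√eigenvalue). The minor axis is floored at 1 px so collinear components
remain well defined. Aspect ratio is minor/major ∈ (0, 1]. Nucleus metrics
are computed on collagen-1 sections, whose vessel mask is the one used for
DAPI masking.

Orientation spread: angles are recentred by their circular mean on the
180° circle (computed by angle doubling), histogrammed over [−90°, 90°)
with 10° bins (configurable; the width must divide 180°), and the FWHM is
the distance between the outermost linear interpolations of the
half-maximum crossings around the modal bin. A side that never falls below
half maximum extends to the histogram edge; a flat histogram returns
180°. Recentring keeps alignments near ±90° from being split across the
seam, and makes the FWHM invariant to global rotation up to binning.

Diameter normalization divides mean intensity, nuclei area fraction and
vessel area fraction by the callus diameter in mm. The unit choice
rescales all groups equally and cancels in group contrasts.

### Statistics

Early healing (weeks 1–3; minimal/reduced/full loading) is analysed per
metric with a fixed-effects two-way ANOVA, interaction included, using
Type II sums of squares because the minimal-loading cells are larger
(n = 5) than the others (n = 4). Post hoc load comparisons use Tukey HSD
within each week, on that stratum's data only. Late healing (full loading;
weeks 3/12/20) uses a one-way ANOVA over time with Tukey HSD across weeks.
α = 0.05 throughout. ANOVA and Tukey are delegated to statsmodels
(OLS + `anova_lm`, `pairwise_tukeyhsd`); the all-observations-equal
degenerate case is reported as F = 0, p = 1 by contract. Batch analysis
skips (with a recorded warning) any metric or stratum lacking the
required factor levels rather than aborting.

## Synthetic data: what it emulates and what it does not

The generator renders the image classes the pipeline quantifies: a smooth
random stain region covering a requested area fraction (threshold of a
Gaussian-filtered noise field at the matching quantile), painted either
piecewise-constant ("flat", which makes intensity recovery exact) or with
anisotropic smoothed noise around the target mean ("fibrous"); saturated
vessel disks (collagen mode) or round saturated dye dots (elastin mode)
placed without overlap by bounded rejection sampling; and elliptical
nuclei with controllable count or area fraction, axis ratio, and
orientations drawn from a wrapped normal (mean, σ) on the 180° circle,
for which the closed-form FWHM 2√(2 ln 2)·σ anchors recovery tests.
Requested nuclear area fractions are met by placing nuclei until the drawn
area is within half a nucleus of the target. Generation is byte-exact
under a fixed seed.

The default cohort mirrors the study design: full loading at weeks
1/2/3/12/20 (n = 4/week), reduced loading at weeks 1–3 (n = 4), minimal
loading at weeks 1–3 (n = 5) and 4 intact references — 47 healing tendons
plus 4 intact, three stains each. The effect preset reproduces the
reported contrast structure: minimal loading ≈ 1.8× the full-loading
stain intensity (reduced ≈ 1.3×), healing nuclear area fractions 5–10 %
against ≈ 1 % intact, early vessel area ≈ 10 % under unloading against
3–4 % under full loading, and smaller callus diameters under unloading.
The design's vessel fractions target the *detected* (post-dilation)
vessel area, since that is what vessel density means downstream; the
drawn disk count is derived from the mean dilated-disk footprint.
Relative per-section noise is lognormal with CV 0.12 (CV 0.08 for
diameters). Cohort images default to 192×192 px (256×256 via the CLI
configuration), sizes at which all mask-level metrics are
well-conditioned. A metric-level sampler (`simulate_metric_table`) draws
per-cell values from the same multiplicative model without rendering
images; with all multipliers at 1 it is the null design used to calibrate
the ANOVA type-I error.

What the generator does **not** emulate: optics (point-spread function,
vignetting, exposure variation), real staining chemistry, touching or
overlapping nuclei, vessel lumina and irregular vessel shapes, and
spatial correlation between the two channels. Passing recovery tests
therefore demonstrates the correctness and calibration of the
measurement chain, not the biological accuracy of any particular
threshold on real micrographs.

## Numerical choices and known limitations

* Threshold comparisons are ≥; dilation uses scikit-image's Euclidean
  disk, verified pixel-for-pixel against a brute-force distance check.
* Otsu binarization runs on non-vessel pixels only, so zeroed vessel
  regions cannot bias the split.
* Orientation of near-round nuclei is intrinsically ill-conditioned:
  rasterization noise in the second moments grows as the axis ratio
  approaches 1 and the size shrinks. Per-nucleus orientation is accurate
  to ≲ 3° for well-resolved nuclei (major axis ≳ 30 px at ratio 0.9;
  much smaller suffices for elongated nuclei). Shape-recovery checks use
  such sizes; sub-resolution nuclei will show larger angular scatter.
* FWHM is quantized by the 10° bins; single-cluster distributions return
  at most one bin width, and sampling noise at n ≈ 500 keeps recovered
  FWHM within ±20 % of the wrapped-normal prediction.
* Tendon diameter is consumed as metadata; the package does not measure
  it from images.
* Problem sizes in the test and acceptance runs (256–512 px fields,
  1000-replicate calibration) were chosen as the smallest at which the
  checked properties are stable; they are the package's own defaults,
  not estimates for any particular microscope format.
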