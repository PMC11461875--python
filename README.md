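# tendonquant

Quantitative histology of healing tendon from two-channel immunofluorescence
micrographs. The package is aimed at tissue-biology groups who image stained
sections (red = an extracellular-matrix stain such as collagen 1, collagen 3
or elastin; blue = DAPI nuclear counterstain) and want reproducible,
investigator-independent numbers per section: how much matrix protein is
present, how much of the field is blood vessel, how dense the cells are, and
how elongated and aligned their nuclei are — followed by the cohort-level
statistics used to compare mechanical-loading groups over healing time.

## What it computes

For each section the pipeline applies fraction-of-range thresholds to the
8-bit channels:

* **Vessel mask** (collagen stains): red ≥ 0.9 of range, dilated by a
  Euclidean disk of radius 8 px so each vessel's bright rim is included.
  Vessel density = masked area / image area.
* **Stain mask**: red ≥ 0.12 (collagens) or ≥ 0.2 (elastin), minus the
  exclusion mask (vessels, or round saturated dye dots for elastin: bright
  components with minor/major axis ratio ≥ 0.5 at threshold 0.7, dilated by
  5 px). Mean intensity *MI* is the average red value over the stain mask.
* **Nuclei** (DAPI): binarized outside the vessel mask (Otsu by default),
  labelled; cell density = nuclear area fraction. Each nucleus gets an
  equivalent ellipse from second-order image moments: aspect ratio
  *AR = b/a* (1 = round, < 1 = spindle-shaped) and orientation θ ∈ [−90°,
  90°) to the horizontal. Alignment is the full width at half maximum
  (FWHM) of the orientation histogram (10° bins after circular recentring);
  FWHM = 180° means no preferred direction.
* **Diameter normalization**: metrics divided by the measured callus
  diameter (mm) to correct for load-dependent callus size.

Cohort tables are analysed the way loading studies are: a two-way
fixed-effects ANOVA (load × time, Type II sums of squares) over early
healing with Tukey HSD across load groups within each week, and a one-way
ANOVA over time in the fully loaded group for late healing, with Tukey HSD
across weeks (α = 0.05).

A synthetic-image generator renders sections with known ground truth
(stain intensity, vessel/dot/nucleus geometry, wrapped-normal orientation
spread σ, for which FWHM = 2√(2 ln 2)·σ), so every stage is testable by
parameter recovery without any raw data.

## Worked example

```python
from tendonquant import generate_section, quantify_section

section, truth = generate_section(
    "collagen1", size=(256, 256), seed=1,
    stain_mean_intensity=150, vessel_count=8,
    nuclei_area_fraction=0.05, orientation_sigma_deg=15,
)
m = quantify_section(section)
print(f"MI={m.mean_intensity:.1f}  vessels={m.vessel_area_fraction:.3f}  "
      f"cells={m.nuclei_area_fraction:.3f}  AR={m.mean_aspect_ratio:.2f}  "
      f"FWHM={m.orientation_fwhm_deg:.1f}")
```

prints

```
MI=150.0  vessels=0.090  cells=0.047  AR=0.61  FWHM=30.2
```

— the piecewise-constant stain intensity is recovered exactly after vessel
exclusion (150.0); the detected vessel fraction (9.0 %) exceeds the drawn
1.7 % because the radius-8 rim dilation is part of the vessel definition;
the cell density (4.7 %) matches the requested 5 % minus nuclei lost under
the vessel mask; and the FWHM of 30.2° sits near the 35.3° expected for a
15° wrapped-normal spread at this sample size.

The same flow runs at cohort scale from a shell:

```bash
tendonquant all --seed 11 --out run       # generate -> quantify -> analyze
tendonquant all --seed 11 --null --out n  # same, with no group effects
```

which writes `manifest.csv`, per-section images, `cohort_metrics.csv`,
`results.csv` and a plain-text `report.txt` with the resolved configuration
and annotated Tukey contrasts.

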