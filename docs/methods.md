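# Methods

This note documents the models, algorithms and numerical choices behind
`rgcmosaic`, and what the synthetic-data validation does and does not show
about real images.

## Coordinate conventions

Pixel coordinates follow image convention: origin top-left, x right,
y down, 0-based. Millimetre coordinates are centred on the optic nerve
head (ONH) with the image y-axis flipped, so a whole-mount oriented
"superior at the top" has superior = +y in mm. `SectorGrid.superior_angle_deg`
(default 90°) rotates the anatomical frame for differently oriented
images. Nasal/temporal laterality is set by an `eye` flag (left eye:
nasal on the +x side of the superior axis); it mirrors the two lateral
quadrant labels and nothing else.

## Cell detection

The chain reproduces the fixed-parameter ImageJ recipe used for
Brn3a-counting, in this order:

1. **Band-pass.** A light Gaussian low-pass (σ = 1 µm) suppresses pixel
   noise, then a background estimated by greyscale morphological opening
   at 63 µm scale (≈3× the largest accepted soma) is subtracted and the
   result clipped at zero. The opening is the same estimator as a
   rolling-ball background: because it ignores sparse bright blobs it is
   not biased upward where somata crowd together, which a local-mean
   background is — that bias systematically shrinks thresholded particles
   in dense regions.
2. **Threshold** at a fixed 8-bit level (default 130).
3. **Watershed** on the Euclidean distance transform of the binary image,
   with markers from h-maxima (suppression depth 1 px, configurable) so
   shallow twin peaks do not split single somata.
4. **Gates.** Equivalent-circle diameter within 7–21 µm (the size window
   is read as a diameter; soma areas of 7–21 µm² would be implausible),
   circularity 4π·area/perimeter² ≥ 0.7 (perimeter by the Freeman
   chain-code estimator of `skimage.measure.regionprops`, ratio clamped
   to ≤1, which a pixelated small disc can exceed), and centroid inside
   the retina mask. Cells are returned in raster-scan order.

The retina area mask comes from the low-intensity band [0, 5] (tissue
photographs near-black on a brighter surround), followed by a 12 µm
morphological closing (bright somata on the retina rim otherwise breach
the outline), largest-connected-component selection and hole filling.
Area is the mask pixel count times the pixel area.

## Mosaic statistics

NNDs are Euclidean distances to the nearest other cell, computed with a
k-d tree; an O(n²) all-pairs oracle in the test suite checks exact
agreement. The regularity index is RI = mean/SD of the NNDs with the
sample (n−1) SD — the choice of denominator is immaterial at the n used
here. RI is reported as NaN (with a warning) when the SD is zero. No edge
correction is applied: cells near the retina border find neighbours on the
inside only, matching standard practice for this statistic.

Per-sector NND statistics average the *globally* computed NNDs over the
cells gated into the sector; distances are never recomputed within a
sector, so a cell's neighbour may legitimately lie across a sector
boundary. NND histograms are normalised to unit area with a 1 µm default
bin; skewness is the third standardised moment; tail fractions are the
proportions of NNDs above 20 and 40 µm.

For a homogeneous 2-D Poisson process the NND is Rayleigh-distributed,
giving the closed forms mean NND = 0.5/√λ and
RI = 0.5·√(4π/(4−π)) ≈ 1.913 used as oracles for the generator and the
statistics.

## Sector grid

Rings are half-open annuli [(k−1)·w, k·w) about the ONH, k = 1…15,
default width w = 0.3 mm (a 4.5 mm outer radius, matching a ~52 mm²
rat retina; the width is configurable). Quadrants are the four 90° wedges
bounded by the two diagonals through the ONH at ±45° to the superior
axis; each boundary ray belongs to the counter-clockwise-following wedge,
and a cell exactly at the ONH joins the wedge containing angle 0. Two
independent implementations — Cartesian sign/slope tests against the
diagonals, and polar-angle binning — give identical assignments and
cross-check each other in the tests.

Sector areas are measured by classifying every mask pixel centre with the
same gating code, so sector areas plus out-of-grid area equal the mask
area exactly, and sector counts plus out-of-grid count equal the total
cell count exactly. Out-of-grid cells and area are reported in the table
attributes and CSV header, never dropped. Sectors with fewer than 3 cells
report an undefined (NaN) RI; a sector with cells but zero mask area
raises, since it indicates inconsistent geometry.

## Degeneration kinetics

One-phase model: `y = (Y0 − Plateau)·exp(−K·X) + Plateau`, reported with
half-life ln2/K and percentage loss 100·(Y0 − Plateau)/Y0. Two-phase
model with plateau:

```
SF = (Y0 − Plateau)·PF·0.01
SS = (Y0 − Plateau)·(100 − PF)·0.01
y  = Plateau + SF·exp(−KF·X) + SS·exp(−KS·X)
```

with KF, KS fixed from the literature half-lives of primary (1.7 d) and
secondary (16.3 d) RGC degeneration, so the only shape parameter is PF,
the percentage of the span lost through the fast component. The spans
satisfy SF + SS = Y0 − Plateau by construction.

Fitting uses trust-region bounded least squares (`scipy.optimize.
least_squares`), parameterised as (span, plateau, rate/PF) with
span, plateau ≥ 0 and PF ∈ [0, 100], so Y0 ≥ Plateau ≥ 0 holds by
construction. Initialisation: span from the first minus last observation,
plateau from the last observation, K = ln2/median positive time.
Replicate observations at a time point enter as individual unweighted
residuals. A constant series is returned flagged `rate-unidentifiable`
(K = NaN) rather than raising; non-convergence and PF pinned at a bound
are likewise flags on the returned fit. Baseline handling: the naïve
control density is treated as the t = 0 observation of every series.

Percentage loss against baseline is 100·(1 − y/y₀), with
round-half-away-from-zero when an integer percentage is reported, the
convention that reproduces printed summary tables.

Cumulative IOP exposure treats the pressure record as piecewise linear,
inserts the exact zero crossings of (IOP − baseline), and integrates the
positive part with the trapezoid rule — exact for piecewise-linear input.

## Synthetic retinas

The generator provides ground truth for every downstream stage, emulating
the study conditions: a disc retina of radius 4.1 mm, target density
1695 cells/mm² (the healthy whole-retina mean), and a hard-core exclusion
radius whose default of 7.2 µm was calibrated once so the generated
control mosaic reproduces the healthy-retina RI (~2.86) and mean NND
(~14.4 µm); it was not adjusted afterwards.

* **Point process.** Homogeneous Poisson for exclusion 0; otherwise
  Matérn type II: proposals at intensity λ_p with uniform marks, a point
  retained iff no proposal within r has a smaller mark. Since the retained
  intensity is (1 − exp(−λ_p·πr²))/(πr²), λ_p is solved from the target
  so the achieved density equals the target in expectation; targets above
  the ceiling 1/(πr²) raise an error naming the bound.
* **Density gradient.** Optional linear thinning with distance from the
  centre (retention 1 − g·d/R), with the base intensity rescaled by
  1/(1 − 2g/3) so the disc-average density is preserved. Chosen as the
  simplest monotone form for the well-known central-to-peripheral density
  decline, whose functional form is not established.
* **Loss patterns.** Diffuse: independent Bernoulli removal at the given
  fraction within the region. Clustered: discs of the given radius seeded
  at uniformly chosen *surviving* in-region cells (guaranteeing progress)
  until the removed in-region fraction first reaches the target; it may
  overshoot by part of one cluster. Out-of-region cells are never touched.
  Regions are ring-range × quadrant-set predicates on the sector grid.
* **Rendering.** Each cell is a radially symmetric Gaussian truncated at
  the soma radius, so its FWHM equals the nominal soma diameter (default
  12 µm) and, like a real stained nucleus, it has a sharp edge — an
  untruncated Gaussian's dim skirt would brighten the tissue between
  cells and destroy the low-intensity mask at realistic densities.
  Tissue is 0, the off-retina surround 20 (above the mask band), optional
  clipped Gaussian noise covers the frame, and the default calibration is
  1 µm/pixel (synthetic images define their own scale; calibration is a
  required input for real images).
* **Determinism.** One integer seed per stochastic operation
  (`numpy.random.default_rng`); identical spec + seed gives bit-identical
  points and rasters.

### What the synthetic validation does not show

The generator omits staining variability, vignetting and tiling seams,
z-projection blur, non-circular and size-varying somata, displaced
amacrine cells and other non-RGC Brn3a-negative structures, and tissue
tears from dissection. Passing the synthetic benchmarks therefore
demonstrates the correctness of the measurement chain (segmentation,
geometry, statistics, fitting), not the biological detection accuracy on
real stained tissue, which must be validated against manual counts.
A physical limitation the synthetic data *does* reproduce: at healthy
densities with soma-scale spacing, some somata genuinely coincide in a
maximum projection, so detected density sits a few percent below ground
truth (≈1% at a 13 µm exclusion, more as spacing tightens below the soma
diameter).

## Problem sizes

Validation runs use retinas of 0.4–2 mm radius (10³–10⁴ cells) rendered
at 1–4 µm/pixel, 20-image batches for detection fidelity, 100-seed
repeats for parameter recovery, and single ~90,000-point mosaics for the
Poisson-RI checks — sizes chosen so the full suite exercises every claim
at comfortable statistical power on a single CPU. A full-scale 4.1 mm
retina at 1 µm/pixel (~67 Mpixel) runs through the same code path
unchanged.
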