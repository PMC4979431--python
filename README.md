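# rgcmosaic

Quantitative spatial and temporal analysis of retinal ganglion cell (RGC)
loss in whole-mount retina images.

In rodent models of glaucoma and other optic neuropathies — partial optic
nerve transection (pONT) and ocular hypertension (OHT) — the standard end
point is the survival of RGCs, visualised by nuclear markers such as Brn3a
in flattened whole-mount retinas. `rgcmosaic` implements an automated
pipeline for these images, for researchers who need whole-retina numbers
rather than sampled fields:

1. **Detection** — ImageJ-style chain on the 8-bit maximum projection:
   rolling-ball background subtraction, fixed 130 intensity threshold,
   distance-transform watershed to split touching somata, gates on
   equivalent-circle diameter (7–21 µm) and circularity (4πA/P² ≥ 0.7),
   plus low-threshold extraction of the retina area mask.
2. **Mosaic statistics** — per-cell nearest-neighbour distances (NND) and
   the regularity index RI = x̄_NND/σ_NND (≈1.91 for a spatially random
   arrangement, ~2.9 for a healthy rat RGC mosaic), with normalised NND
   histograms, skewness and >20 µm / >40 µm tail fractions that separate
   diffuse from clustered loss.
3. **Spatial segmentation** — every cell gated by its Euclidean distance
   d = √((x−a)² + (y−b)²) from the optic nerve head (a, b) into 15
   concentric rings (0.3 mm) × 4 anatomical quadrants = 60 non-overlapping
   sectors, each with count, area, density, mean NND and RI.
4. **Degeneration kinetics** — per-sector density time courses fit to a
   one-phase decay `y = (Y0−Plateau)·exp(−K·X) + Plateau` (half-life,
   % loss) and to a two-phase decay with rates fixed at the primary
   (t½ = 1.7 d) and secondary (t½ = 16.3 d) degeneration half-lives,
   whose free parameter PF estimates the percentage of primary
   degeneration in each sector. Cumulative IOP exposure (mmHg·day) is
   computed as the area under the above-baseline pressure curve.
5. **Synthetic retinas** — a Matérn-II hard-core / Poisson mosaic
   generator with programmable diffuse or clustered regional loss and an
   8-bit renderer, providing exact ground truth for every stage.

## Worked example

`examples/` contains one short script per capability. For instance,
simulating a 1 mm retina at near-physiological density and counting its
cells (`examples/01_simulate_and_count.py`):

```
ground-truth cells : 5401
detected cells     : 5377
retina area        : 3.141 mm²
detected density   : 1712.0 cells/mm² (target 1700)
```

The detector recovers 99.6% of the generated somata; the detected density
sits within 1% of the generator target. Mosaic regularity
(`examples/02_mosaic_regularity.py`):

```
random (Poisson)   exclusion  0.0 µm -> mean NND 12.19 µm, RI 1.91
healthy mosaic     exclusion  7.2 µm -> mean NND 14.02 µm, RI 2.83
strongly regular   exclusion 12.0 µm -> mean NND 16.59 µm, RI 4.68
```

A random arrangement reproduces the closed-form Poisson RI of 1.913; a
7.2 µm exclusion radius reproduces the regularity (RI ≈ 2.9) and spacing
(mean NND ≈ 14 µm) reported for healthy rat retina. Decay kinetics on the
bundled reference density tables (`examples/04_decay_kinetics.py`) fit the
pONT whole-retina course with a ~4.5-day half-life and 74% total loss, and
the OHT course with ~24% loss.

The same functionality is exposed as a thin CLI:

```bash
rgcmosaic simulate --out-dir sim --field-radius-mm 1 --density 700 --exclusion-radius-um 20
rgcmosaic detect --image sim/image.tif --pixel-size-um 1 --onh-x 515 --onh-y 515 --out cells.csv
rgcmosaic segment --cells cells.csv --image sim/image.tif --pixel-size-um 1 \
    --onh-x 515 --onh-y 515 --ring-width-mm 0.067 --out sectors.csv
rgcmosaic fit --series series.csv --mode two --out fits.csv
rgcmosaic run --config run.yaml   # config-driven end-to-end pipeline
```

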