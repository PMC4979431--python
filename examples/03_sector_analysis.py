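"""Ring/quadrant segmentation of a retina with superior-quadrant loss.

Simulates clustered cell loss restricted to the superior quadrant (the
spatial signature of dorsal optic-nerve injury), gates every surviving
cell into 15 concentric rings x 4 quadrants about the optic nerve head,
and prints per-quadrant densities. The superior quadrant should sit well
below the others; the NND-distribution skewness separates clustered from
diffuse loss at the same overall fraction.
"""

import numpy as np

from rgcmosaic import (
    LossPattern,
    MosaicSpec,
    SectorGrid,
    SectorRegion,
    apply_loss,
    generate_mosaic,
    mosaic_summary,
    nearest_neighbour_distances,
    render_image,
    sector_table,
)

spec = MosaicSpec(field_radius_mm=1.0, target_density_per_mm2=1695.0, seed=17)
base = generate_mosaic(spec)

grid = SectorGrid(ring_width_mm=1.0 / 15, n_rings=15)
superior = SectorRegion(grid=grid, quadrants=frozenset({"Superior"}))
depleted = apply_loss(
    base,
    LossPattern(mode="clustered", fraction_removed=0.5, region=superior,
                cluster_radius_um=80.0, seed=3),
)

_, geometry = render_image(depleted, pixel_size_um=4.0, field_radius_mm=1.0)
nnd_um = nearest_neighbour_distances(depleted) * 1000.0
table = sector_table(depleted, geometry, grid, nnd_um)

print(f"cells before loss: {len(base)}, after superior clustered loss: {len(depleted)}")
print("\nper-quadrant totals (summed over rings):")
for quad, group in table.groupby("quadrant"):
    density = group["cell_count"].sum() / group["area_mm2"].sum()
    print(f"  {quad:9s} {group['cell_count'].sum():5d} cells, {density:7.1f} cells/mm²")

diffuse = apply_loss(base, LossPattern(mode="diffuse", fraction_removed=0.5, seed=3))
print("\nNND-distribution skewness at matched 50% whole-retina loss:")
print(f"  diffuse loss   : {mosaic_summary(diffuse).skewness:.3f}")
clustered = apply_loss(
    base, LossPattern(mode="clustered", fraction_removed=0.5,
                      cluster_radius_um=80.0, seed=3),
)
print(f"  clustered loss : {mosaic_summary(clustered).skewness:.3f} "
      "(higher skew = patchy loss, the secondary-degeneration signature)")
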