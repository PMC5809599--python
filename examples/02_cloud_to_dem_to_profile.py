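"""From a raw text point cloud to a DEM to a sagittal elevation profile.

This is the data path for a real scan: the instrument's relative-coordinate
point cloud is shifted to absolute coordinates, gridded onto a regular raster
(linear TIN interpolation; cells outside the scanned area stay nodata), and a
transect along the axial midline yields the elevation profile used for
landmarking.
"""

import io

import numpy as np

from trilomorph import (extract_profile, grid_point_cloud, midline,
                        parse_point_cloud, to_absolute_coordinates)

# a tiny synthetic "scan" in the .MAP-style relative dialect: x y z per line
rng = np.random.default_rng(0)
xy = rng.uniform(0.0, 2.0, size=(4000, 2))
z = 0.1 * np.sin(3 * xy[:, 0]) + 0.05 * xy[:, 1]
text = "\n".join(f"{x} {y} {h}" for (x, y), h in zip(xy, z))

cloud = parse_point_cloud(io.StringIO(text), dialect="map_relative",
                          specimen_id="demo")
cloud = to_absolute_coordinates(cloud, origin=(10.0, 5.0, 0.0))
print(f"parsed {len(cloud)} points; x range {cloud.x.min():.2f}..{cloud.x.max():.2f} mm")

dem = grid_point_cloud(cloud, cell_size=0.02, method="linear_tin")
print(f"gridded to {dem.n_rows} x {dem.n_cols} cells "
      f"({dem.valid_mask.mean():.0%} inside the scanned hull)")

prof = extract_profile(dem, midline(dem), n_samples=500)
print(f"sagittal profile: {len(prof)} samples over {prof.length:.2f} mm, "
      f"relief {prof.relief:.4f} mm")
print("\nThe profile's relief combines the sine ridges (amplitude 0.1 mm)")
print("with the 0.05 mm/mm cross-slope sampled along the midline.")
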