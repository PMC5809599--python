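"""Grid a surface point cloud into a DEM and summarise its relief.

The optical scanner samples a 5 x 5 mm window at 1500 lines per axis, so the
default cell size is 5/1500 mm (~3.33 um). Gridding interpolates scattered
(x, y, z) samples onto regular cell centers; cells outside the convex hull of
the cloud stay nodata — no relief is invented beyond the measured area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import DegenerateGeometryError, EmptyRasterError
from .surface_io import DEM, PointCloud, require_noncollinear

#: scan window width / lines per axis, in mm
DEFAULT_CELL_SIZE = 5.0 / 1500.0
GRID_METHODS = ("nearest", "linear_tin", "idw")


@dataclass
class DemSummary:
    """Elevation statistics over the valid cells of one DEM."""

    z_min: float
    z_max: float
    relief: float  # z_max - z_min, mm
    n_valid_cells: int
    coverage_fraction: float


def grid_point_cloud(cloud: PointCloud, cell_size: float = DEFAULT_CELL_SIZE,
                     method: str = "linear_tin") -> DEM:
    """Interpolate a point cloud onto a regular grid.

    Methods: ``linear_tin`` (Delaunay / TIN linear facets, the default),
    ``nearest`` (nearest sample), ``idw`` (inverse-distance-squared over the 8
    nearest samples). Grid extent is the cloud's bounding box; cells outside
    the convex hull are nodata.
    """
    if method not in GRID_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {GRID_METHODS}")
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    pts = cloud.points
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points to grid")
    if method == "linear_tin":
        require_noncollinear(pts)
    xy, z = pts[:, :2], pts[:, 2]
    x_min, y_min = xy.min(axis=0)
    x_max, y_max = xy.max(axis=0)
    n_cols = max(1, int(np.ceil((x_max - x_min) / cell_size - 1e-9)))
    n_rows = max(1, int(np.ceil((y_max - y_min) / cell_size - 1e-9)))
    if n_cols == 1 and n_rows == 1:
        warnings.warn("cell_size exceeds the cloud extent; producing a single-cell DEM")
    xc = x_min + (np.arange(n_cols) + 0.5) * cell_size
    yc = y_min + (np.arange(n_rows) + 0.5) * cell_size
    gx, gy = np.meshgrid(xc, yc)
    targets = np.column_stack([gx.ravel(), gy.ravel()])

    hull_mask = None
    try:
        tri = Delaunay(xy)
        hull_mask = tri.find_simplex(targets) >= 0
    except QhullError:
        if method == "linear_tin":
            raise DegenerateGeometryError(
                "cannot triangulate a collinear cloud with method='linear_tin'") from None

    if method == "linear_tin":
        vals = LinearNDInterpolator(tri, z)(targets)
    elif method == "nearest":
        vals = NearestNDInterpolator(xy, z)(targets)
    else:  # idw, power 2, 8 nearest neighbours
        k = min(8, len(pts))
        dist, idx = cKDTree(xy).query(targets, k=k)
        dist = np.atleast_2d(dist.reshape(len(targets), k))
        idx = np.atleast_2d(idx.reshape(len(targets), k))
        exact = dist[:, 0] < 1e-12
        with np.errstate(divide="ignore"):
            w = 1.0 / dist ** 2
        w[exact] = 0.0
        w[exact, 0] = 1.0
        vals = (w * z[idx]).sum(axis=1) / w.sum(axis=1)
    if hull_mask is not None:
        vals = np.where(hull_mask, vals, np.nan)
    return DEM(vals.reshape(n_rows, n_cols), origin_x=x_min, origin_y=y_min,
               cell_size=cell_size)


def dem_summary(dem: DEM) -> DemSummary:
    """Min/max/relief and coverage over the non-nodata cells."""
    mask = dem.valid_mask
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise EmptyRasterError("DEM has no valid cells")
    v = dem.values[mask]
    z_min, z_max = float(v.min()), float(v.max())
    return DemSummary(z_min=z_min, z_max=z_max, relief=z_max - z_min,
                      n_valid_cells=n_valid,
                      coverage_fraction=n_valid / dem.values.size)
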