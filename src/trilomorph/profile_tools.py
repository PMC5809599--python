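"""Elevation profiles: extraction from DEMs, resampling, relief tables.

A sagittal profile runs along the axial midline of the glabella; an exsagittal
profile is a parallel transect offset to one side. Both are ordered
(distance-along-line, elevation) series, mm on both axes. Per-specimen relief
(max - min elevation of the profile) summarised per population is the boxplot
statistic used to compare preservation between localities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, EmptyProfileError, TrilomorphError
from .surface_io import DEM

DEFAULT_N_SAMPLES = 1500  # one per instrument scan line
#: exsagittal offset as a fraction of the scan-window width
DEFAULT_EXSAGITTAL_OFFSET = 0.15


@dataclass
class Profile:
    """Ordered (s, z) elevation series along a straight line.

    ``s`` is horizontal distance along the line from its first endpoint (mm),
    strictly increasing from 0; ``z`` is elevation (mm). ``line`` stores the
    (x0, y0, x1, y1) endpoints in DEM coordinates when known.
    """

    s: np.ndarray
    z: np.ndarray
    specimen_id: str = ""
    orientation: str = "sagittal"  # or "exsagittal"
    line: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.s.shape != self.z.shape or self.s.ndim != 1:
            raise ValueError("s and z must be 1-D arrays of equal length")
        if len(self.s) < 2:
            raise ValueError("a profile needs at least 2 samples")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if not (np.all(np.isfinite(self.s)) and np.all(np.isfinite(self.z))):
            raise ValueError("profile samples must be finite")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])

    @property
    def relief(self) -> float:
        return float(self.z.max() - self.z.min())

    def to_csv(self, stream: IO[str]) -> None:
        pd.DataFrame({"s_mm": self.s, "z_mm": self.z}).to_csv(stream, index=False)

    @classmethod
    def from_csv(cls, stream: IO[str], specimen_id: str = "",
                 orientation: str = "sagittal") -> "Profile":
        df = pd.read_csv(stream)
        cols = {c.lower().strip(): c for c in df.columns}
        try:
            s, z = df[cols["s_mm"]].to_numpy(), df[cols["z_mm"]].to_numpy()
        except KeyError:
            raise TrilomorphError("profile CSV needs columns s_mm,z_mm") from None
        return cls(s=s, z=z, specimen_id=specimen_id, orientation=orientation)


@dataclass
class ReliefTable:
    """Per-specimen relief plus per-population five-number summaries."""

    per_specimen: pd.DataFrame   # columns: specimen_id, population, relief_mm
    per_population: pd.DataFrame  # index: population; min, q1, median, q3, max


def _bilinear(dem: DEM, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear interpolation on cell centers; NaN where any corner is nodata.

    Coordinates inside the DEM extent but within the outer half-cell band are
    clamped to the nearest cell center line (the interpolant degenerates to
    the edge value there).
    """
    xc, yc = dem.x_centers, dem.y_centers
    fx = np.clip((xs - xc[0]) / dem.cell_size, 0.0, len(xc) - 1.0)
    fy = np.clip((ys - yc[0]) / dem.cell_size, 0.0, len(yc) - 1.0)
    j0 = np.minimum(fx.astype(int), len(xc) - 2) if len(xc) > 1 else np.zeros_like(fx, int)
    i0 = np.minimum(fy.astype(int), len(yc) - 2) if len(yc) > 1 else np.zeros_like(fy, int)
    j1 = np.minimum(j0 + 1, len(xc) - 1)
    i1 = np.minimum(i0 + 1, len(yc) - 1)
    tx = fx - j0
    ty = fy - i0
    v = dem.values
    z = ((1 - tx) * (1 - ty) * v[i0, j0] + tx * (1 - ty) * v[i0, j1]
         + (1 - tx) * ty * v[i1, j0] + tx * ty * v[i1, j1])
    return z


def extract_profile(dem: DEM, line: Sequence[float],
                    n_samples: int = DEFAULT_N_SAMPLES,
                    specimen_id: str = "", orientation: str = "sagittal") -> Profile:
    """Sample elevation at ``n_samples`` equally spaced points along a line.

    ``line`` is (x0, y0, x1, y1) in DEM coordinates; both endpoints must lie
    inside the DEM extent. Elevation is bilinear in the 4 surrounding cell
    centers; samples touching nodata cells are dropped.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    x0, y0, x1, y1 = map(float, line)
    xmin, ymin, xmax, ymax = dem.extent
    for (px, py) in ((x0, y0), (x1, y1)):
        if not (xmin <= px <= xmax and ymin <= py <= ymax):
            raise BoundsError(f"line endpoint ({px}, {py}) outside DEM extent "
                              f"[{xmin}, {xmax}] x [{ymin}, {ymax}]")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    length = float(np.hypot(x1 - x0, y1 - y0))
    z = _bilinear(dem, xs, ys)
    ok = np.isfinite(z)
    if not ok.any() or ok.sum() < 2:
        raise EmptyProfileError("profile line crosses only nodata cells")
    s = t * length
    return Profile(s=s[ok], z=z[ok], specimen_id=specimen_id,
                   orientation=orientation, line=(x0, y0, x1, y1))


def resample_profile(p: Profile, n: int) -> Profile:
    """Linear resampling onto ``n`` uniform s positions; endpoints preserved."""
    if n < 2:
        raise ValueError("n must be >= 2")
    s_new = np.linspace(p.s[0], p.s[-1], n)
    z_new = np.interp(s_new, p.s, p.z)
    return Profile(s=s_new, z=z_new, specimen_id=p.specimen_id,
                   orientation=p.orientation, line=p.line)


def midline(dem: DEM, orientation: str = "sagittal",
            offset_fraction: float = DEFAULT_EXSAGITTAL_OFFSET) -> tuple[float, float, float, float]:
    """Default profile line: vertical midline of the scan window (sagittal) or
    a parallel line offset by ``offset_fraction`` of the window width."""
    xmin, ymin, xmax, ymax = dem.extent
    x = 0.5 * (xmin + xmax)
    if orientation == "exsagittal":
        x += offset_fraction * (xmax - xmin)
    eps = 0.51 * dem.cell_size  # keep endpoints on the cell-center lattice
    return (x, ymin + eps, x, ymax - eps)


def relief_by_group(profiles: Sequence[Profile], labels: Sequence[str]) -> ReliefTable:
    """Per-specimen relief and per-population quartiles (inclusive method)."""
    if len(profiles) != len(labels):
        raise ValueError("labels must align one-to-one with profiles")
    per = pd.DataFrame({
        "specimen_id": [p.specimen_id or f"spec{i}" for i, p in enumerate(profiles)],
        "population": list(labels),
        "relief_mm": [p.relief for p in profiles],
    })
    if per["specimen_id"].duplicated().any():
        dup = per.loc[per["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen ids: {dup}")
    rows = {}
    for pop, grp in per.groupby("population", sort=False):
        r = grp["relief_mm"].to_numpy()
        q1, med, q3 = np.percentile(r, [25, 50, 75])  # linear = Tukey inclusive
        rows[pop] = {"min": r.min(), "q1": q1, "median": med, "q3": q3,
                     "max": r.max(), "n": len(r)}
    return ReliefTable(per_specimen=per,
                       per_population=pd.DataFrame(rows).T.rename_axis("population"))
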