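"""Point-cloud and DEM text I/O.

Surface scans arrive as plain-text XYZ tables (one point per line, mm units).
Optical roughness meters deliver the cloud in coordinates relative to the scan
window; :func:`to_absolute_coordinates` translates them into the specimen's
absolute frame. DEMs are interchanged as ESRI ASCII grids (.asc) — a plain-text
raster with a six-line header — with elevations in mm.

Internally nodata cells are held as NaN; the integer sentinel (-9999 by ESRI
convention) only appears on disk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO

import numpy as np

from .errors import DegenerateGeometryError, FormatError, ParseError

DIALECTS = ("xyz_whitespace", "xyz_csv", "map_relative")
DEFAULT_NODATA = -9999.0

_COMMENT_PREFIXES = ("#", ";", "//")


@dataclass
class PointCloud:
    """Raw (x, y, z) surface samples of one specimen, in mm.

    ``source`` records where the points came from (file name or dialect);
    ``relative`` flags clouds still in scan-window coordinates.
    """

    points: np.ndarray  # (n, 3) float64
    specimen_id: str = ""
    source: str = ""
    relative: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("all coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class DEM:
    """Regular elevation grid.

    ``values`` is (n_rows, n_cols) with row index increasing northwards
    (row 0 = bottom row), matching the mathematical y axis. ``origin_x`` /
    ``origin_y`` locate the lower-left *corner* of the lower-left cell.
    Nodata cells are NaN in memory; ``nodata`` is the on-disk sentinel.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the full grid rectangle."""
        return (self.origin_x, self.origin_y,
                self.origin_x + self.n_cols * self.cell_size,
                self.origin_y + self.n_rows * self.cell_size)


def _is_comment(line: str) -> bool:
    s = line.strip()
    return not s or any(s.startswith(p) for p in _COMMENT_PREFIXES)


def parse_point_cloud(stream: IO[str] | str, dialect: str = "xyz_whitespace",
                      specimen_id: str = "") -> PointCloud:
    """Parse a text point cloud.

    Dialects: ``xyz_whitespace`` (x y z per line), ``xyz_csv`` (x,y,z), and
    ``map_relative`` — whitespace x y z relative to the scan window's
    lower-left corner, the form roughness-meter .MAP exports take.

    Lines whose first token is not numeric are treated as headers/comments and
    skipped; a line that starts numeric but carries a malformed later field is
    an error (with its line number).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sep = "," if dialect == "xyz_csv" else None
    pts: list[tuple[float, float, float]] = []
    n_lines = 0
    for lineno, line in enumerate(stream, start=1):
        n_lines += 1
        if _is_comment(line):
            continue
        fields = [f for f in line.strip().split(sep) if f != ""]
        try:
            first = float(fields[0])
        except (ValueError, IndexError):
            continue  # header line (e.g. "x y z")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        try:
            pts.append((first, float(fields[1]), float(fields[2])))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
    if not pts:
        raise ParseError(f"no valid data points in {n_lines} line(s)")
    return PointCloud(np.array(pts, dtype=float), specimen_id=specimen_id,
                      source=dialect, relative=(dialect == "map_relative"))


def write_point_cloud(cloud: PointCloud, stream: IO[str],
                      dialect: str = "xyz_whitespace") -> None:
    """Write a cloud back to text; round-trips exactly (shortest-repr floats)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "xyz_csv" else " "
    for x, y, z in cloud.points:
        stream.write(f"{float(x)!r}{sep}{float(y)!r}{sep}{float(z)!r}\n")


def to_absolute_coordinates(cloud: PointCloud,
                            origin: tuple[float, float, float]) -> PointCloud:
    """Translate a relative-coordinate cloud into the absolute frame.

    Every point is shifted by ``origin`` (the scan window's position); point
    count and order are unchanged.
    """
    origin = np.asarray(origin, dtype=float)
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValueError("origin must be 3 finite coordinates")
    return PointCloud(cloud.points + origin, specimen_id=cloud.specimen_id,
                      source=cloud.source, relative=False)


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_dem_grid(stream: IO[str] | str) -> DEM:
    """Read an ESRI ASCII grid. Header keys are case-insensitive;
    ``NODATA_value`` is optional (defaults to -9999)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    tokens = stream.read().split()
    header: dict[str, float] = {}
    i = 0
    while i + 1 < len(tokens):
        key = tokens[i].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            header[key] = float(tokens[i + 1])
            i += 2
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"missing header key(s): {', '.join(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if ncols <= 0 or nrows <= 0:
        raise FormatError("ncols and nrows must be positive")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    data = tokens[i:]
    if len(data) != nrows * ncols:
        raise FormatError(
            f"expected {nrows * ncols} values ({nrows}x{ncols}), got {len(data)}")
    try:
        vals = np.array(data, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise FormatError(f"non-numeric grid value: {exc}") from None
    vals[vals == nodata] = np.nan
    # on disk the first row is the northernmost; flip to row 0 = bottom
    return DEM(vals[::-1], origin_x=header["xllcorner"],
               origin_y=header["yllcorner"], cell_size=header["cellsize"],
               nodata=nodata)


def write_dem_grid(dem: DEM, stream: IO[str]) -> None:
    """Write a DEM as an ESRI ASCII grid (top row first, nodata as sentinel)."""
    stream.write(f"ncols {dem.n_cols}\n")
    stream.write(f"nrows {dem.n_rows}\n")
    stream.write(f"xllcorner {float(dem.origin_x)!r}\n")
    stream.write(f"yllcorner {float(dem.origin_y)!r}\n")
    stream.write(f"cellsize {float(dem.cell_size)!r}\n")
    stream.write(f"NODATA_value {float(dem.nodata)!r}\n")
    out = dem.values[::-1]
    for row in out:
        stream.write(" ".join(repr(float(dem.nodata)) if not np.isfinite(v)
                              else repr(float(v)) for v in row))
        stream.write("\n")


def require_noncollinear(points: np.ndarray, tol: float = 1e-12) -> None:
    """Raise if fewer than 3 points or all (x, y) positions are collinear."""
    if len(points) < 3:
        raise DegenerateGeometryError("need at least 3 points")
    xy = points[:, :2] - points[:, :2].mean(axis=0)
    # rank of the 2-D scatter: collinear clouds have a zero second singular value
    s = np.linalg.svd(xy, compute_uv=False)
    if s[1] <= tol * max(s[0], 1.0):
        raise DegenerateGeometryError("all points are collinear in the x-y plane")
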