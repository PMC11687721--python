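"""Inverse-distance-weighted interpolation of site-level occupancy onto a
regular planar grid, with ESRI ASCII grid I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0
EXACT_TOL = 1e-9


@dataclass
class GridSpec:
    """Regular grid: lower-left corner, square cell size, and dimensions."""

    x0: float
    y0: float
    cellsize: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cellsize <= 0 or self.ncols < 1 or self.nrows < 1:
            raise ValueError("invalid grid specification")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped (nrows, ncols); row 0 is
        the top row (matching the ASCII grid layout)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.y0 + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)


@dataclass
class OccupancySurface:
    """Interpolated probability surface on a :class:`GridSpec`.

    ``values`` is (nrows, ncols) with row 0 at the top; NaN marks NODATA.
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("values shape does not match grid")


def make_grid(
    x: np.ndarray, y: np.ndarray, cellsize: float, margin: float = 0.0
) -> GridSpec:
    """Grid covering the bounding box of the points plus ``margin``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0, y0 = x.min() - margin, y.min() - margin
    ncols = max(1, int(np.ceil((x.max() + margin - x0) / cellsize)))
    nrows = max(1, int(np.ceil((y.max() + margin - y0) / cellsize)))
    return GridSpec(x0=float(x0), y0=float(y0), cellsize=cellsize, ncols=ncols, nrows=nrows)


def idw_interpolate(
    points,
    grid: GridSpec,
    power: float = 2.0,
    max_points: int | None = None,
) -> OccupancySurface:
    """Inverse-distance-weighted surface from (x, y, value) samples.

    Each cell takes sum(w_i v_i)/sum(w_i) with w_i = d_i^(-power) over the
    ``max_points`` nearest samples (all samples if unset). A cell whose
    center lies on a sample point takes that sample's value exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("points must be a nonempty (n, 3) array of (x, y, value)")
    if power <= 0:
        raise ValueError("power must be positive")
    px, py, pv = pts[:, 0], pts[:, 1], pts[:, 2]

    gx, gy = grid.cell_centers()
    cells = np.column_stack([gx.ravel(), gy.ravel()])

    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([px, py]))
    k = len(pts) if max_points is None else min(max_points, len(pts))
    dist, idx = tree.query(cells, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]

    exact = dist[:, 0] < EXACT_TOL
    # normalize by each cell's nearest distance so d^-power cannot overflow
    # even at large powers (weights are then <= 1 with the nearest at 1)
    dmin = np.maximum(dist[:, :1], EXACT_TOL)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.power(dist / dmin, -power)
        vals = np.einsum("ij,ij->i", w, pv[idx]) / w.sum(axis=1)
    vals[exact] = pv[idx[exact, 0]]
    return OccupancySurface(grid=grid, values=vals.reshape(grid.nrows, grid.ncols))


def write_surface(surface: OccupancySurface, path) -> None:
    """ESRI ASCII grid writer (rows top-to-bottom, %.17g values)."""
    g = surface.grid
    lines = [
        f"ncols {g.ncols}",
        f"nrows {g.nrows}",
        f"xllcorner {g.x0:.17g}",
        f"yllcorner {g.y0:.17g}",
        f"cellsize {g.cellsize:.17g}",
        f"NODATA_value {NODATA:g}",
    ]
    vals = np.where(np.isnan(surface.values), NODATA, surface.values)
    for row in vals:
        lines.append(" ".join(f"{v:.17g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_surface(path) -> OccupancySurface:
    """Read an ESRI ASCII grid written by :func:`write_surface`."""
    text = Path(path).read_text().strip().splitlines()
    header = {}
    for line in text[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    grid = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cellsize=header["cellsize"],
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
    )
    nodata = header["nodata_value"]
    values = np.array([[float(v) for v in line.split()] for line in text[6:]])
    values[values == nodata] = np.nan
    return OccupancySurface(grid=grid, values=values)
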