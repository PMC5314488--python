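"""Pycnophylactic (mean-preserving) interpolation of block scores to a raster.

Block-average aesthetics scores are an intensity attached to whole polygons;
mapping them directly gives hard discontinuities at block edges.  Tobler's
pycnophylactic interpolation smooths the surface while honouring the data:
each iteration replaces every cell by the average of its neighbours and then
additively re-adjusts the cells of each zone so the zone's mean recovers its
input value.  The classic formulation preserves zone *volume* (count data);
here the preserved quantity is the zone mean, which for equal-area cells is
volume preservation up to the zone-area factor.

Cells are assigned to zones by cell-center containment; boundary handling is
edge replication (no-flow), and an optional clamp keeps the surface inside a
stated range (with re-adjustment after clamping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely import contains_xy
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "ZoneValueLayer",
    "ScoreRaster",
    "pycnophylactic_interpolate",
    "read_zones_geojson",
    "write_esri_ascii",
]

NODATA = -9999.0


@dataclass
class ZoneValueLayer:
    """Zone polygons, one real value each (e.g. average block score)."""

    zone_ids: list[str]
    geometries: list[BaseGeometry]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.zone_ids) == len(self.geometries) == self.values.size):
            raise ValueError("zone_ids, geometries and values must be parallel")
        if not np.isfinite(self.values).all():
            bad = self.zone_ids[int(np.argmax(~np.isfinite(self.values)))]
            raise ValueError(f"non-finite value for zone {bad!r}")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        bs = np.array([g.bounds for g in self.geometries])
        return (bs[:, 0].min(), bs[:, 1].min(), bs[:, 2].max(), bs[:, 3].max())


@dataclass
class ScoreRaster:
    """Interpolated surface with zone assignment and convergence log.

    ``grid`` rows run north to south (row 0 is the top); ``zone_grid`` holds
    the zone index per cell or -1 outside all zones; ``origin`` is the
    (xllcorner, yllcorner) of the grid in map units.
    """

    grid: np.ndarray
    zone_grid: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    zone_ids: list[str]
    convergence: list[tuple[int, float]]

    def zone_means(self) -> np.ndarray:
        out = np.full(len(self.zone_ids), np.nan)
        for zi in range(len(self.zone_ids)):
            mask = self.zone_grid == zi
            if mask.any():
                out[zi] = self.grid[mask].mean()
        return out


def _rasterize(layer: ZoneValueLayer, cell_m: float):
    minx, miny, maxx, maxy = layer.bounds
    ncols = max(1, int(np.ceil((maxx - minx) / cell_m)))
    nrows = max(1, int(np.ceil((maxy - miny) / cell_m)))
    xs = minx + (np.arange(ncols) + 0.5) * cell_m
    ys = maxy - (np.arange(nrows) + 0.5) * cell_m  # row 0 at the top
    xx, yy = np.meshgrid(xs, ys)
    zone_grid = np.full((nrows, ncols), -1, dtype=int)
    for zi, geom in enumerate(layer.geometries):
        gminx, gminy, gmaxx, gmaxy = geom.bounds
        sub = (
            (xx >= gminx - cell_m)
            & (xx <= gmaxx + cell_m)
            & (yy >= gminy - cell_m)
            & (yy <= gmaxy + cell_m)
            & (zone_grid == -1)
        )
        if not sub.any():
            continue
        hit = contains_xy(geom, xx[sub], yy[sub])
        idx = np.argwhere(sub)
        claimed = idx[hit]
        zone_grid[claimed[:, 0], claimed[:, 1]] = zi
    for zi, zid in enumerate(layer.zone_ids):
        if not (zone_grid == zi).any():
            raise ValueError(
                f"zone {zid!r} rasterizes to no cell at cell size {cell_m}; "
                "use a smaller cell"
            )
    return zone_grid, (minx, miny), nrows, ncols


def _neighbour_mean(grid: np.ndarray, inside: np.ndarray, neighbourhood: int) -> np.ndarray:
    """Mean of 4- or 8-neighbours, edge-replicated, NaN-outside excluded."""
    padded = np.pad(grid, 1, mode="edge")
    w = np.pad(inside.astype(float), 1, mode="edge")
    pv = np.where(np.isnan(padded), 0.0, padded) * w
    if neighbourhood == 4:
        shifts = [(0, 1), (2, 1), (1, 0), (1, 2)]
    elif neighbourhood == 8:
        shifts = [(i, j) for i in range(3) for j in range(3) if (i, j) != (1, 1)]
    else:
        raise ValueError("neighbourhood must be 4 or 8")
    num = np.zeros_like(grid)
    den = np.zeros_like(grid)
    r, c = grid.shape
    for di, dj in shifts:
        num += pv[di : di + r, dj : dj + c]
        den += w[di : di + r, dj : dj + c]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, grid)


def pycnophylactic_interpolate(
    layer: ZoneValueLayer,
    cell_m: float,
    max_iter: int = 1000,
    tol: float = 1e-4,
    neighbourhood: int = 4,
    clamp: tuple[float, float] | None = None,
) -> ScoreRaster:
    """Smooth zone values into a continuous surface, preserving zone means.

    Iterates {neighbour smoothing with edge replication; additive per-zone
    re-adjustment restoring each zone's mean; optional clamp to ``clamp``
    followed by another re-adjustment} until the maximum absolute cell
    change drops below ``tol`` or ``max_iter`` is reached.  The convergence
    log records (iteration, max absolute change).
    """
    zone_grid, origin, nrows, ncols = _rasterize(layer, cell_m)
    inside = zone_grid >= 0
    grid = np.full((nrows, ncols), np.nan)
    masks = [zone_grid == zi for zi in range(len(layer.zone_ids))]
    for zi, mask in enumerate(masks):
        grid[mask] = layer.values[zi]

    log: list[tuple[int, float]] = []
    for it in range(1, max_iter + 1):
        prev = grid.copy()
        smoothed = _neighbour_mean(grid, inside, neighbourhood)
        grid = np.where(inside, smoothed, np.nan)
        for zi, mask in enumerate(masks):
            grid[mask] += layer.values[zi] - grid[mask].mean()
        if clamp is not None:
            lo, hi = clamp
            np.clip(grid, lo, hi, out=grid)
            # restore zone means without re-breaching the clamp: spread the
            # residual over cells that can still move in the needed direction
            for zi, mask in enumerate(masks):
                cells = grid[mask]
                for _ in range(20):
                    resid = layer.values[zi] - cells.mean()
                    if abs(resid) < tol * 1e-3:
                        break
                    free = cells < hi - 1e-15 if resid > 0 else cells > lo + 1e-15
                    if not free.any():
                        break
                    cells[free] += resid * cells.size / free.sum()
                    np.clip(cells, lo, hi, out=cells)
                grid[mask] = cells
        change = float(np.nanmax(np.abs(grid - prev))) if inside.any() else 0.0
        log.append((it, change))
        if change < tol:
            break
    return ScoreRaster(
        grid=grid,
        zone_grid=zone_grid,
        cell_size=cell_m,
        origin=origin,
        zone_ids=list(layer.zone_ids),
        convergence=log,
    )


# ---------------------------------------------------------------------------
# I/O

def read_zones_geojson(path: str | Path, value_property: str = "value") -> ZoneValueLayer:
    """Read zone polygons with a real ``value`` property from GeoJSON."""
    with open(path) as fh:
        gj = json.load(fh)
    ids, geoms, vals = [], [], []
    for i, feat in enumerate(gj["features"]):
        props = feat["properties"]
        ids.append(str(props.get("zone_id", i)))
        geoms.append(shape(feat["geometry"]))
        vals.append(float(props[value_property]))
    return ZoneValueLayer(ids, geoms, np.array(vals))


def write_esri_ascii(path: str | Path, raster: ScoreRaster) -> None:
    """Write the surface as an ESRI ASCII grid (NODATA outside all zones)."""
    nrows, ncols = raster.grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]}\n"
        f"yllcorner {raster.origin[1]}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    body = np.where(np.isnan(raster.grid), NODATA, raster.grid)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")
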