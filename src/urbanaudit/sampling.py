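"""Area-proportional spatial sampling of audit points within neighbourhoods.

Audit points are placed inside residential zoning polygons so that the
probability of landing in a zone *type* (R1 detached dwellings ... R5
high-rise, RM mobile home) equals that type's share of the neighbourhood's
total residential area — zoning density standing in as a proxy for
within-neighbourhood variation when no finer socio-economic data exist.
Each selected point gets a circular observation buffer (default radius
100 m) delimiting where observations are made.

Geometry is handled with shapely; polygons must be in a projected
coordinate system in meters (buffering in degrees is refused).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely import contains_xy
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "ZoningMap",
    "AuditPoint",
    "sample_audit_points",
    "assign_points_to_blocks",
    "read_zoning_geojson",
    "write_points_geojson",
    "write_buffers_geojson",
]

ZONE_TYPES = ("R1", "R2", "R3", "R4", "R5", "RM")

#: redraw budget per requested point before giving up on min_separation
ATTEMPT_BUDGET = 200


def _looks_geographic(geoms: Iterable[BaseGeometry]) -> bool:
    """Heuristic: every coordinate inside lon/lat bounds ⇒ likely degrees."""
    xs, ys = [], []
    for g in geoms:
        minx, miny, maxx, maxy = g.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    return (
        bool(xs)
        and min(xs) >= -180 and max(xs) <= 180
        and min(ys) >= -90 and max(ys) <= 90
    )


@dataclass
class ZoningMap:
    """Residential zoning polygons grouped by neighbourhood.

    ``zones`` maps neighbourhood id -> list of (zone_type, polygon); polygons
    are validated (non-self-intersecting) and must use projected coordinates
    in meters.
    """

    zones: dict[str, list[tuple[str, Polygon]]]

    def __post_init__(self) -> None:
        all_polys = []
        for nid, zlist in self.zones.items():
            for ztype, poly in zlist:
                if poly.area == 0:  # degenerate zones carry no probability
                    continue
                if not poly.is_valid:
                    raise ValueError(
                        f"invalid (self-intersecting) zone polygon of type "
                        f"{ztype} in neighbourhood {nid!r}"
                    )
                all_polys.append(poly)
        if _looks_geographic(all_polys):
            raise ValueError(
                "zoning coordinates look geographic (degrees); re-project to "
                "a metric CRS before sampling — 100 m buffers in degrees are "
                "meaningless"
            )

    def type_areas(self, neighbourhood_id: str) -> dict[str, float]:
        """Total area (m^2) per zone type within one neighbourhood."""
        areas: dict[str, float] = {}
        for ztype, poly in self.zones[neighbourhood_id]:
            areas[ztype] = areas.get(ztype, 0.0) + poly.area
        return areas

    @property
    def neighbourhood_ids(self) -> list[str]:
        return sorted(self.zones)


@dataclass(frozen=True)
class AuditPoint:
    """A sampled audit point with its circular observation buffer."""

    x: float
    y: float
    neighbourhood_id: str
    zone_type: str
    radius_m: float
    seed: int
    buffer: Polygon = field(repr=False, compare=False)

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


def _uniform_point_in(
    polys: Sequence[Polygon], rng: np.random.Generator, max_tries: int = 10_000
) -> Point:
    """Uniform point over a union of polygons via area-weighted bbox rejection."""
    areas = np.array([p.area for p in polys])
    probs = areas / areas.sum()
    for _ in range(max_tries):
        poly = polys[rng.choice(len(polys), p=probs)]
        minx, miny, maxx, maxy = poly.bounds
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if contains_xy(poly, x, y):
            return Point(x, y)
    raise RuntimeError("rejection sampling failed; polygon nearly degenerate?")


def sample_audit_points(
    zoning: ZoningMap,
    k_per_neighbourhood: int,
    radius_m: float = 100.0,
    seed: int = 0,
    min_separation: float | None = None,
) -> list[AuditPoint]:
    """Draw k audit points per neighbourhood, zone-type area-proportional.

    Each point independently draws a zone type with probability equal to the
    type's share of the neighbourhood's residential area, then a uniform
    location within that type's (pooled) polygons.  ``min_separation``
    defaults to ``2*radius_m`` (non-overlapping buffers); points violating it
    are redrawn up to a bounded attempt budget.  Fully reproducible from
    ``seed``; neighbourhoods are processed in sorted id order.
    """
    if k_per_neighbourhood < 1:
        raise ValueError("k_per_neighbourhood must be >= 1")
    if min_separation is None:
        min_separation = 2.0 * radius_m
    rng = np.random.default_rng(seed)
    out: list[AuditPoint] = []
    for nid in zoning.neighbourhood_ids:
        areas = zoning.type_areas(nid)
        types = sorted(t for t, a in areas.items() if a > 0)
        if not types:
            raise ValueError(f"neighbourhood {nid!r} has no residential area")
        probs = np.array([areas[t] for t in types])
        probs = probs / probs.sum()
        polys_by_type = {
            t: [p for zt, p in zoning.zones[nid] if zt == t and p.area > 0]
            for t in types
        }
        placed: list[AuditPoint] = []
        attempts = 0
        while len(placed) < k_per_neighbourhood:
            if attempts >= ATTEMPT_BUDGET * k_per_neighbourhood:
                raise RuntimeError(
                    f"could not place {k_per_neighbourhood} points at least "
                    f"{min_separation} m apart in neighbourhood {nid!r} "
                    f"(achieved {len(placed)})"
                )
            attempts += 1
            ztype = types[rng.choice(len(types), p=probs)]
            pt = _uniform_point_in(polys_by_type[ztype], rng)
            if min_separation > 0 and any(
                pt.distance(q.point) < min_separation for q in placed
            ):
                continue
            placed.append(
                AuditPoint(
                    x=pt.x,
                    y=pt.y,
                    neighbourhood_id=nid,
                    zone_type=ztype,
                    radius_m=radius_m,
                    seed=seed,
                    buffer=pt.buffer(radius_m),
                )
            )
        out.extend(placed)
    return out


def assign_points_to_blocks(
    points: Sequence[AuditPoint | Point],
    blocks: Mapping[str, Polygon],
) -> dict[int, tuple[str, bool]]:
    """Map each point (by position in the list) to its containing block id.

    Boundary points touching several blocks are assigned to the
    lexicographically smallest block id and flagged (second tuple element).
    A point outside every block raises.
    """
    out: dict[int, tuple[str, bool]] = {}
    ids = sorted(blocks)
    for i, p in enumerate(points):
        pt = p.point if isinstance(p, AuditPoint) else p
        inside = [bid for bid in ids if blocks[bid].contains(pt)]
        if inside:
            out[i] = (inside[0], False)
            continue
        touching = [bid for bid in ids if blocks[bid].intersects(pt)]
        if not touching:
            raise ValueError(f"point {i} at ({pt.x}, {pt.y}) lies outside all blocks")
        # on a block boundary: smallest-id block wins, assignment is flagged
        out[i] = (touching[0], True)
    return out


# ---------------------------------------------------------------------------
# GeoJSON interfaces (plain json + shapely, no CRS machinery)

def read_zoning_geojson(path: str | Path) -> ZoningMap:
    """Read zone polygons from GeoJSON with properties neighbourhood_id, zone_type."""
    with open(path) as fh:
        gj = json.load(fh)
    zones: dict[str, list[tuple[str, Polygon]]] = {}
    for feat in gj["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        zones.setdefault(str(props["neighbourhood_id"]), []).append(
            (str(props["zone_type"]), geom)
        )
    return ZoningMap(zones)


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_points_geojson(path: str | Path, points: Sequence[AuditPoint]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(p.point),
            "properties": {
                "neighbourhood_id": p.neighbourhood_id,
                "zone_type": p.zone_type,
                "radius_m": p.radius_m,
                "seed": p.seed,
            },
        }
        for p in points
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def write_buffers_geojson(path: str | Path, points: Sequence[AuditPoint]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(p.buffer),
            "properties": {
                "neighbourhood_id": p.neighbourhood_id,
                "zone_type": p.zone_type,
                "radius_m": p.radius_m,
            },
        }
        for p in points
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats)))
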