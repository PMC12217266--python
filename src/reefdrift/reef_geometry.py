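"""Reef polygons: GeoJSON I/O, plan areas, seeding rule, and point-in-reef queries.

Reefs are the sources and destinations of the dispersal analysis. Each polygon
carries a reef id and a complex id (reefs are grouped into named complexes for
block-level aggregation). A :class:`ReefSet` keeps its polygons ordered from
north to south — the matrix convention used throughout — and answers bulk
containment queries through an STRtree spatial index.

The seeding rule follows the larval-release protocol for broadcast-spawning
corals: polygons above 1 km^2 receive 200 larvae per km^2 of plan area,
smaller polygons receive a floor of 200 larvae.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape
from shapely.strtree import STRtree

from .grid import EARTH_RADIUS_M

__all__ = [
    "ReefPolygon", "ReefSet", "read_reefs", "write_reefs",
    "area_km2", "seed_count", "sample_release_points", "locate",
    "SEED_DENSITY_PER_KM2", "SEED_FLOOR", "SEED_AREA_THRESHOLD_KM2",
]

SEED_DENSITY_PER_KM2 = 200.0
SEED_FLOOR = 200
SEED_AREA_THRESHOLD_KM2 = 1.0


def _laea_xy(lon, lat, lon0, lat0, radius=EARTH_RADIUS_M):
    """Lambert azimuthal equal-area forward projection about (lon0, lat0), metres."""
    lam = np.deg2rad(np.asarray(lon, dtype=float) - lon0)
    phi = np.deg2rad(np.asarray(lat, dtype=float))
    phi0 = math.radians(lat0)
    c = 1.0 + math.sin(phi0) * np.sin(phi) + math.cos(phi0) * np.cos(phi) * np.cos(lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(2.0 / c)
    x = radius * k * np.cos(phi) * np.sin(lam)
    y = radius * k * (math.cos(phi0) * np.sin(phi) - math.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y


def area_km2(polygon: Polygon) -> float:
    """Plan area of a lon/lat polygon in km^2.

    Shoelace area on a local equal-area azimuthal projection centred at the
    polygon centroid; exact up to projection distortion, negligible for reefs
    a few km across. Vertex order does not matter.
    """
    if polygon.is_empty or len(polygon.exterior.coords) < 4:
        raise ValueError("degenerate ring: polygon needs >= 3 distinct vertices")
    c = polygon.centroid
    ext = np.asarray(polygon.exterior.coords)
    x, y = _laea_xy(ext[:, 0], ext[:, 1], c.x, c.y)
    area = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    for ring in polygon.interiors:
        r = np.asarray(ring.coords)
        xh, yh = _laea_xy(r[:, 0], r[:, 1], c.x, c.y)
        area -= 0.5 * abs(np.dot(xh[:-1], yh[1:]) - np.dot(xh[1:], yh[:-1]))
    if not area > 1e-6:  # < 1 m^2 of plan area: degenerate for reef purposes
        raise ValueError("degenerate ring: zero plan area")
    return float(area / 1e6)


def seed_count(area: float) -> int:
    """Larvae seeded on a polygon of the given plan area (km^2).

    Above the 1 km^2 threshold (strictly exceeding): 200 larvae per km^2,
    rounded to the nearest integer (half away from zero). At or below the
    threshold: a flat 200 larvae.
    """
    if not area > 0:
        raise ValueError("reef area must be positive")
    if area > SEED_AREA_THRESHOLD_KM2:
        return int(math.floor(SEED_DENSITY_PER_KM2 * area + 0.5))
    return SEED_FLOOR


@dataclass(frozen=True)
class ReefPolygon:
    reef_id: str
    complex_id: str
    polygon: Polygon
    area_km2: float = dc_field(default=None)

    def __post_init__(self):
        if not self.polygon.is_valid:
            raise ValueError(f"reef '{self.reef_id}': invalid (self-intersecting?) ring")
        if self.area_km2 is None:
            object.__setattr__(self, "area_km2", area_km2(self.polygon))

    @property
    def centroid_lat(self) -> float:
        return float(self.polygon.centroid.y)


class ReefSet:
    """Ordered collection of reef polygons with a spatial index.

    Order is by centroid latitude, north to south, matching the connectivity
    matrix convention (source reefs increase in latitude from top to bottom).
    """

    def __init__(self, reefs):
        reefs = sorted(reefs, key=lambda r: -r.centroid_lat)
        ids = [r.reef_id for r in reefs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reef_id(s): {dupes}")
        self.reefs = list(reefs)
        self._tree = STRtree([r.polygon for r in self.reefs])
        self._geoms = np.array([r.polygon for r in self.reefs], dtype=object)
        overlaps = self._tree.query(self._geoms, predicate="overlaps")
        if overlaps.size:
            warnings.warn("overlapping reef polygons; locate() resolves by reef order")

    def __len__(self):
        return len(self.reefs)

    def __iter__(self):
        return iter(self.reefs)

    def __getitem__(self, k) -> ReefPolygon:
        return self.reefs[k]

    @property
    def reef_ids(self):
        return [r.reef_id for r in self.reefs]

    @property
    def complex_map(self):
        return {r.reef_id: r.complex_id for r in self.reefs}

    @property
    def complex_order(self):
        """Complex labels in first-appearance (north-to-south) order."""
        seen = []
        for r in self.reefs:
            if r.complex_id not in seen:
                seen.append(r.complex_id)
        return seen

    def locate_many(self, lon, lat) -> np.ndarray:
        """Index of the containing reef for each point, -1 where none.

        Overlaps resolve to the first reef in north-to-south order. Boundary
        points count as contained.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        pts = shapely.points(lon, lat)
        qi, ti = self._tree.query(pts, predicate="intersects")
        out = np.full(lon.shape, -1, dtype=int)
        if qi.size:
            order = np.lexsort((ti, qi))  # per point, keep smallest reef index
            qi, ti = qi[order], ti[order]
            first = np.concatenate(([True], qi[1:] != qi[:-1]))
            out[qi[first]] = ti[first]
        return out

    def locate(self, lon, lat):
        """reef_id containing the point, or None."""
        k = int(self.locate_many([lon], [lat])[0])
        return self.reefs[k].reef_id if k >= 0 else None


def locate(lon, lat, reefs: ReefSet):
    return reefs.locate(lon, lat)


def sample_release_points(polygon: Polygon, n: int, rng: np.random.Generator,
                          max_attempts: int = 10_000):
    """n release points uniform over the polygon, by bounding-box rejection."""
    if n < 1:
        raise ValueError("n must be >= 1")
    minx, miny, maxx, maxy = polygon.bounds
    lons = np.empty(n)
    lats = np.empty(n)
    got = 0
    for _ in range(max_attempts):
        m = max(2 * (n - got), 32)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(polygon, x, y)
        k = min(int(keep.sum()), n - got)
        lons[got:got + k] = x[keep][:k]
        lats[got:got + k] = y[keep][:k]
        got += k
        if got == n:
            return lons, lats
    raise RuntimeError("rejection sampling failed; polygon too thin?")


# -- I/O ---------------------------------------------------------------------

def read_reefs(path, reef_id_prop="reef_id", complex_id_prop="complex_id",
               split_multipolygons=True) -> ReefSet:
    """Load reef polygons from a GeoJSON FeatureCollection (RFC 7946, lon-lat).

    MultiPolygons are split into parts with suffixed ids by default. Shapefile
    input is not supported in this build; convert to GeoJSON first (e.g. with
    `ogr2ogr -f GeoJSON`).
    """
    spath = str(path)
    if spath.lower().endswith((".shp", ".shx", ".dbf")):
        raise ValueError("shapefile input is not supported; convert to GeoJSON first")
    with open(spath) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    reefs = []
    for feat in feats:
        props = feat.get("properties") or {}
        if reef_id_prop not in props:
            raise ValueError(f"feature missing '{reef_id_prop}' property")
        rid = str(props[reef_id_prop])
        cid = str(props.get(complex_id_prop, rid))
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            if split_multipolygons:
                for k, part in enumerate(geom.geoms):
                    reefs.append(ReefPolygon(f"{rid}-{k}", cid, part))
                continue
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon":
            raise ValueError(f"reef '{rid}': unsupported geometry {geom.geom_type}")
        reefs.append(ReefPolygon(rid, cid, geom))
    if not reefs:
        raise ValueError("no reef features found")
    return ReefSet(reefs)


def write_reefs(reefs: ReefSet, path) -> None:
    feats = []
    for r in reefs:
        feats.append({
            "type": "Feature",
            "properties": {"reef_id": r.reef_id, "complex_id": r.complex_id,
                           "area_km2": round(r.area_km2, 6)},
            "geometry": mapping(r.polygon),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
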