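"""Synthetic, divergence-free surface-current fields and reef sets.

A Delagoa-Bight-like sector of a western-boundary current system is emulated
with streamfunction-based building blocks: a uniform drift, a
Rankine vortex (solid-body core, 1/r exterior; the stand-in for mesoscale
cyclones and anticyclones) and a Gaussian jet following a waypoint path (the
coastal streams). Because velocities derive from a scalar streamfunction by
central differences on one fixed local-metres metric, the discrete divergence
of every generated field vanishes identically: particles cannot artificially
accumulate, and the streamfunction doubles as a free conservation oracle for
the tracker.

Three named scenarios mirror the region's flow regimes:

A. a slow coastal jet hugging the bight (peak ~0.3 m/s) — the weak alongshore
   stream whose transit times between distant reef complexes exceed the
   pelagic larval duration;
B. a fast straight jet bypassing the bight mouth (peak ~1.0 m/s) plus a
   cyclonic lee eddy inside the bight — larvae released in the bight
   recirculate before reaching the jet, lengthening travel times;
C. a fast coastal stream (>= 1.5 m/s, western-boundary-current strength) fed
   by a large offshore anticyclone — distant complexes connect within the
   settlement window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import erf
from shapely.geometry import Polygon

from .current_field import FlowField
from .grid import EARTH_RADIUS_M, GridSpec, LocalMetric, times_to_seconds
from .reef_geometry import ReefPolygon, ReefSet

__all__ = [
    "BightCoast", "UniformDrift", "RankineVortex", "GaussianJet", "Modulation",
    "Component", "ScenarioSpec", "make_landmask", "streamfunction",
    "velocity_field", "scenario_library", "generate_reefs", "write_currents",
    "default_grid", "default_coast", "DEFAULT_BAND_LATITUDES",
]


# -- coastline ----------------------------------------------------------------

@dataclass(frozen=True)
class BightCoast:
    """A meridional coastline (land to the west) with a concave bight.

    The coastline longitude recedes landward by ``indent_deg`` around
    ``bight_lat`` with a Gaussian profile of scale ``half_width_deg``,
    producing the concave undulation that deflects alongshore currents.
    """

    coast_lon: float
    bight_lat: float
    half_width_deg: float
    indent_deg: float

    def __post_init__(self):
        if self.indent_deg < 0:
            raise ValueError("indentation depth must be >= 0")
        if self.half_width_deg <= 0:
            raise ValueError("bight half-width must be > 0")

    def coastline_lon(self, lat):
        """Longitude of the land/ocean boundary at the given latitude(s)."""
        lat = np.asarray(lat, dtype=float)
        return self.coast_lon - self.indent_deg * np.exp(
            -((lat - self.bight_lat) / self.half_width_deg) ** 2
        )

    def is_land(self, lon, lat):
        return np.asarray(lon, dtype=float) <= self.coastline_lon(lat)


def make_landmask(grid: GridSpec, coast: BightCoast | None) -> np.ndarray:
    """Boolean (lat, lon) mask, True on land. coast=None -> all ocean."""
    if coast is None:
        return np.zeros((grid.nlat, grid.nlon), dtype=bool)
    lon2, lat2 = np.meshgrid(grid.lons, grid.lats)
    mask = coast.is_land(lon2, lat2)
    if mask.all():
        raise ValueError("degenerate domain: grid is entirely land")
    return mask


# -- flow components -----------------------------------------------------------

@dataclass(frozen=True)
class UniformDrift:
    """Constant background drift (m/s). psi = v*x - u*y."""
    u: float
    v: float

    def psi(self, x, y, metric):
        return self.v * x - self.u * y


@dataclass(frozen=True)
class RankineVortex:
    """Idealised eddy: solid-body core, 1/r exterior tangential speed.

    rotation +1 = counterclockwise (southern-hemisphere anticyclone),
    -1 = clockwise (southern-hemisphere cyclone). Peak tangential speed
    ``peak_speed`` m/s occurs at ``core_radius_km``.
    """
    lon: float
    lat: float
    core_radius_km: float
    peak_speed: float
    rotation: int = 1

    def __post_init__(self):
        if self.core_radius_km <= 0:
            raise ValueError("core radius must be > 0")
        if not math.isfinite(self.peak_speed):
            raise ValueError("peak speed must be finite")

    def psi(self, x, y, metric):
        xc, yc = metric.to_xy(self.lon, self.lat)
        rc = self.core_radius_km * 1e3
        r = np.hypot(x - xc, y - yc)
        core = self.peak_speed * r * r / (2.0 * rc)
        outer = self.peak_speed * rc * (0.5 + np.log(np.maximum(r, rc) / rc))
        return self.rotation * np.where(r <= rc, core, outer)


@dataclass(frozen=True)
class GaussianJet:
    """A jet flowing along a waypoint path with a Gaussian cross-profile.

    Speed on the axis is ``peak_speed`` m/s, decaying as exp(-(d/W)^2) with
    signed cross-track distance d and width W = ``width_km``. Flow runs from
    the first waypoint towards the last.
    """
    waypoints: tuple  # ((lon, lat), ...)
    width_km: float
    peak_speed: float

    def __post_init__(self):
        if self.width_km <= 0:
            raise ValueError("jet width must be > 0")
        if len(self.waypoints) < 2:
            raise ValueError("jet path needs >= 2 waypoints")
        if not math.isfinite(self.peak_speed):
            raise ValueError("peak speed must be finite")

    def _signed_distance(self, x, y, metric):
        wp = np.asarray(self.waypoints, dtype=float)
        px_all, py_all = metric.to_xy(wp[:, 0], wp[:, 1])
        # extend the end segments far out so the sign seam behind each endpoint
        # (where the cross product flips across the path extension) lies outside
        # any realistic domain
        ext = 5e6  # metres
        for tail, head in ((0, 1), (-1, -2)):
            dx, dy = px_all[tail] - px_all[head], py_all[tail] - py_all[head]
            norm = math.hypot(dx, dy)
            px_all[tail] += dx / norm * ext
            py_all[tail] += dy / norm * ext
        ax, ay = px_all[:-1], py_all[:-1]
        bx, by = px_all[1:], py_all[1:]
        px = np.asarray(x, dtype=float)[..., None]
        py = np.asarray(y, dtype=float)[..., None]
        dx, dy = bx - ax, by - ay
        seg2 = dx * dx + dy * dy
        t = np.clip(((px - ax) * dx + (py - ay) * dy) / seg2, 0.0, 1.0)
        cx, cy = ax + t * dx, ay + t * dy
        d2 = (px - cx) ** 2 + (py - cy) ** 2
        k = np.argmin(d2, axis=-1)
        idx = np.indices(k.shape)
        dmin = np.sqrt(d2[(*idx, k)])
        cross = dx[k] * (py[..., 0] - ay[k]) - dy[k] * (px[..., 0] - ax[k])
        return np.where(cross >= 0, dmin, -dmin)  # positive to the left of travel

    def psi(self, x, y, metric):
        w = self.width_km * 1e3
        d = self._signed_distance(x, y, metric)
        return -self.peak_speed * w * (math.sqrt(math.pi) / 2.0) * erf(d / w)


@dataclass(frozen=True)
class Modulation:
    """Piecewise-linear amplitude vs time (clamped outside the knots)."""
    times: tuple  # datetime64-convertible knots
    amplitudes: tuple

    def __call__(self, t_seconds: float) -> float:
        ts = times_to_seconds(np.asarray(self.times, dtype="datetime64[ns]"))
        return float(np.interp(t_seconds, ts, np.asarray(self.amplitudes, dtype=float)))


@dataclass(frozen=True)
class Component:
    shape: object  # UniformDrift | RankineVortex | GaussianJet
    modulation: Modulation | None = None

    def amplitude(self, t_seconds: float) -> float:
        return 1.0 if self.modulation is None else self.modulation(t_seconds)


@dataclass(frozen=True)
class ScenarioSpec:
    """A synthetic flow scenario: components + coastline + reference point."""
    components: tuple
    coast: BightCoast | None = None
    lon_ref: float = 0.0
    lat_ref: float = 0.0

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("scenario needs at least one component")

    @property
    def metric(self) -> LocalMetric:
        return LocalMetric(self.lon_ref, self.lat_ref)


def streamfunction(spec: ScenarioSpec, lon, lat, t) -> np.ndarray:
    """Total streamfunction psi (m^2/s) at positions and one instant.

    Pure function: the sum of the component streamfunctions, each scaled by
    its time modulation. ``t`` may be a datetime64 or float epoch seconds.
    """
    t_sec = float(times_to_seconds(t)) if isinstance(t, np.datetime64) else float(t)
    metric = spec.metric
    x, y = metric.to_xy(lon, lat)
    psi = np.zeros(np.broadcast(np.asarray(lon, float), np.asarray(lat, float)).shape)
    with np.errstate(invalid="ignore"):  # non-finite inputs surface downstream
        for comp in spec.components:
            a = comp.amplitude(t_sec)
            if a != 0.0:
                psi = psi + a * comp.shape.psi(x, y, metric)
    return psi


def velocity_field(spec: ScenarioSpec, grid: GridSpec) -> FlowField:
    """Evaluate the scenario on a grid: u = -dpsi/dy, v = +dpsi/dx.

    Central differences on the scenario's fixed local-metres metric, so the
    matching discrete divergence is identically zero. Land nodes are masked.
    """
    metric = spec.metric
    x1d, _ = metric.to_xy(grid.lons, grid.lat_center)
    _, y1d = metric.to_xy(grid.lon_center, grid.lats)
    lon2, lat2 = np.meshgrid(grid.lons, grid.lats)
    mask = make_landmask(grid, spec.coast)
    t_secs = grid.times_seconds
    nt = t_secs.size
    u = np.empty((nt, grid.nlat, grid.nlon))
    v = np.empty_like(u)
    for k, ts in enumerate(t_secs):
        psi = streamfunction(spec, lon2, lat2, ts)
        if not np.all(np.isfinite(psi)):
            raise ValueError("non-finite streamfunction")
        u[k] = -np.gradient(psi, y1d, axis=0)
        v[k] = np.gradient(psi, x1d, axis=1)
    u[:, mask] = np.nan
    v[:, mask] = np.nan
    return FlowField(lon=grid.lons, lat=grid.lats, times=grid.times, u=u, v=v, landmask=mask)


# -- the default study domain --------------------------------------------------

def default_grid(n_days: int = 20, start="2000-02-01", resolution_deg: float = 1 / 24) -> GridSpec:
    """~4 deg x 8 deg domain at 1/24 deg with daily snapshots.

    Finer than the 1/12 deg reanalysis it emulates, so mesoscale structures
    are resolved at desk scale while runtimes stay in minutes.
    """
    times = np.datetime64(start) + np.arange(n_days) * np.timedelta64(1, "D")
    return GridSpec(32.0, 36.0, resolution_deg, -28.0, -20.0, resolution_deg, times)


def default_coast() -> BightCoast:
    return BightCoast(coast_lon=32.8, bight_lat=-25.4, half_width_deg=0.8, indent_deg=0.6)


#: Alongshore complex bands, north to south (degrees latitude).
DEFAULT_BAND_LATITUDES = {"BA": -21.6, "INHM": -23.2, "INHC": -25.6, "MRC": -26.85}


def _coastal_waypoints(coast: BightCoast, offshore_km: float,
                       lat_from: float = -20.2, lat_to: float = -27.8, step: float = 0.2):
    lats = np.arange(lat_from, lat_to - 1e-9, -step)
    clon = coast.coastline_lon(lats)
    dlon = offshore_km * 1e3 / (EARTH_RADIUS_M * np.cos(np.deg2rad(lats)) * np.pi / 180.0)
    return tuple(zip(clon + dlon, lats))


def scenario_library(name: str, grid: GridSpec | None = None, times=None,
                     coast: BightCoast | None = None) -> ScenarioSpec:
    """Named flow regimes A/B/C of the emulated region (see module docs)."""
    grid = grid or default_grid()
    if times is not None:
        grid = GridSpec(grid.lon_min, grid.lon_max, grid.dlon,
                        grid.lat_min, grid.lat_max, grid.dlat, times)
    coast = coast or default_coast()
    name = str(name).upper()
    if name == "A":
        comps = (
            Component(GaussianJet(_coastal_waypoints(coast, 25.0), width_km=40.0,
                                  peak_speed=0.3)),
        )
    elif name == "B":
        comps = (
            Component(GaussianJet((
                (33.55, -20.2), (33.55, -24.6), (33.15, -25.7),
                (32.98, -26.6), (32.95, -27.8)), width_km=40.0, peak_speed=1.0)),
            Component(RankineVortex(lon=32.70, lat=-25.35, core_radius_km=40.0,
                                    peak_speed=0.45, rotation=-1)),  # lee cyclone
        )
    elif name == "C":
        comps = (
            Component(GaussianJet(_coastal_waypoints(coast, 30.0), width_km=45.0,
                                  peak_speed=1.6)),
            Component(RankineVortex(lon=34.8, lat=-21.3, core_radius_km=80.0,
                                    peak_speed=0.4, rotation=1)),  # offshore anticyclone
        )
    else:
        raise ValueError(f"unknown scenario '{name}'; expected A, B or C")
    return ScenarioSpec(components=comps, coast=coast,
                        lon_ref=grid.lon_center, lat_ref=grid.lat_center)


# -- synthetic reefs -----------------------------------------------------------

def generate_reefs(coast: BightCoast, n_per_complex: int = 4,
                   complexes=("BA", "INHM", "INHC", "MRC"), rng_seed: int = 0,
                   band_latitudes=None, offshore_km=(5.0, 20.0),
                   area_range_km2=(0.5, 3.0), lat_jitter: float = 0.15,
                   grid: GridSpec | None = None) -> ReefSet:
    """Synthetic reef polygons in alongshore bands, one band per complex.

    Small rotated squares (plan area drawn from ``area_range_km2``) are placed
    5-30 km offshore of the coastline at each band latitude; every vertex is
    checked to be in ocean (and inside the grid if one is given), with bounded
    retries. Deterministic for a fixed seed.
    """
    if n_per_complex < 1:
        raise ValueError("n_per_complex must be >= 1")
    band_latitudes = band_latitudes or DEFAULT_BAND_LATITUDES
    rng = np.random.default_rng(rng_seed)
    m_per_deg_lat = EARTH_RADIUS_M * np.pi / 180.0
    reefs = []
    for cx in complexes:
        lat0 = band_latitudes[cx]
        for k in range(n_per_complex):
            for _attempt in range(200):
                lat_c = lat0 + rng.uniform(-lat_jitter, lat_jitter)
                dist_m = rng.uniform(offshore_km[0], offshore_km[1]) * 1e3
                m_per_deg_lon = m_per_deg_lat * np.cos(np.deg2rad(lat_c))
                lon_c = float(coast.coastline_lon(lat_c)) + dist_m / m_per_deg_lon
                area = rng.uniform(*area_range_km2)
                half = math.sqrt(area) * 1e3 / 2.0
                theta = rng.uniform(0, np.pi / 2)
                ca, sa = math.cos(theta), math.sin(theta)
                corners = [(-half, -half), (half, -half), (half, half), (-half, half)]
                verts = [
                    (lon_c + (ca * dx - sa * dy) / m_per_deg_lon,
                     lat_c + (sa * dx + ca * dy) / m_per_deg_lat)
                    for dx, dy in corners
                ]
                vlon = np.array([p[0] for p in verts])
                vlat = np.array([p[1] for p in verts])
                ok = not np.any(coast.is_land(vlon, vlat))
                if ok and grid is not None:
                    ok = (vlon.min() > grid.lon_min and vlon.max() < grid.lon_max
                          and vlat.min() > grid.lat_min and vlat.max() < grid.lat_max)
                if ok:
                    poly = Polygon(verts)
                    if any(poly.intersects(r.polygon) for r in reefs):
                        continue  # keep generated reefs disjoint
                    reefs.append(ReefPolygon(f"{cx}-{k:02d}", cx, poly))
                    break
            else:
                raise RuntimeError(f"could not place reef {cx}-{k:02d} in ocean")
    return ReefSet(reefs)


def write_currents(field: FlowField, path) -> None:
    """Write a FlowField as CF-style NetCDF (round-trips bit-for-float)."""
    field.to_dataset().to_netcdf(path, encoding={
        "uo": {"dtype": "f8"}, "vo": {"dtype": "f8"}, "landmask": {"dtype": "i1"},
    })
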