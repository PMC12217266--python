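"""Regular lon/lat grids and the local Cartesian metric shared by the field modules.

Positions are geographic degrees east/north on a spherical Earth; velocities and
displacements are metres. A single equirectangular projection about a reference
point converts between the two, with the zonal scale frozen at the reference
latitude so that streamfunction differentiation and the discrete divergence
check share one metric exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = ["EARTH_RADIUS_M", "GridSpec", "LocalMetric"]


def _as_times(times) -> np.ndarray:
    t = np.asarray(times, dtype="datetime64[ns]")
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a non-empty 1-D sequence")
    return t


def times_to_seconds(times) -> np.ndarray:
    """Convert datetime64 values to float seconds since the Unix epoch."""
    t = np.asarray(times, dtype="datetime64[ns]")
    return t.astype("int64") / 1e9


def seconds_to_datetime64(seconds) -> np.ndarray:
    return (np.asarray(seconds) * 1e9).astype("int64").astype("datetime64[ns]")


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with an ordered, uniformly spaced time axis."""

    lon_min: float
    lon_max: float
    dlon: float
    lat_min: float
    lat_max: float
    dlat: float
    times: np.ndarray = field(default=None)  # datetime64[ns], daily by default

    def __post_init__(self):
        if self.dlon <= 0 or self.dlat <= 0:
            raise ValueError("grid spacing must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid bounds must be increasing")
        times = self.times
        if times is None:
            times = np.datetime64("2000-02-01") + np.arange(20) * np.timedelta64(1, "D")
        times = _as_times(times)
        if times.size > 1:
            steps = np.diff(times.astype("int64"))
            if not np.all(steps > 0):
                raise ValueError("times must be strictly increasing")
            if not np.all(steps == steps[0]):
                raise ValueError("times must be uniformly spaced")
        object.__setattr__(self, "times", times)
        if self.nlon < 2 or self.nlat < 2:
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.dlon)) + 1

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.dlat)) + 1

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.dlon * np.arange(self.nlon)

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + self.dlat * np.arange(self.nlat)

    @property
    def lon_center(self) -> float:
        return 0.5 * (self.lon_min + self.lon_max)

    @property
    def lat_center(self) -> float:
        return 0.5 * (self.lat_min + self.lat_max)

    @property
    def times_seconds(self) -> np.ndarray:
        return times_to_seconds(self.times)


@dataclass(frozen=True)
class LocalMetric:
    """Equirectangular projection about (lon_ref, lat_ref), in metres.

    The zonal metre-per-degree factor uses cos(lat_ref) everywhere, making the
    projection a fixed linear map degrees -> metres. Adequate for domains a few
    degrees across; the tracker itself converts displacements with the local
    cos(lat) instead (see :func:`reefdrift.tracker.meters_to_degrees`).
    """

    lon_ref: float
    lat_ref: float
    radius: float = EARTH_RADIUS_M

    @property
    def m_per_deg_lat(self) -> float:
        return self.radius * np.pi / 180.0

    @property
    def m_per_deg_lon(self) -> float:
        return self.radius * np.cos(np.deg2rad(self.lat_ref)) * np.pi / 180.0

    def to_xy(self, lon, lat):
        x = (np.asarray(lon, dtype=float) - self.lon_ref) * self.m_per_deg_lon
        y = (np.asarray(lat, dtype=float) - self.lat_ref) * self.m_per_deg_lat
        return x, y

    def to_lonlat(self, x, y):
        lon = self.lon_ref + np.asarray(x, dtype=float) / self.m_per_deg_lon
        lat = self.lat_ref + np.asarray(y, dtype=float) / self.m_per_deg_lat
        return lon, lat
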