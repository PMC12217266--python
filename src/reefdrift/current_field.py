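"""Gridded surface-current fields: NetCDF reading and continuous sampling.

A :class:`FlowField` holds daily-mean surface velocity snapshots on a regular
lon/lat grid plus a static landmask. The tracker samples it bilinearly in
space and linearly in time; near the coast, land nodes contribute zero
velocity and the bilinear weights are renormalised over the ocean nodes, which
avoids spurious onshore drift from masked values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

from .grid import times_to_seconds

__all__ = ["FlowField", "AnalyticField", "read_currents", "sample_velocity", "is_ocean"]

# accepted spellings of metres per second
_MS_UNITS = {"m s-1", "m/s", "m s**-1", "ms-1", "meter second-1", "m.s-1", "meters s-1"}

# variable-name dialects tried in order when no explicit map is given
_DEFAULT_VAR_MAP = {
    "u": ("uo", "u", "water_u", "eastward_velocity", "ugos"),
    "v": ("vo", "v", "water_v", "northward_velocity", "vgos"),
    "lon": ("longitude", "lon", "x"),
    "lat": ("latitude", "lat", "y"),
    "time": ("time",),
    "landmask": ("landmask", "mask", "land_binary_mask"),
}
_STD_NAMES = {
    "u": "eastward_sea_water_velocity",
    "v": "northward_sea_water_velocity",
}


class OutsideDomainError(ValueError):
    """A query fell outside the field's spatial hull or time span."""


@dataclass
class FlowField:
    """Surface velocity time series on a regular lon/lat grid.

    u, v have shape (time, lat, lon) in m/s with NaN over land; landmask is
    (lat, lon), True on land.
    """

    lon: np.ndarray
    lat: np.ndarray
    times: np.ndarray  # datetime64[ns]
    u: np.ndarray
    v: np.ndarray
    landmask: np.ndarray
    _u0: np.ndarray = dc_field(init=False, repr=False)
    _v0: np.ndarray = dc_field(init=False, repr=False)
    _wet: np.ndarray = dc_field(init=False, repr=False)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.landmask = np.asarray(self.landmask, dtype=bool)
        nt, nlat, nlon = self.times.size, self.lat.size, self.lon.size
        if self.u.shape != (nt, nlat, nlon) or self.v.shape != (nt, nlat, nlon):
            raise ValueError("u/v shapes do not match (time, lat, lon) axes")
        if self.landmask.shape != (nlat, nlon):
            raise ValueError("landmask shape does not match (lat, lon) axes")
        for name, arr in (("longitude", self.lon), ("latitude", self.lat)):
            if arr.size < 2 or not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} coordinate must be ascending with >= 2 nodes")
        if not np.all(np.diff(self.times.astype("int64")) > 0):
            raise ValueError("time coordinate must be strictly increasing")
        ocean = ~self.landmask
        if not (np.all(np.isfinite(self.u[:, ocean])) and np.all(np.isfinite(self.v[:, ocean]))):
            raise ValueError("non-finite velocity at ocean nodes")
        self._u0 = np.where(np.isfinite(self.u), self.u, 0.0)
        self._v0 = np.where(np.isfinite(self.v), self.v, 0.0)
        self._wet = ocean.astype(float)

    # -- geometry -----------------------------------------------------------
    @property
    def times_seconds(self) -> np.ndarray:
        return times_to_seconds(self.times)

    @property
    def bounds(self):
        return (self.lon[0], self.lon[-1], self.lat[0], self.lat[-1])

    def in_domain(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )

    def in_time_span(self, t_seconds) -> bool:
        ts = self.times_seconds
        return bool(ts[0] <= t_seconds <= ts[-1])

    # -- queries ------------------------------------------------------------
    def is_ocean(self, lon, lat):
        """Nearest-node ocean test. Returns (ocean, in_domain) boolean arrays."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = self.in_domain(lon, lat)
        j = np.clip(np.rint((lon - self.lon[0]) / (self.lon[1] - self.lon[0])), 0, self.lon.size - 1).astype(int)
        i = np.clip(np.rint((lat - self.lat[0]) / (self.lat[1] - self.lat[0])), 0, self.lat.size - 1).astype(int)
        ocean = ~self.landmask[i, j] & inside
        return ocean, inside

    def sample_velocity(self, lon, lat, t_seconds):
        """Sample (u, v) in m/s at positions (lon, lat) and one instant.

        Bilinear in space, linear in time between the two bracketing
        snapshots; land nodes contribute zero velocity with their bilinear
        weight renormalised over the ocean nodes of the cell. Returns
        (u, v, in_domain); out-of-domain queries get u = v = 0 and
        in_domain = False (the tracker treats that as a domain exit).
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ts = self.times_seconds
        if not self.in_time_span(t_seconds):
            z = np.zeros_like(lon)
            return z, z.copy(), np.zeros(lon.shape, dtype=bool)
        inside = self.in_domain(lon, lat)

        dlon = self.lon[1] - self.lon[0]
        dlat = self.lat[1] - self.lat[0]
        fx = np.clip((lon - self.lon[0]) / dlon, 0.0, self.lon.size - 1.0)
        fy = np.clip((lat - self.lat[0]) / dlat, 0.0, self.lat.size - 1.0)
        j0 = np.minimum(fx.astype(int), self.lon.size - 2)
        i0 = np.minimum(fy.astype(int), self.lat.size - 2)
        ax = fx - j0
        ay = fy - i0

        # time bracket
        k0 = min(int(np.searchsorted(ts, t_seconds, side="right") - 1), ts.size - 2) if ts.size > 1 else 0
        k0 = max(k0, 0)
        if ts.size == 1:
            tau = 0.0
            k1 = 0
        else:
            k1 = k0 + 1
            tau = (t_seconds - ts[k0]) / (ts[k1] - ts[k0])

        w00 = (1 - ax) * (1 - ay)
        w01 = ax * (1 - ay)
        w10 = (1 - ax) * ay
        w11 = ax * ay
        m00 = self._wet[i0, j0]
        m01 = self._wet[i0, j0 + 1]
        m10 = self._wet[i0 + 1, j0]
        m11 = self._wet[i0 + 1, j0 + 1]
        wsum = w00 * m00 + w01 * m01 + w10 * m10 + w11 * m11

        def _interp(a):
            v0 = (
                w00 * m00 * a[k0, i0, j0] + w01 * m01 * a[k0, i0, j0 + 1]
                + w10 * m10 * a[k0, i0 + 1, j0] + w11 * m11 * a[k0, i0 + 1, j0 + 1]
            )
            v1 = (
                w00 * m00 * a[k1, i0, j0] + w01 * m01 * a[k1, i0, j0 + 1]
                + w10 * m10 * a[k1, i0 + 1, j0] + w11 * m11 * a[k1, i0 + 1, j0 + 1]
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                out = ((1 - tau) * v0 + tau * v1) / wsum
            return np.where(wsum > 0, out, 0.0)

        u = np.where(inside, _interp(self._u0), 0.0)
        v = np.where(inside, _interp(self._v0), 0.0)
        return u, v, inside

    # -- I/O ----------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "uo": (("time", "latitude", "longitude"), self.u,
                       {"units": "m s-1", "standard_name": _STD_NAMES["u"],
                        "long_name": "eastward surface velocity"}),
                "vo": (("time", "latitude", "longitude"), self.v,
                       {"units": "m s-1", "standard_name": _STD_NAMES["v"],
                        "long_name": "northward surface velocity"}),
                "landmask": (("latitude", "longitude"), self.landmask.astype("i1"),
                             {"long_name": "land binary mask", "flag_values": "0, 1",
                              "flag_meanings": "ocean land"}),
            },
            coords={
                "time": ("time", self.times, {"standard_name": "time"}),
                "latitude": ("latitude", self.lat,
                             {"units": "degrees_north", "standard_name": "latitude"}),
                "longitude": ("longitude", self.lon,
                              {"units": "degrees_east", "standard_name": "longitude"}),
            },
            attrs={"Conventions": "CF-1.8", "source": "reefdrift synthetic surface currents"},
        )
        return ds


class AnalyticField:
    """A velocity field defined by closed-form functions, for verification runs.

    ``u_fn(lon, lat, t_seconds)`` and ``v_fn`` return m/s. Everything inside
    ``bounds`` (lon_min, lon_max, lat_min, lat_max; None = unbounded) is ocean.
    Useful as an exact oracle for the tracker: no grid, no interpolation.
    """

    def __init__(self, u_fn, v_fn, bounds=None):
        self.u_fn = u_fn
        self.v_fn = v_fn
        self.bounds = bounds

    def in_domain(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if self.bounds is None:
            return np.ones(np.broadcast(lon, lat).shape, dtype=bool)
        x0, x1, y0, y1 = self.bounds
        return (lon >= x0) & (lon <= x1) & (lat >= y0) & (lat <= y1)

    def in_time_span(self, t_seconds) -> bool:
        return True

    def is_ocean(self, lon, lat):
        inside = self.in_domain(lon, lat)
        return inside.copy(), inside

    def sample_velocity(self, lon, lat, t_seconds):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = self.in_domain(lon, lat)
        u = np.where(inside, np.asarray(self.u_fn(lon, lat, t_seconds), dtype=float), 0.0)
        v = np.where(inside, np.asarray(self.v_fn(lon, lat, t_seconds), dtype=float), 0.0)
        return u, v, inside


def _find_name(ds: xr.Dataset, role: str, var_map) -> str:
    candidates = (var_map or {}).get(role, _DEFAULT_VAR_MAP[role])
    if isinstance(candidates, str):
        candidates = (candidates,)
    pool = list(ds.variables)
    for name in candidates:
        if name in pool:
            return name
    # fall back to CF standard_name attributes for velocities
    if role in _STD_NAMES:
        for name in ds.data_vars:
            if ds[name].attrs.get("standard_name") == _STD_NAMES[role]:
                return name
    if role == "landmask":
        return ""
    raise ValueError(
        f"required variable for '{role}' not found; tried {tuple(candidates)}"
    )


def read_currents(path, var_map=None) -> FlowField:
    """Read a CF-style NetCDF currents file into a validated FlowField.

    Accepts common variable-name dialects (override with ``var_map``), requires
    velocities in m/s, normalises a descending latitude axis to ascending, and
    converts missing values to the landmask.
    """
    with xr.open_dataset(path, decode_times=True) as ds:
        ds = ds.load()
    u_name = _find_name(ds, "u", var_map)
    v_name = _find_name(ds, "v", var_map)
    lon_name = _find_name(ds, "lon", var_map)
    lat_name = _find_name(ds, "lat", var_map)
    time_name = _find_name(ds, "time", var_map)
    mask_name = _find_name(ds, "landmask", var_map)

    for name in (u_name, v_name):
        units = str(ds[name].attrs.get("units", "m s-1")).strip().lower()
        if units not in _MS_UNITS:
            raise ValueError(f"variable '{name}' has units '{units}', expected m/s")

    lat = ds[lat_name].values
    if lat.size >= 2 and lat[0] > lat[-1]:
        ds = ds.isel({lat_name: slice(None, None, -1)})
        lat = ds[lat_name].values
    lon = ds[lon_name].values
    for cname, cvals in ((lon_name, lon), (lat_name, lat)):
        if not np.all(np.diff(cvals) > 0):
            raise ValueError(f"coordinate '{cname}' is not monotone ascending")

    u = ds[u_name].transpose(time_name, lat_name, lon_name).values.astype(float)
    v = ds[v_name].transpose(time_name, lat_name, lon_name).values.astype(float)
    if mask_name:
        landmask = ds[mask_name].transpose(lat_name, lon_name).values.astype(bool)
    else:
        landmask = ~np.all(np.isfinite(u) & np.isfinite(v), axis=0)
    u = np.where(landmask[None, :, :], np.nan, u)
    v = np.where(landmask[None, :, :], np.nan, v)
    return FlowField(lon=lon, lat=lat, times=ds[time_name].values, u=u, v=v, landmask=landmask)


# thin functional wrappers matching the module surface -----------------------

def sample_velocity(field: FlowField, lon, lat, t_seconds):
    return field.sample_velocity(lon, lat, t_seconds)


def is_ocean(field: FlowField, lon, lat):
    return field.is_ocean(lon, lat)
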