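"""Lagrangian particle tracking: RK2 advection plus random-walk diffusion.

Virtual larvae are advanced with the explicit-midpoint (second-order
Runge-Kutta) scheme at a 30-minute internal step, with an additive Gaussian
random walk of constant horizontal diffusivity K (default 933 m^2/s,
per-axis displacement std sqrt(2 K dt)) representing sub-grid variability.
Transport is surface-only: no vertical motion, windage, mortality or swimming.

Coastline semantics: a particle pushed onto land is held at its last ocean
position with status STRANDED, keeps ageing, and may re-enter the ocean if the
currents change. Particles leaving the grid hull freeze as LEFT_DOMAIN; after
``max_age_days`` (the pelagic larval duration) a particle freezes as INACTIVE.
Both of those states are absorbing; ACTIVE and STRANDED interconvert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
import xarray as xr

from .grid import EARTH_RADIUS_M, seconds_to_datetime64, times_to_seconds

__all__ = [
    "Status", "TrackerConfig", "ReleaseBatch", "TrajectorySet",
    "meters_to_degrees", "rk2_step", "diffusion_step", "advance", "run",
]


class Status(IntEnum):
    ACTIVE = 0
    STRANDED = 1
    INACTIVE = 2
    LEFT_DOMAIN = 3


@dataclass(frozen=True)
class TrackerConfig:
    dt: float = 1800.0                 # internal step, seconds
    diffusivity: float = 933.0         # horizontal random-walk K, m^2/s
    earth_radius: float = EARTH_RADIUS_M
    max_age_days: float = 10.0         # pelagic larval duration
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.max_age_days <= 0:
            raise ValueError("max_age_days must be > 0")

    @property
    def max_age_seconds(self) -> float:
        return self.max_age_days * 86400.0

    @property
    def n_steps(self) -> int:
        return int(round(self.max_age_seconds / self.dt))


def meters_to_degrees(dx_m, dy_m, lat, radius: float = EARTH_RADIUS_M):
    """Convert metric displacements to (dlon, dlat) at the given latitude."""
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) >= 89.0):
        raise ValueError("latitude too close to the pole for the metric conversion")
    dlat = np.asarray(dy_m, dtype=float) / radius * (180.0 / np.pi)
    dlon = np.asarray(dx_m, dtype=float) / (radius * np.cos(np.deg2rad(lat))) * (180.0 / np.pi)
    return dlon, dlat


def rk2_step(field, lon, lat, t_seconds, dt, radius: float = EARTH_RADIUS_M):
    """Explicit-midpoint advection step.

    Half-step with v(x, t), full step with v(x_half, t + dt/2); displacements
    are metres converted to degrees at the latitude where they apply. Returns
    (lon_new, lat_new, sampled_ok); a failed velocity sample (outside the
    domain or time span) flags the particle for LEFT_DOMAIN.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    u1, v1, ok1 = field.sample_velocity(lon, lat, t_seconds)
    dlon1, dlat1 = meters_to_degrees(u1 * dt / 2.0, v1 * dt / 2.0, lat, radius)
    lon_h, lat_h = lon + dlon1, lat + dlat1
    u2, v2, ok2 = field.sample_velocity(lon_h, lat_h, t_seconds + dt / 2.0)
    dlon2, dlat2 = meters_to_degrees(u2 * dt, v2 * dt, lat_h, radius)
    return lon + dlon2, lat + dlat2, ok1 & ok2


def diffusion_step(K: float, dt: float, rng: np.random.Generator, n: int = 1):
    """Random-walk displacements: independent N(0, sqrt(2 K dt)) metres per axis."""
    if K < 0:
        raise ValueError("diffusivity must be >= 0")
    std = np.sqrt(2.0 * K * dt)
    draws = rng.standard_normal((n, 2)) * std
    return draws[:, 0], draws[:, 1]


@dataclass
class ParticleArrays:
    """State of one release batch (vectorised over particles)."""
    lon: np.ndarray
    lat: np.ndarray
    status: np.ndarray  # int8 Status codes
    age: np.ndarray     # seconds

    @classmethod
    def release(cls, lon, lat):
        lon = np.asarray(lon, dtype=float).copy()
        lat = np.asarray(lat, dtype=float).copy()
        return cls(lon, lat, np.full(lon.shape, Status.ACTIVE, dtype=np.int8),
                   np.zeros(lon.shape))


def advance(field, particles: ParticleArrays, t_seconds: float,
            cfg: TrackerConfig, rng: np.random.Generator) -> ParticleArrays:
    """Advance all ACTIVE/STRANDED particles by one step; apply the status machine."""
    moving = (particles.status == Status.ACTIVE) | (particles.status == Status.STRANDED)
    n = particles.lon.size
    # draws are consumed for every particle each step so streams stay aligned
    dx_m, dy_m = diffusion_step(cfg.diffusivity, cfg.dt, rng, n)
    if not moving.any():
        return particles
    lon_t, lat_t, ok = rk2_step(field, particles.lon, particles.lat, t_seconds,
                                cfg.dt, cfg.earth_radius)
    dlon, dlat = meters_to_degrees(dx_m, dy_m, particles.lat, cfg.earth_radius)
    lon_t = lon_t + dlon
    lat_t = lat_t + dlat
    ocean, inside = field.is_ocean(lon_t, lat_t)

    left = moving & (~ok | ~inside)
    to_ocean = moving & ~left & ocean
    to_shore = moving & ~left & ~ocean

    particles.lon[to_ocean] = lon_t[to_ocean]
    particles.lat[to_ocean] = lat_t[to_ocean]
    particles.status[to_ocean] = Status.ACTIVE
    particles.status[to_shore] = Status.STRANDED  # held at last ocean position
    particles.status[left] = Status.LEFT_DOMAIN

    particles.age[moving] += cfg.dt
    expired = (particles.age >= cfg.max_age_seconds) & (
        (particles.status == Status.ACTIVE) | (particles.status == Status.STRANDED)
    )
    particles.status[expired] = Status.INACTIVE
    return particles


@dataclass(frozen=True)
class ReleaseBatch:
    lon: np.ndarray
    lat: np.ndarray
    source_reef: np.ndarray  # one reef id per particle (object/str array)
    time: np.datetime64

    def __post_init__(self):
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        src = np.asarray(self.source_reef, dtype=object)
        if src.ndim == 0:
            src = np.full(self.lon.shape, src[()], dtype=object)
        object.__setattr__(self, "source_reef", src)
        object.__setattr__(self, "time", np.datetime64(self.time, "ns"))
        if not (self.lon.shape == self.lat.shape == self.source_reef.shape):
            raise ValueError("release arrays must share one shape")


class TrajectorySet:
    """Per-particle position/status series at tracker resolution.

    Arrays have shape (n_particles, n_records); record r of particle p is at
    time release_time[p] + r * dt. No particle is ever removed — counts are
    conserved and state changes are visible as status codes.
    """

    def __init__(self, lon, lat, status, release_times, source_reef, dt,
                 particle_id=None, metadata=None):
        self.lon = np.asarray(lon, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        self.status = np.asarray(status, dtype=np.int8)
        self.release_times = np.asarray(release_times, dtype="datetime64[ns]")
        self.source_reef = np.asarray(source_reef, dtype=object)
        self.dt = float(dt)
        n = self.lon.shape[0]
        self.particle_id = (np.arange(n) if particle_id is None
                            else np.asarray(particle_id))
        self.metadata = metadata or {}
        if not (self.lon.shape == self.lat.shape == self.status.shape):
            raise ValueError("trajectory arrays must share one shape")

    @property
    def n_particles(self) -> int:
        return self.lon.shape[0]

    @property
    def n_records(self) -> int:
        return self.lon.shape[1]

    @property
    def age_seconds(self) -> np.ndarray:
        """Age of each record column, seconds since release."""
        return self.dt * np.arange(self.n_records)

    def record_times_seconds(self) -> np.ndarray:
        """(n_particles, n_records) epoch seconds of every record."""
        return times_to_seconds(self.release_times)[:, None] + self.age_seconds[None, :]

    def to_dataframe(self) -> pd.DataFrame:
        n, m = self.lon.shape
        return pd.DataFrame({
            "particle_id": np.repeat(self.particle_id, m),
            "source_reef": np.repeat(self.source_reef, m),
            "time": seconds_to_datetime64(self.record_times_seconds().ravel()),
            "lon": self.lon.ravel(),
            "lat": self.lat.ravel(),
            "status": self.status.ravel(),
        })

    def to_dataset(self) -> xr.Dataset:
        """CF-style trajectory dataset (dims trajectory x obs)."""
        return xr.Dataset(
            {
                "lon": (("trajectory", "obs"), self.lon,
                        {"units": "degrees_east", "standard_name": "longitude"}),
                "lat": (("trajectory", "obs"), self.lat,
                        {"units": "degrees_north", "standard_name": "latitude"}),
                "status": (("trajectory", "obs"), self.status,
                           {"flag_values": "0, 1, 2, 3",
                            "flag_meanings": "active stranded inactive left_domain"}),
                "time": (("trajectory", "obs"),
                         seconds_to_datetime64(self.record_times_seconds())),
                "release_time": (("trajectory",), self.release_times),
                "source_reef": (("trajectory",), self.source_reef.astype(str)),
            },
            coords={"trajectory": self.particle_id},
            attrs={"featureType": "trajectory", "internal_dt_seconds": self.dt,
                   **{k: str(v) for k, v in self.metadata.items()}},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path) -> "TrajectorySet":
        with xr.open_dataset(path) as ds:
            ds = ds.load()
        return cls(
            lon=ds["lon"].values, lat=ds["lat"].values, status=ds["status"].values,
            release_times=ds["release_time"].values,
            source_reef=ds["source_reef"].values.astype(object),
            dt=float(ds.attrs["internal_dt_seconds"]),
            particle_id=ds["trajectory"].values,
        )


def run(field, releases, cfg: TrackerConfig) -> TrajectorySet:
    """Track every release batch from its release time through the larval duration.

    Each batch gets its own counter-based (Philox) RNG stream spawned from the
    master seed, so results are reproducible and independent of batch order.
    Particle count is conserved: particles are re-flagged, never dropped.
    """
    releases = list(releases)
    if not releases:
        raise ValueError("empty release list")
    n_steps = cfg.n_steps
    field_end = None
    if hasattr(field, "times_seconds"):
        field_end = field.times_seconds[-1]
    streams = np.random.SeedSequence(cfg.seed).spawn(len(releases))

    lon_all, lat_all, st_all, rel_all, src_all = [], [], [], [], []
    for batch, ss in zip(releases, streams):
        rng = np.random.Generator(np.random.Philox(ss))
        t0 = float(times_to_seconds(batch.time))
        steps = n_steps
        if field_end is not None and t0 + n_steps * cfg.dt > field_end:
            steps = max(int((field_end - t0) // cfg.dt), 0)
            warnings.warn(
                f"release at {batch.time} truncated to {steps} steps: "
                "field time span ends before the full larval duration")
        n = batch.lon.size
        state = ParticleArrays.release(batch.lon, batch.lat)
        lon = np.empty((n, n_steps + 1))
        lat = np.empty((n, n_steps + 1))
        status = np.empty((n, n_steps + 1), dtype=np.int8)
        lon[:, 0], lat[:, 0], status[:, 0] = state.lon, state.lat, state.status
        for k in range(1, n_steps + 1):
            if k <= steps:
                state = advance(field, state, t0 + (k - 1) * cfg.dt, cfg, rng)
            lon[:, k], lat[:, k], status[:, k] = state.lon, state.lat, state.status
        lon_all.append(lon)
        lat_all.append(lat)
        st_all.append(status)
        rel_all.append(np.full(n, batch.time, dtype="datetime64[ns]"))
        src_all.append(batch.source_reef)

    return TrajectorySet(
        lon=np.concatenate(lon_all), lat=np.concatenate(lat_all),
        status=np.concatenate(st_all), release_times=np.concatenate(rel_all),
        source_reef=np.concatenate(src_all), dt=cfg.dt,
        metadata={"seed": cfg.seed, "diffusivity": cfg.diffusivity,
                  "max_age_days": cfg.max_age_days, "n_releases": len(releases)},
    )
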