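"""Larval biology windows, connectivity events, and the analytics products.

A larva can settle only during its competency window: after the precompetency
developmental period (default 4 days) and before the end of the pelagic larval
duration (default 10 days), leaving a six-day settlement window. A
connectivity event is the intersection of a competent, ACTIVE larva with a
reef polygon; a larva may connect to several destinations in its lifespan but
counts once per (particle, destination) pair. Stranded records are not
containment-tested by default (reefs are subtidal).

Products mirror the standard source-sink analyses: a reef-by-reef connectivity
matrix (diagonal = self-recruitment), travel-time mean/std matrices, complex-
level block sums, and temporal contribution tables to one destination complex
with intra-complex exchanges omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .reef_geometry import ReefSet
from .tracker import Status, TrajectorySet

__all__ = [
    "BiologyConfig", "ConnectivityEvent", "ConnectivityMatrix", "TravelTimeStats",
    "detect_events", "build_matrix", "travel_time_stats", "aggregate_complexes",
    "temporal_contributions", "build_release_schedule", "EVENT_COLUMNS",
]

EVENT_COLUMNS = ["particle_id", "source_reef", "dest_reef",
                 "release_time", "arrival_time", "travel_time_h"]


@dataclass(frozen=True)
class BiologyConfig:
    pld_days: float = 10.0
    precompetency_days: float = 4.0

    def __post_init__(self):
        if not 0 <= self.precompetency_days < self.pld_days:
            raise ValueError("need 0 <= precompetency < PLD")

    @property
    def settlement_window_days(self) -> float:
        return self.pld_days - self.precompetency_days


@dataclass(frozen=True)
class ConnectivityEvent:
    particle_id: int
    source_reef: str
    dest_reef: str
    release_time: np.datetime64
    arrival_time: np.datetime64
    travel_time_h: float


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "particle_id": pd.Series(dtype=int),
        "source_reef": pd.Series(dtype=object),
        "dest_reef": pd.Series(dtype=object),
        "release_time": pd.Series(dtype="datetime64[ns]"),
        "arrival_time": pd.Series(dtype="datetime64[ns]"),
        "travel_time_h": pd.Series(dtype=float),
    })


def detect_events(trajectories: TrajectorySet, reefs: ReefSet,
                  bio: BiologyConfig = BiologyConfig(),
                  test_stranded: bool = False) -> pd.DataFrame:
    """Scan trajectories against reef polygons; one event per (particle, reef).

    Records are containment-tested when status is ACTIVE (optionally also
    STRANDED), and precompetency <= age <= PLD. The first containment per
    (particle, destination) emits one event with travel_time equal to the age
    at that record; the particle is not removed and may connect to further
    reefs. Self-events (destination = source reef) are recorded.
    """
    if trajectories.dt > 1800.0:
        import warnings
        warnings.warn("trajectory step coarser than 30 min: crossings may be missed")
    age = trajectories.age_seconds
    in_window = (age >= bio.precompetency_days * 86400.0) & (age <= bio.pld_days * 86400.0)
    statuses = (Status.ACTIVE, Status.STRANDED) if test_stranded else (Status.ACTIVE,)
    ok = np.isin(trajectories.status, statuses) & in_window[None, :]
    p_idx, r_idx = np.nonzero(ok)  # ordered by particle then record
    if p_idx.size == 0:
        return empty_events()
    reef_at = reefs.locate_many(trajectories.lon[p_idx, r_idx],
                                trajectories.lat[p_idx, r_idx])
    hit = reef_at >= 0
    p_idx, r_idx, reef_at = p_idx[hit], r_idx[hit], reef_at[hit]
    if p_idx.size == 0:
        return empty_events()
    # first record per (particle, reef): rows are already sorted by record
    key = p_idx.astype(np.int64) * len(reefs) + reef_at
    _, first = np.unique(key, return_index=True)
    p_idx, r_idx, reef_at = p_idx[first], r_idx[first], reef_at[first]

    travel_s = age[r_idx]
    release = trajectories.release_times[p_idx]
    reef_ids = np.asarray(reefs.reef_ids, dtype=object)
    ev = pd.DataFrame({
        "particle_id": trajectories.particle_id[p_idx],
        "source_reef": trajectories.source_reef[p_idx],
        "dest_reef": reef_ids[reef_at],
        "release_time": release,
        "arrival_time": release + (travel_s * 1e9).astype("timedelta64[ns]"),
        "travel_time_h": travel_s / 3600.0,
    })
    return ev.sort_values(["particle_id", "travel_time_h"], kind="stable",
                          ignore_index=True)


@dataclass
class ConnectivityMatrix:
    """counts[i, j] = distinct larvae released at source reef i that reached j."""
    counts: pd.DataFrame          # index/columns = reef ids, north to south
    released: pd.Series           # particles released per source reef

    def __post_init__(self):
        bad = self.counts.max(axis=1) > self.released.reindex(self.counts.index)
        if bad.any():
            raise ValueError("counts exceed released particles for some source reef")

    @property
    def self_recruitment(self) -> pd.Series:
        return pd.Series(np.diag(self.counts.values), index=self.counts.index,
                         name="self_recruitment")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def build_matrix(events: pd.DataFrame, reefs: ReefSet,
                 released_counts) -> ConnectivityMatrix:
    """Accumulate events into the reef-by-reef connectivity matrix."""
    order = reefs.reef_ids
    known = set(order)
    for col in ("source_reef", "dest_reef"):
        unknown = set(events[col]) - known
        if unknown:
            raise ValueError(f"event references unknown reef(s): {sorted(unknown)}")
    released = pd.Series(released_counts, dtype=float).reindex(order).fillna(0)
    tab = pd.crosstab(events["source_reef"], events["dest_reef"])
    counts = tab.reindex(index=order, columns=order, fill_value=0).astype(int)
    counts.index.name = "source_reef"
    counts.columns.name = "dest_reef"
    return ConnectivityMatrix(counts=counts, released=released)


@dataclass
class TravelTimeStats:
    """Per reef pair: mean and population std of travel time (hours), and n.

    Cells are NaN exactly where no connections were observed.
    """
    mean: pd.DataFrame
    std: pd.DataFrame
    n: pd.DataFrame


def travel_time_stats(events: pd.DataFrame, reefs: ReefSet) -> TravelTimeStats:
    order = reefs.reef_ids
    g = events.groupby(["source_reef", "dest_reef"])["travel_time_h"]
    mean = g.mean().unstack().reindex(index=order, columns=order)
    std = g.std(ddof=0).unstack().reindex(index=order, columns=order)
    n = g.size().unstack().reindex(index=order, columns=order).fillna(0).astype(int)
    std = std.where(n != 1, 0.0).where(n > 0)  # population std: 0 for n=1, NaN for n=0
    return TravelTimeStats(mean=mean, std=std, n=n)


def aggregate_complexes(matrix, complex_map: dict) -> pd.DataFrame:
    """Block-sum a reef-level counts matrix by (source complex, dest complex)."""
    counts = matrix.counts if isinstance(matrix, ConnectivityMatrix) else matrix
    unmapped = [r for r in counts.index if r not in complex_map]
    if unmapped:
        raise ValueError(f"reefs not mapped to a complex: {unmapped}")
    # complex order follows the first appearance in (north-to-south) reef order
    order = list(dict.fromkeys(complex_map[r] for r in counts.index))
    src_keys = np.asarray([complex_map[r] for r in counts.index], dtype=object)
    dst_keys = np.asarray([complex_map[c] for c in counts.columns], dtype=object)
    src = counts.groupby(src_keys, sort=False).sum()
    both = src.T.groupby(dst_keys, sort=False).sum().T
    out = both.reindex(index=order, columns=order, fill_value=0)
    out.index.name = "source_complex"
    out.columns.name = "dest_complex"
    return out


def temporal_contributions(events: pd.DataFrame, destination_complex: str,
                           complex_map: dict, group_by: str = "year") -> pd.DataFrame:
    """Larvae received by one complex per year (or per release), by source complex.

    Events whose source complex equals the destination complex are intentionally
    omitted, so the table shows external supply only. Tidy output with columns
    (group, source_complex, count).
    """
    if group_by not in ("year", "release"):
        raise ValueError("group_by must be 'year' or 'release'")
    known = set(complex_map.values())
    if destination_complex not in known:
        raise ValueError(f"unknown complex '{destination_complex}'")
    ev = events.copy()
    ev["source_complex"] = ev["source_reef"].map(complex_map)
    ev["dest_complex"] = ev["dest_reef"].map(complex_map)
    if ev["source_complex"].isna().any() or ev["dest_complex"].isna().any():
        raise ValueError("event references a reef without a complex mapping")
    ev = ev[(ev["dest_complex"] == destination_complex)
            & (ev["source_complex"] != destination_complex)]
    if ev.empty:
        return pd.DataFrame(columns=["group", "source_complex", "count"])
    rt = pd.to_datetime(ev["release_time"])
    ev = ev.assign(group=rt.dt.year if group_by == "year" else rt)
    out = (ev.groupby(["group", "source_complex"]).size()
             .rename("count").reset_index())
    return out


def build_release_schedule(years, start_month: int = 2, start_day: int = 1,
                           months=(2, 3), interval_hours: float = 48.0):
    """Release datetimes: every 2 days through Feb-Mar, at midnight, per year.

    Anchored at Feb 1 00:00 with a fixed 48-hour stride while the date stays
    within the spawning months; a non-leap year yields 30 releases (Feb 1 ..
    Mar 31), a leap year 30 releases ending Mar 30.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    out = []
    step = timedelta(hours=interval_hours)
    for year in years:
        t = datetime(int(year), start_month, start_day)
        while t.month in months:
            out.append(np.datetime64(t, "ns"))
            t = t + step
    return out
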