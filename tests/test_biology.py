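"""Biology windows, event detection, matrices and temporal aggregation."""

import numpy as np
import pandas as pd
import pytest

import reefdrift as rd

from .conftest import box_polygon

T0 = np.datetime64("2000-02-01T00:00:00", "ns")
DT = 1800.0
N_REC = 481  # 10 days at 30-minute steps


def reef_pair():
    return rd.ReefSet([
        rd.ReefPolygon("N", "X", box_polygon(33.0, -24.0, 2.0, 2.0)),
        rd.ReefPolygon("S", "Y", box_polygon(33.0, -26.0, 2.0, 2.0)),
    ])


def make_traj(position_plan, source="N", n_records=N_REC):
    """One-particle trajectory from a list of (start_age_days, end_age_days, lon, lat).

    Ages outside every plan interval sit at a far-off ocean point.
    """
    lon = np.full((1, n_records), 30.0)
    lat = np.full((1, n_records), -25.0)
    ages = DT * np.arange(n_records) / 86400.0
    for a0, a1, x, y in position_plan:
        sel = (ages >= a0) & (ages <= a1)
        lon[0, sel] = x
        lat[0, sel] = y
    status = np.full((1, n_records), rd.Status.ACTIVE, dtype=np.int8)
    status[0, -1] = rd.Status.INACTIVE
    return rd.TrajectorySet(lon=lon, lat=lat, status=status,
                            release_times=np.array([T0]),
                            source_reef=np.array([source], dtype=object), dt=DT)


class TestBiologyConfig:
    def test_settlement_window(self):
        assert rd.BiologyConfig().settlement_window_days == 6.0

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            rd.BiologyConfig(pld_days=4.0, precompetency_days=4.0)


class TestDetectEvents:
    def test_precompetent_crossing_yields_no_event(self):
        traj = make_traj([(3.0, 3.5, 33.0, -26.0)])  # on reef S only before day 4
        events = rd.detect_events(traj, reef_pair())
        assert events.empty

    def test_competent_arrival_at_five_days(self):
        traj = make_traj([(5.0, 5.5, 33.0, -26.0)])
        events = rd.detect_events(traj, reef_pair())
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev.dest_reef == "S" and ev.travel_time_h == 120.0
        assert ev.arrival_time == T0 + np.timedelta64(5 * 86400, "s")

    def test_multiple_destinations_but_once_per_reef(self):
        traj = make_traj([(4.5, 5.0, 33.0, -26.0),   # S
                          (6.0, 6.5, 33.0, -24.0),   # N (self-complex reef)
                          (8.0, 8.5, 33.0, -26.0)])  # re-entering S: no new event
        reefs = reef_pair()
        events = rd.detect_events(traj, reefs)
        assert list(events.dest_reef) == ["S", "N"]
        # brute-force oracle: re-scan every record against every polygon
        import shapely
        expected = {}
        ages = DT * np.arange(N_REC)
        for r in range(N_REC):
            if not (4 * 86400 <= ages[r] <= 10 * 86400):
                continue
            if traj.status[0, r] != rd.Status.ACTIVE:
                continue
            for reef in reefs:
                if shapely.intersects_xy(reef.polygon, traj.lon[0, r], traj.lat[0, r]):
                    expected.setdefault(reef.reef_id, ages[r] / 3600.0)
                    break
        got = dict(zip(events.dest_reef, events.travel_time_h))
        assert got == expected

    def test_self_recruitment_event_recorded(self):
        traj = make_traj([(0.0, 10.0, 33.0, -24.0)], source="N")  # sits on its reef
        events = rd.detect_events(traj, reef_pair())
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev.source_reef == "N" and ev.dest_reef == "N"
        assert ev.travel_time_h == 4 * 24.0  # first competent record

    def test_stranded_records_not_tested_by_default(self):
        traj = make_traj([(5.0, 6.0, 33.0, -26.0)])
        traj.status[:, :] = rd.Status.STRANDED
        assert rd.detect_events(traj, reef_pair()).empty
        assert len(rd.detect_events(traj, reef_pair(), test_stranded=True)) == 1

    def test_travel_times_respect_biology_window(self):
        traj = make_traj([(0.0, 10.0, 33.0, -26.0)])
        bio = rd.BiologyConfig(pld_days=9.0, precompetency_days=3.0)
        ev = rd.detect_events(traj, reef_pair(), bio)
        assert (ev.travel_time_h >= 3 * 24).all() and (ev.travel_time_h <= 9 * 24).all()

    def test_coarse_trajectory_warns(self):
        traj = make_traj([(5.0, 6.0, 33.0, -26.0)])
        coarse = rd.TrajectorySet(lon=traj.lon[:, ::4], lat=traj.lat[:, ::4],
                                  status=traj.status[:, ::4],
                                  release_times=traj.release_times,
                                  source_reef=traj.source_reef, dt=DT * 4)
        with pytest.warns(UserWarning, match="coarser"):
            rd.detect_events(coarse, reef_pair())


def random_events(rng, n, reef_ids, years=(2000,)):
    src = rng.choice(reef_ids, n)
    dst = rng.choice(reef_ids, n)
    rel = np.array([np.datetime64(f"{rng.choice(years)}-02-01", "ns")
                    + np.timedelta64(int(d) * 2, "D") for d in rng.integers(0, 25, n)])
    tt = rng.uniform(96, 240, n).round(1)
    return pd.DataFrame({
        "particle_id": np.arange(n), "source_reef": src, "dest_reef": dst,
        "release_time": rel,
        "arrival_time": rel + (tt * 3.6e12).astype("timedelta64[ns]"),
        "travel_time_h": tt,
    })


class TestMatrix:
    def test_no_events_zero_matrix(self, study_reefs):
        from reefdrift.biology import empty_events
        m = rd.build_matrix(empty_events(), study_reefs,
                            {r.reef_id: 10 for r in study_reefs})
        assert (m.counts.values == 0).all()

    def test_three_particles_one_destination(self, study_reefs):
        a, b = study_reefs.reef_ids[:2]
        ev = random_events(np.random.default_rng(0), 3, [a])
        ev["source_reef"] = a
        ev["dest_reef"] = b
        m = rd.build_matrix(ev, study_reefs, {r.reef_id: 10 for r in study_reefs})
        assert m.counts.loc[a, b] == 3
        assert m.counts.values.sum() == 3

    def test_matrix_matches_independent_tally(self, study_reefs):
        rng = np.random.default_rng(5)
        ev = random_events(rng, 400, study_reefs.reef_ids)
        released = {r.reef_id: 1000 for r in study_reefs}
        m = rd.build_matrix(ev, study_reefs, released)
        # brute-force tally oracle
        for i in study_reefs.reef_ids:
            for j in study_reefs.reef_ids:
                want = sum(1 for s, d in zip(ev.source_reef, ev.dest_reef)
                           if s == i and d == j)
                assert m.counts.loc[i, j] == want

    def test_unknown_reef_rejected(self, study_reefs):
        ev = random_events(np.random.default_rng(1), 5, ["nonexistent"])
        with pytest.raises(ValueError, match="unknown reef"):
            rd.build_matrix(ev, study_reefs, {r.reef_id: 10 for r in study_reefs})

    def test_counts_cannot_exceed_released(self, study_reefs):
        a = study_reefs.reef_ids[0]
        ev = random_events(np.random.default_rng(2), 30, [a])
        ev["source_reef"] = a
        with pytest.raises(ValueError, match="exceed"):
            rd.build_matrix(ev, study_reefs, {r.reef_id: 1 for r in study_reefs})


class TestTravelTimeStats:
    def test_single_event(self, study_reefs):
        a, b = study_reefs.reef_ids[:2]
        ev = random_events(np.random.default_rng(0), 1, [a])
        ev["source_reef"], ev["dest_reef"], ev["travel_time_h"] = a, b, 120.0
        s = rd.travel_time_stats(ev, study_reefs)
        assert s.mean.loc[a, b] == 120.0 and s.std.loc[a, b] == 0.0
        assert s.n.loc[a, b] == 1

    def test_hand_arithmetic_pair(self, study_reefs):
        a, b = study_reefs.reef_ids[:2]
        ev = random_events(np.random.default_rng(0), 2, [a])
        ev["source_reef"], ev["dest_reef"] = a, b
        ev["travel_time_h"] = [96.0, 144.0]
        s = rd.travel_time_stats(ev, study_reefs)
        assert s.mean.loc[a, b] == 120.0
        assert s.std.loc[a, b] == 24.0  # population standard deviation

    def test_matches_two_pass_oracle_and_emptiness_pattern(self, study_reefs):
        rng = np.random.default_rng(11)
        ev = random_events(rng, 300, study_reefs.reef_ids)
        s = rd.travel_time_stats(ev, study_reefs)
        m = rd.build_matrix(ev, study_reefs, {r.reef_id: 1000 for r in study_reefs})
        for i in study_reefs.reef_ids:
            for j in study_reefs.reef_ids:
                vals = [t for src, d, t in zip(ev.source_reef, ev.dest_reef,
                                               ev.travel_time_h)
                        if src == i and d == j]
                if not vals:  # blank exactly where the count matrix is zero
                    assert np.isnan(s.mean.loc[i, j]) and m.counts.loc[i, j] == 0
                    continue
                mu = sum(vals) / len(vals)
                var = sum((v - mu) ** 2 for v in vals) / len(vals)
                assert s.mean.loc[i, j] == pytest.approx(mu, abs=1e-9)
                assert s.std.loc[i, j] == pytest.approx(var ** 0.5, abs=1e-9)


class TestAggregateComplexes:
    def test_identity_map_leaves_matrix_unchanged(self, study_reefs):
        rng = np.random.default_rng(3)
        ev = random_events(rng, 100, study_reefs.reef_ids)
        m = rd.build_matrix(ev, study_reefs, {r.reef_id: 1000 for r in study_reefs})
        out = rd.aggregate_complexes(m, {r: r for r in study_reefs.reef_ids})
        np.testing.assert_array_equal(out.values, m.counts.values)

    def test_uniform_blocks_sum_to_four(self):
        reefs = rd.ReefSet([
            rd.ReefPolygon(f"{c}{k}", c, box_polygon(33.0 + 0.1 * k, lat, 1, 1))
            for c, lat in (("P", -21.0), ("Q", -25.0)) for k in range(2)
        ])
        counts = pd.DataFrame(1, index=reefs.reef_ids, columns=reefs.reef_ids)
        out = rd.aggregate_complexes(counts, reefs.complex_map)
        assert (out.values == 4).all()

    def test_blocks_match_brute_force(self, study_reefs):
        rng = np.random.default_rng(4)
        ev = random_events(rng, 250, study_reefs.reef_ids)
        m = rd.build_matrix(ev, study_reefs, {r.reef_id: 1000 for r in study_reefs})
        cmap = study_reefs.complex_map
        out = rd.aggregate_complexes(m, cmap)
        for ci in out.index:
            for cj in out.columns:
                want = sum(m.counts.loc[i, j]
                           for i in study_reefs.reef_ids if cmap[i] == ci
                           for j in study_reefs.reef_ids if cmap[j] == cj)
                assert out.loc[ci, cj] == want

    def test_unmapped_reef_rejected(self, study_reefs):
        m = pd.DataFrame(0, index=study_reefs.reef_ids, columns=study_reefs.reef_ids)
        with pytest.raises(ValueError, match="not mapped"):
            rd.aggregate_complexes(m, {})


class TestTemporalContributions:
    CMAP = {"n1": "N", "n2": "N", "m1": "M", "s1": "S"}

    def test_intra_complex_events_omitted(self):
        ev = random_events(np.random.default_rng(0), 10, ["m1"])
        ev["source_reef"] = "m1"
        ev["dest_reef"] = "m1"
        out = rd.temporal_contributions(ev, "M", self.CMAP)
        assert out.empty

    def test_two_sources_stack_to_external_total(self):
        rng = np.random.default_rng(1)
        ev = random_events(rng, 40, ["n1", "n2", "s1", "m1"])
        ev["dest_reef"] = "m1"
        out = rd.temporal_contributions(ev, "M", self.CMAP, group_by="year")
        external = (ev.source_reef != "m1").sum()
        assert out["count"].sum() == external
        assert set(out.source_complex) <= {"N", "S"}

    def test_release_grouping_sums_to_yearly_grouping(self):
        rng = np.random.default_rng(2)
        ev = random_events(rng, 200, ["n1", "n2", "s1", "m1"], years=(2000, 2001))
        ev.loc[::3, "dest_reef"] = "m1"
        by_rel = rd.temporal_contributions(ev, "M", self.CMAP, group_by="release")
        by_year = rd.temporal_contributions(ev, "M", self.CMAP, group_by="year")
        rolled = (by_rel.assign(year=pd.to_datetime(by_rel.group).dt.year)
                  .groupby(["year", "source_complex"])["count"].sum())
        for (y, c), n in rolled.items():
            assert by_year.set_index(["group", "source_complex"]).loc[(y, c), "count"] == n

    def test_unknown_complex_rejected(self):
        ev = random_events(np.random.default_rng(0), 3, ["n1"])
        with pytest.raises(ValueError, match="unknown complex"):
            rd.temporal_contributions(ev, "ZZ", self.CMAP)


class TestReleaseSchedule:
    def test_non_leap_year_30_releases_feb1_to_mar31(self):
        sched = rd.build_release_schedule([2001])
        assert len(sched) == 30
        assert sched[0] == np.datetime64("2001-02-01T00:00:00", "ns")
        assert sched[-1] == np.datetime64("2001-03-31T00:00:00", "ns")

    def test_leap_year_spacing_and_month_bounds(self):
        sched = np.array(rd.build_release_schedule([2004]))
        assert len(sched) == 30
        gaps = np.diff(sched).astype("timedelta64[h]").astype(int)
        assert (gaps == 48).all()
        months = sched.astype("datetime64[M]").astype(int) % 12 + 1
        assert set(months) <= {2, 3}

    def test_all_releases_at_midnight(self):
        sched = np.array(rd.build_release_schedule([2000, 2001, 2004]))
        seconds_in_day = (sched - sched.astype("datetime64[D]")).astype(
            "timedelta64[s]").astype(int)
        assert (seconds_in_day == 0).all()

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            rd.build_release_schedule([])
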