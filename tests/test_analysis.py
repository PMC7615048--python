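"""Summary statistics against hand-built fixtures and oracles."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath

from iknm import analysis, geometry as geo
from iknm.engine import SNAPSHOT_COLUMNS, EVENT_COLUMNS, Trajectory, \
    RunConfig


def snapshot_from(nuclei, time=80.0):
    """Build a snapshot DataFrame from (id, phase, center, area) tuples."""
    rows = []
    for nid, phase, center, area in nuclei:
        v = geo.regular_polygon(center, area)
        c = v.mean(axis=0)
        rows.append([time, nid, phase, c[0], c[1], geo.polygon_area(v),
                     v[:, 1].min(), v[:, 1].max()] + list(v.ravel()))
    return pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)


def events_from(records):
    return pd.DataFrame([[t, e, nid, pid, 0.0, 0.0]
                         for t, e, nid, pid in records],
                        columns=EVENT_COLUMNS)


class TestPhaseFractions:
    def test_hand_built_four_nucleus_census(self):
        snap = snapshot_from([(0, "G1", (1, 1), 0.7), (1, "G1", (3, 1), 0.7),
                              (2, "S", (1, 3), 0.7), (3, "G2", (3, 3), 0.7)])
        traj = Trajectory(snapshots=snap, frames=pd.DataFrame(),
                          events=pd.DataFrame(columns=EVENT_COLUMNS),
                          config=RunConfig(), seed=0)
        out = analysis.phase_fractions(traj, [80.0])
        assert out.iloc[0]["fraction_G1"] == pytest.approx(0.5)
        assert out.iloc[0]["fraction_S"] == pytest.approx(0.25)
        assert out.iloc[0]["fraction_G2"] == pytest.approx(0.25)

    def test_fresh_seed_census(self, short_run):
        out = analysis.phase_fractions(short_run, [72.0])
        assert out.iloc[0]["fraction_G1"] == pytest.approx(0.7)
        assert out.iloc[0]["fraction_S"] == pytest.approx(0.3)
        assert out.iloc[0]["fraction_G2"] == pytest.approx(0.0)

    def test_fractions_sum_to_one_at_every_time(self, short_run):
        times = short_run.frames["time"].iloc[::4]
        out = analysis.phase_fractions(short_run, times)
        s = out[["fraction_G1", "fraction_S", "fraction_G2"]].sum(axis=1)
        assert np.allclose(s, 1.0, atol=1e-9)

    def test_m_counted_with_g2_by_default(self):
        snap = snapshot_from([(0, "M", (1, 1), 0.7), (1, "G1", (3, 1), 0.7)])
        traj = Trajectory(snapshots=snap, frames=pd.DataFrame(),
                          events=pd.DataFrame(columns=EVENT_COLUMNS),
                          config=RunConfig(), seed=0)
        out = analysis.phase_fractions(traj, [80.0])
        assert out.iloc[0]["fraction_G2"] == pytest.approx(0.5)
        out2 = analysis.phase_fractions(traj, [80.0], merge_M=False)
        assert out2.iloc[0]["fraction_G2"] == pytest.approx(0.0)
        assert out2.iloc[0]["fraction_M"] == pytest.approx(0.5)


class TestABDistribution:
    def test_single_occupied_bin(self):
        snap = snapshot_from([(i, "G1", (1 + i, 3.9), 0.3)
                              for i in range(4)])
        out = analysis.ab_distribution(snap, apical_z=4.0)
        assert len(out) == 1
        assert out.iloc[0]["fraction"] == pytest.approx(1.0)
        assert out.iloc[0]["bin"] == 0   # depth 0.1 -> bin [0, 0.5)

    def test_mass_conservation(self, short_run):
        snap = analysis.snapshot_at(short_run, 76.0)
        apz = float(short_run.frames["apical_height"].iloc[-1])
        out = analysis.ab_distribution(snap, apical_z=apz)
        assert out["fraction"].sum() == pytest.approx(1.0)
        assert out["count"].sum() == len(snap)

    def test_hand_built_depths_match_manual_count(self):
        # depths: 0.2, 0.2, 0.7, 1.3 -> bins 0, 0, 1, 2
        snap = snapshot_from([(0, "G1", (1.0, 3.8), 0.3),
                              (1, "S", (2.0, 3.8), 0.3),
                              (2, "G1", (3.0, 3.3), 0.3),
                              (3, "G2", (4.0, 2.7), 0.3)])
        out = analysis.ab_distribution(snap, apical_z=4.0)
        by_bin = out.groupby("bin")["count"].sum().to_dict()
        assert by_bin == {0: 2, 1: 1, 2: 1}

    def test_marginal_consistency_with_census(self, short_run):
        """Summing the depth distribution per phase gives the census."""
        snap = analysis.snapshot_at(short_run, 75.0)
        apz = 5.0
        out = analysis.ab_distribution(snap, apical_z=apz)
        census = snap["phase"].value_counts(normalize=True)
        for phase, frac in census.items():
            assert out[out["phase"] == phase]["fraction"].sum() == \
                pytest.approx(frac, abs=1e-9)


class TestCrowdingIndex:
    def test_isolated_nucleus_zero(self):
        snap = snapshot_from([(0, "G1", (2.5, 2.0), 0.7)])
        ci = analysis.crowding_index(snap, 0, wall_left=0, wall_right=5,
                                     apical_z=4.0)
        assert ci == pytest.approx(0.0)

    def test_border_nucleus_excluded(self):
        snap = snapshot_from([(0, "G1", (0.6, 2.0), 0.7)])
        assert analysis.crowding_index(snap, 0, 0, 5, 4.0) is None

    def test_saturated_neighborhood_close_to_one(self):
        # focal nucleus ringed by a dense grid of neighbors
        nuclei = [(0, "G1", (5.0, 5.0), np.pi / 4)]
        k = 1
        for dx in np.arange(-1.8, 1.9, 0.9):
            for dz in np.arange(-1.8, 1.9, 0.9):
                if abs(dx) < 0.45 and abs(dz) < 0.45:
                    continue
                nuclei.append((k, "S", (5 + dx, 5 + dz), 0.78))
                k += 1
        snap = snapshot_from(nuclei, time=80.0)
        ci = analysis.crowding_index(snap, 0, 0, 10, 10.0)
        assert ci > 0.75

    def test_against_rasterization(self, rng):
        """Occupancy fraction agrees with a pixel-count oracle."""
        nuclei = [(0, "G1", (5.0, 3.0), np.pi / 4)]
        for k in range(1, 7):
            c = (rng.uniform(3.5, 6.5), rng.uniform(1.8, 4.2))
            nuclei.append((k, "S", c, rng.uniform(0.4, 0.8)))
        snap = snapshot_from(nuclei)
        ci = analysis.crowding_index(snap, 0, 0, 10, 10.0)
        focal = geo.regular_polygon((5.0, 3.0), np.pi / 4)
        x0, z0 = focal.min(0)
        x1, z1 = focal.max(0)
        rx = (x0 - 0.75, x1 + 0.75)
        rz = (z0 - 0.25, z1 + 0.25)
        pitch = 4e-3
        gx, gz = np.meshgrid(np.arange(*rx, pitch), np.arange(*rz, pitch))
        pts = np.column_stack([gx.ravel(), gz.ravel()])
        in_focal = MplPath(focal).contains_points(pts)
        occupied = np.zeros(len(pts), dtype=bool)
        for k in range(1, 7):
            _, _, c, a = nuclei[k]
            occupied |= MplPath(geo.regular_polygon(c, a)).contains_points(pts)
        # overlap-area sum counts doubly covered pixels twice
        multi = np.zeros(len(pts))
        for k in range(1, 7):
            _, _, c, a = nuclei[k]
            multi += MplPath(geo.regular_polygon(c, a)).contains_points(pts)
        oracle = multi.sum() / (len(pts) - in_focal.sum())
        assert ci == pytest.approx(oracle, abs=0.01)

    def test_monotone_when_neighbor_added(self):
        base = [(0, "G1", (5.0, 3.0), np.pi / 4),
                (1, "S", (6.0, 3.0), 0.7)]
        more = base + [(2, "S", (4.0, 3.0), 0.7)]
        ci1 = analysis.crowding_index(snapshot_from(base), 0, 0, 10, 10.0)
        ci2 = analysis.crowding_index(snapshot_from(more), 0, 0, 10, 10.0)
        assert 0.0 <= ci1 <= ci2 <= 1.0


class TestG2Durations:
    def test_simple_log(self):
        ev = events_from([(80.0, "SG2", 5, -1), (84.0, "DIVISION", 10, 5),
                          (84.0, "DIVISION", 11, 5)])
        per, series = analysis.g2_durations(ev)
        assert len(per) == 1
        assert per.iloc[0]["duration"] == pytest.approx(4.0)
        assert series.iloc[0]["mean_duration"] == pytest.approx(4.0)

    def test_arrested_excluded_from_durations(self):
        ev = events_from([(80.0, "SG2", 5, -1), (90.0, "SG2", 6, -1),
                          (84.0, "DIVISION", 10, 5),
                          (84.0, "DIVISION", 11, 5)])
        per, _ = analysis.g2_durations(ev)
        assert set(per["nucleus_id"]) == {5}

    def test_hand_built_five_event_log(self):
        ev = events_from([
            (74.0, "SG2", 1, -1), (76.5, "DIVISION", 20, 1),
            (76.5, "DIVISION", 21, 1),
            (90.0, "SG2", 2, -1), (104.0, "DIVISION", 30, 2),
            (104.0, "DIVISION", 31, 2)])
        per, series = analysis.g2_durations(ev, time_bin=12.0)
        got = dict(zip(per["nucleus_id"], per["duration"]))
        assert got == {1: pytest.approx(2.5), 2: pytest.approx(14.0)}
        assert len(series) == 2

    def test_orphan_division_raises(self):
        ev = events_from([(84.0, "DIVISION", 10, 5),
                          (84.0, "DIVISION", 11, 5)])
        with pytest.raises(analysis.AnalysisError):
            analysis.g2_durations(ev)


class TestG2Arrested:
    def test_all_divide_gives_zero_series(self):
        ev = events_from([(80.0, "SG2", 5, -1), (84.0, "DIVISION", 10, 5),
                          (84.0, "DIVISION", 11, 5)])
        out = analysis.g2_arrested(ev, t_end=116.0)
        assert (out["count"] == 0).all()

    def test_cumulative_counts_monotone_and_correct(self):
        ev = events_from([(75.0, "SG2", 1, -1), (95.0, "SG2", 2, -1),
                          (100.0, "SG2", 3, -1),
                          (78.0, "DIVISION", 10, 1),
                          (78.0, "DIVISION", 11, 1)])
        out = analysis.g2_arrested(ev, t_end=116.0, time_bin=12.0)
        assert np.all(np.diff(out["cumulative"]) >= 0)
        assert out["cumulative"].iloc[-1] == 2

    def test_partitions_g2_entries_with_durations(self, short_run):
        ev = short_run.events
        n_entries = (ev["event"] == "SG2").sum()
        per, _ = analysis.g2_durations(ev)
        arrested = analysis.g2_arrested(ev, t_end=78.0)
        assert len(per) + arrested["count"].sum() == n_entries


class TestTerminalVelocity:
    @staticmethod
    def synthetic_trajectory(z_of_t, div_time=80.0, nid=3):
        times = np.arange(72.0, div_time + 0.25, 0.25)
        rows = []
        for t in times:
            v = geo.regular_polygon((2.0, z_of_t(t)), 0.5)
            c = v.mean(axis=0)
            rows.append([t, nid, "G2", c[0], c[1], 0.5,
                         v[:, 1].min(), v[:, 1].max()] + list(v.ravel()))
        snaps = pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)
        ev = events_from([(div_time, "DIVISION", 10, nid),
                          (div_time, "DIVISION", 11, nid)])
        return Trajectory(snapshots=snaps, frames=pd.DataFrame(),
                          events=ev, config=RunConfig(), seed=0)

    def test_unit_climb_in_final_hour(self):
        traj = self.synthetic_trajectory(lambda t: 1.0 + max(t - 79.0, 0.0))
        per, _ = analysis.terminal_velocity(traj)
        assert per.iloc[0]["velocity"] == pytest.approx(1.0)

    def test_stationary_nucleus_zero(self):
        traj = self.synthetic_trajectory(lambda t: 2.0)
        per, _ = analysis.terminal_velocity(traj)
        assert per.iloc[0]["velocity"] == pytest.approx(0.0)

    def test_three_divisions_match_manual_differences(self):
        parts = []
        evs = []
        for k, (nid, speed) in enumerate([(1, 0.5), (2, 1.5), (3, 0.25)]):
            tr = self.synthetic_trajectory(
                lambda t, s=speed: 1.0 + s * (t - 72.0), div_time=80.0,
                nid=nid)
            parts.append(tr.snapshots)
            evs.append(tr.events.assign(parent_id=nid,
                                        nucleus_id=[10 + k, 20 + k]))
        traj = Trajectory(snapshots=pd.concat(parts),
                          frames=pd.DataFrame(),
                          events=pd.concat(evs), config=RunConfig(),
                          seed=0)
        per, _ = analysis.terminal_velocity(traj)
        got = dict(zip(per["parent_id"], per["velocity"]))
        assert got[1] == pytest.approx(0.5)
        assert got[2] == pytest.approx(1.5)
        assert got[3] == pytest.approx(0.25)

    def test_coarse_cadence_rejected(self):
        traj = self.synthetic_trajectory(lambda t: 2.0)
        traj.snapshots = traj.snapshots.iloc[::4]   # cadence 1 h
        with pytest.raises(analysis.AnalysisError):
            analysis.terminal_velocity(traj)


class TestThicknessAndLayers:
    def test_single_layer(self):
        snap = snapshot_from([(i, "G1", (1 + i * 1.02, 0.51), np.pi / 4)
                              for i in range(5)])
        out = analysis.thickness_and_layers(snap, apical_z=1.1)
        assert out["layers"] == pytest.approx(1.0, abs=0.2)

    def test_two_stacked_rows(self):
        nuclei = [(i, "G1", (1 + i * 1.02, 0.51), np.pi / 4)
                  for i in range(5)]
        nuclei += [(5 + i, "G1", (1 + i * 1.02, 1.53), np.pi / 4)
                   for i in range(5)]
        out = analysis.thickness_and_layers(snapshot_from(nuclei),
                                            apical_z=2.1)
        assert out["layers"] == pytest.approx(2.0, abs=0.25)

    def test_span_invariant_to_lateral_translation(self):
        nuclei = [(i, "G1", (1 + i, 0.5 + 0.3 * i), 0.5) for i in range(5)]
        shifted = [(i, p, (c[0] + 7.0, c[1]), a)
                   for (i, p, c, a) in nuclei]
        a = analysis.thickness_and_layers(snapshot_from(nuclei), 4.0)
        b = analysis.thickness_and_layers(snapshot_from(shifted), 4.0)
        assert a["occupied_span"] == pytest.approx(b["occupied_span"])


class TestShapeIndex:
    def test_regular_20gon_closed_form(self):
        p = geo.regular_polygon((0, 0), 1.0)
        expected = 1.0 / geo.max_extent(p)
        assert analysis.shape_index(p) == pytest.approx(expected)

    def test_elongation_decreases_index(self):
        p = geo.regular_polygon((0, 0), 1.0)
        for s in (1.5, 2.0, 3.0):
            q = p.copy()
            q[:, 0] *= s
            q[:, 1] /= s
            assert analysis.shape_index(q) < analysis.shape_index(p)
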