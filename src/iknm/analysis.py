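"""Summary statistics computed from trajectories and event logs.

Every statistic here is a pure function of the recorded snapshots and
events: recomputation is idempotent, and ensemble aggregation is
order-independent across replicates.  Depths are reported from the
apical side (depth = apical height − centroid z) in G1∅ units; the
three-way phase census counts M-phase nuclei with G2, matching what a
two-color cell-cycle reporter can resolve (switchable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box

from . import geometry as geo
from .geometry import N_VERTICES

#: default depth bin width for apical-basal distributions (G1∅)
AB_BIN_WIDTH = 0.5
#: default time bin for G2-duration / arrest series (h)
TIME_BIN = 12.0
#: 2D crowding-neighborhood margins (G1∅): wider laterally than
#: apico-basally, mirroring the anisotropic in vivo neighborhood
CROWDING_MARGIN_X = 0.75
CROWDING_MARGIN_Z = 0.25


class AnalysisError(ValueError):
    """Statistic requested from insufficient or inconsistent data."""


def _vertices(row) -> np.ndarray:
    cols = [f"v{i}{c}" for i in range(N_VERTICES) for c in ("x", "z")]
    return np.asarray([row[c] for c in cols]).reshape(N_VERTICES, 2)


def snapshot_at(trajectory, time: float) -> pd.DataFrame:
    """Nucleus rows of the recorded frame nearest to ``time``."""
    snaps = trajectory.snapshots
    if snaps.empty:
        raise AnalysisError("trajectory has no snapshots")
    times = snaps["time"].unique()
    t = times[np.argmin(np.abs(times - time))]
    return snaps[snaps["time"] == t]


def phase_fractions(trajectories, times, merge_M: bool = True
                    ) -> pd.DataFrame:
    """Phase-fraction census over time, ensemble mean ± SD.

    Accepts one trajectory or a list.  Returns one row per requested
    time with columns ``fraction_G1/S/G2`` (+ ``_sd`` for ensembles and
    ``fraction_M`` when ``merge_M`` is off); fractions at each time sum
    to 1.
    """
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    rows = []
    for t_req in np.atleast_1d(times):
        per_rep = []
        for traj in trajectories:
            snap = snapshot_at(traj, t_req)
            if snap.empty:
                raise AnalysisError(f"empty snapshot at t={t_req}")
            n = len(snap)
            counts = snap["phase"].value_counts()
            g1 = counts.get("G1", 0) / n
            s = counts.get("S", 0) / n
            g2 = counts.get("G2", 0) / n
            m = counts.get("M", 0) / n
            if merge_M:
                per_rep.append((g1, s, g2 + m, 0.0, n))
            else:
                per_rep.append((g1, s, g2, m, n))
        arr = np.asarray(per_rep)
        row = {"time": float(t_req),
               "fraction_G1": arr[:, 0].mean(),
               "fraction_S": arr[:, 1].mean(),
               "fraction_G2": arr[:, 2].mean(),
               "n_total": arr[:, 4].sum()}
        if not merge_M:
            row["fraction_M"] = arr[:, 3].mean()
        if len(trajectories) > 1:
            row.update({"fraction_G1_sd": arr[:, 0].std(ddof=1),
                        "fraction_S_sd": arr[:, 1].std(ddof=1),
                        "fraction_G2_sd": arr[:, 2].std(ddof=1)})
        rows.append(row)
    return pd.DataFrame(rows)


def ab_distribution(snapshot: pd.DataFrame, apical_z: float,
                    bin_width: float = AB_BIN_WIDTH) -> pd.DataFrame:
    """Apical-basal distribution of nuclei by phase.

    Nuclei are assigned to half-open depth bins ``[k·w, (k+1)·w)`` by
    centroid depth (apical z − centroid z) and counts are normalized by
    the total number of nuclei, so the distribution sums to 1 over bins
    and phases.
    """
    if snapshot.empty:
        raise AnalysisError("empty snapshot")
    depth = apical_z - snapshot["cz"].to_numpy()
    k = np.floor(depth / bin_width).astype(int)
    n = len(snapshot)
    df = pd.DataFrame({"bin": k, "phase": snapshot["phase"].to_numpy()})
    out = (df.groupby(["bin", "phase"]).size().rename("count")
           .reset_index())
    out["depth_lo"] = out["bin"] * bin_width
    out["depth_hi"] = (out["bin"] + 1) * bin_width
    out["fraction"] = out["count"] / n
    return out[["bin", "depth_lo", "depth_hi", "phase", "count",
                "fraction"]]


def crowding_index(snapshot: pd.DataFrame, nucleus_id: int,
                   wall_left: float, wall_right: float,
                   apical_z: float,
                   margin_x: float = CROWDING_MARGIN_X,
                   margin_z: float = CROWDING_MARGIN_Z) -> float | None:
    """Fraction of a nucleus's expanded neighborhood occupied by others.

    The nucleus's bounding rectangle is expanded by ``margin_x``
    laterally and ``margin_z`` apico-basally, then clipped to the box;
    the index is the summed overlap area of all *other* nuclei with the
    rectangle divided by the rectangle area not occupied by the focal
    nucleus.  Returns ``None`` for border nuclei whose expanded
    rectangle crosses a lateral wall (these are excluded, as border
    nuclei are in the imaging analog).
    """
    rows = snapshot[snapshot["id"] == nucleus_id]
    if rows.empty:
        raise AnalysisError(f"nucleus {nucleus_id} not in snapshot")
    focal = _vertices(rows.iloc[0])
    x0, z0 = focal.min(axis=0)
    x1, z1 = focal.max(axis=0)
    rx0, rx1 = x0 - margin_x, x1 + margin_x
    rz0, rz1 = z0 - margin_z, z1 + margin_z
    if rx0 < wall_left or rx1 > wall_right:
        return None
    rz0 = max(rz0, 0.0)
    rz1 = min(rz1, apical_z)
    rect = shapely_box(rx0, rz0, rx1, rz1)
    if rect.area <= 0:
        raise AnalysisError("empty neighborhood rectangle")
    focal_in = geo.to_shapely(focal).intersection(rect).area
    denom = rect.area - focal_in
    if denom <= 0:
        raise AnalysisError("neighborhood fully occupied by focal nucleus")
    occupied = 0.0
    for _, row in snapshot.iterrows():
        if row["id"] == nucleus_id:
            continue
        other = geo.to_shapely(_vertices(row))
        if other.bounds[2] < rx0 or other.bounds[0] > rx1 \
                or other.bounds[3] < rz0 or other.bounds[1] > rz1:
            continue
        occupied += other.intersection(rect).area
    return float(min(occupied / denom, 1.0))


def crowding_indices(snapshot, wall_left, wall_right, apical_z,
                     **kw) -> pd.DataFrame:
    """Crowding index for every non-border nucleus of a snapshot."""
    rows = []
    for nid in snapshot["id"]:
        ci = crowding_index(snapshot, nid, wall_left, wall_right,
                            apical_z, **kw)
        if ci is not None:
            rows.append({"id": int(nid), "crowding_index": ci})
    return pd.DataFrame(rows, columns=["id", "crowding_index"])


def g2_durations(events: pd.DataFrame, time_bin: float = TIME_BIN
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lineage G2 durations and their binned time series.

    The G2 duration of a completed lineage is division time − G2-entry
    time, assigned to the G2-entry time.  Nuclei that enter G2 but
    never divide are excluded here (they are the arrested set).  A
    division is matched to the *mother's* G2 entry through the
    daughters' ``parent_id``.
    """
    sg2 = events[events["event"] == "SG2"].set_index("nucleus_id")["time"]
    div = (events[events["event"] == "DIVISION"]
           .groupby("parent_id")["time"].first())
    orphans = set(div.index) - set(sg2.index)
    if orphans:
        raise AnalysisError(f"division without G2 entry for {orphans}")
    rows = []
    for nid, t_div in div.items():
        t_g2 = sg2.loc[nid]
        rows.append({"nucleus_id": int(nid), "g2_entry": float(t_g2),
                     "duration": float(t_div - t_g2)})
    per = pd.DataFrame(rows,
                       columns=["nucleus_id", "g2_entry", "duration"])
    if per.empty:
        return per, pd.DataFrame(columns=["bin_lo", "bin_hi",
                                          "mean_duration", "sd", "n"])
    k = np.floor((per["g2_entry"] - per["g2_entry"].min() * 0)
                 / time_bin).astype(int)
    per = per.assign(bin=k)
    series = (per.groupby("bin")
              .agg(mean_duration=("duration", "mean"),
                   sd=("duration", "std"), n=("duration", "size"))
              .reset_index())
    series["bin_lo"] = series["bin"] * time_bin
    series["bin_hi"] = (series["bin"] + 1) * time_bin
    return per, series[["bin_lo", "bin_hi", "mean_duration", "sd", "n"]]


def g2_arrested(events: pd.DataFrame, t_end: float,
                time_bin: float = TIME_BIN) -> pd.DataFrame:
    """Cumulative count of G2-arrested nuclei binned by G2-entry time.

    Arrested = entered G2 but produced no division by ``t_end``.
    Together with :func:`g2_durations` this partitions the set of G2
    entries exactly.
    """
    sg2 = events[events["event"] == "SG2"]
    divided = set(events[events["event"] == "DIVISION"]["parent_id"])
    arrested = sg2[~sg2["nucleus_id"].isin(divided)]
    n_bins = int(np.ceil(t_end / time_bin)) - int(np.floor(
        sg2["time"].min() / time_bin)) if len(sg2) else 0
    t0_bin = np.floor(sg2["time"].min() / time_bin) * time_bin \
        if len(sg2) else 0.0
    edges = t0_bin + time_bin * np.arange(max(n_bins, 1) + 1)
    counts, _ = np.histogram(arrested["time"], bins=edges)
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "count": counts, "cumulative": np.cumsum(counts)})


def terminal_velocity(trajectory, window: float = 1.0,
                      fit_degree: int = 3) -> tuple[pd.DataFrame, dict]:
    """Apical-ward centroid speed during the hour preceding each division.

    For each division, the mother's centroid z displacement over the
    ``window`` hours before the division time, divided by the window
    (G1∅/h).  A least-squares polynomial trend (degree 3) over division
    time provides the begin/end ratio.  Requires snapshot cadence
    ≤ window/4.
    """
    snaps = trajectory.snapshots
    times = np.sort(snaps["time"].unique())
    if len(times) < 2 or np.max(np.diff(times)) > window / 4 + 1e-9:
        raise AnalysisError(
            "snapshot cadence too coarse for the velocity window: need "
            f"<= {window / 4} h, have {np.max(np.diff(times)) if len(times) > 1 else np.inf} h")
    div = trajectory.events[trajectory.events["event"] == "DIVISION"]
    rows = []
    by_id = {nid: g.sort_values("time")
             for nid, g in snaps.groupby("id")}
    for parent, g in div.groupby("parent_id"):
        t_div = float(g["time"].iloc[0])
        hist = by_id.get(parent)
        if hist is None:
            continue
        t_hist = hist["time"].to_numpy()
        z_hist = hist["cz"].to_numpy()
        t1 = t_hist[t_hist <= t_div + 1e-9]
        if len(t1) == 0 or t1[-1] < t_div - window / 4:
            continue
        t_lo = t_div - window
        if t_hist[0] > t_lo + 1e-9:
            continue   # mother too young for a full window
        z_end = z_hist[np.searchsorted(t_hist, t1[-1])]
        z_start = np.interp(t_lo, t_hist, z_hist)
        rows.append({"parent_id": int(parent), "division_time": t_div,
                     "velocity": (z_end - z_start) / window})
    per = pd.DataFrame(rows, columns=["parent_id", "division_time",
                                      "velocity"])
    trend = {"coefficients": None, "begin": np.nan, "end": np.nan,
             "end_begin_ratio": np.nan}
    if len(per) > fit_degree + 1:
        t = per["division_time"].to_numpy()
        coef = np.polyfit(t, per["velocity"].to_numpy(), fit_degree)
        begin = float(np.polyval(coef, t.min()))
        end = float(np.polyval(coef, t.max()))
        trend = {"coefficients": coef.tolist(), "begin": begin,
                 "end": end,
                 "end_begin_ratio": end / begin if begin else np.nan}
    return per, trend


def thickness_and_layers(snapshot: pd.DataFrame, apical_z: float
                         ) -> dict:
    """Tissue thickness, occupied span and a layer estimate.

    Thickness is the apical height; the occupied span is the 2.5–97.5%
    interquantile range of centroid depths; the layer estimate divides
    the occupied span by the mean nuclear diameter (diameter of the
    disc of equal area).
    """
    if snapshot.empty:
        raise AnalysisError("empty snapshot")
    depth = apical_z - snapshot["cz"].to_numpy()
    lo, hi = np.percentile(depth, [2.5, 97.5])
    span = float(hi - lo)
    diam = float(np.mean(2.0 * np.sqrt(snapshot["area"].to_numpy()
                                       / np.pi)))
    return {"thickness": float(apical_z), "occupied_span": span,
            "mean_diameter": diam,
            "layers": span / diam + 1.0 if diam > 0 else np.nan}


def shape_index(poly: np.ndarray) -> float:
    """Compactness measure: area divided by the largest dimension."""
    return geo.polygon_area(poly) / geo.max_extent(poly)
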