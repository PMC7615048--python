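"""Simulation loop: seeding, configuration, stepping, recording.

A run advances the tissue from 72 to 116 h AEL (hours after egg
laying) in fixed increments ``dt``.  Each step applies, in this order:
(1) cell-cycle updates — re-anchorings, target-area growth, phase
transitions, divisions — so new daughters relax mechanically in the
same step; (2) the constrained energy minimization; (3) snapshot and
event recording.  A single RNG stream per replicate feeds every
stochastic draw (seeding positions and elapsed fractions, S durations,
daughter choice, re-anchor delay) in documented call order, so a run
is bit-reproducible from its config and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry as geo
from .geometry import N_VERTICES
from .mechanics import Box, Cable, MechanicalParams, minimize_state
from .cell_cycle import (CycleParams, Nucleus, advance_phase, divide,
                         g1_duration_at, draw_S_duration, reanchor,
                         update_target_area)

#: seeded nucleus area: a disc of diameter 1 G1∅ has area π/4
SEED_AREA = np.pi / 4.0


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Single source of configuration truth for a run or ensemble."""

    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    dt: float = 0.05                 # h (3 min of simulated time)
    snapshot_every: float = 0.25     # h between recorded snapshots
    seed: int = 0
    n_replicates: int = 20
    box_width: float = 5.0           # G1∅, rest width
    box_height: float = 3.0          # G1∅, apical rest height
    mitotic_zone_depth: float = 0.5  # G1∅
    grid_spacing: float = 0.5        # G1∅ between apical control points
    n_seed_nuclei: int = 10
    n_seed_G1: int = 7
    n_seed_S: int = 3
    output_dir: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.snapshot_every < self.dt - 1e-12:
            raise ConfigError("snapshot_every must be >= dt")
        if self.n_seed_G1 + self.n_seed_S > self.n_seed_nuclei:
            raise ConfigError("seed phase counts exceed nucleus count")
        if self.box_width <= 1 or self.box_height <= 1:
            raise ConfigError("box must be larger than one nucleus")
        if self.cycle.t_end <= self.cycle.t_start:
            raise ConfigError("t_end must exceed t_start")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cycle"]["reanchor_delay_options"] = list(
            self.cycle.reanchor_delay_options)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "mechanics" in d:
            mk = {f.name for f in _dc_fields(MechanicalParams)}
            bad = set(d["mechanics"]) - mk
            if bad:
                raise ConfigError(f"unknown mechanics keys: {sorted(bad)}")
            d["mechanics"] = MechanicalParams(**d["mechanics"])
        if "cycle" in d:
            ck = {f.name for f in _dc_fields(CycleParams)}
            bad = set(d["cycle"]) - ck
            if bad:
                raise ConfigError(f"unknown cycle keys: {sorted(bad)}")
            cyc = dict(d["cycle"])
            if "reanchor_delay_options" in cyc:
                cyc["reanchor_delay_options"] = tuple(
                    cyc["reanchor_delay_options"])
            d["cycle"] = CycleParams(**cyc)
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


@dataclass
class SimulationState:
    """The object the minimizer advances: time, box, nuclei, RNG."""

    t: float
    box: Box
    nuclei: list
    rng: np.random.Generator
    step_index: int = 0
    next_id: int = 0


@dataclass
class Trajectory:
    """Per-frame snapshots, per-frame summaries and discrete events."""

    snapshots: pd.DataFrame
    frames: pd.DataFrame
    events: pd.DataFrame
    config: RunConfig
    seed: int

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.snapshots.to_csv(d / "snapshots.csv", index=False)
        self.frames.to_csv(d / "frames.csv", index=False)
        self.events.to_csv(d / "events.csv", index=False)
        self.config.to_yaml(d / "config.yaml")
        (d / "meta.json").write_text(json.dumps({"seed": self.seed}))

    @classmethod
    def load(cls, directory) -> "Trajectory":
        d = Path(directory)
        return cls(
            snapshots=pd.read_csv(d / "snapshots.csv"),
            frames=pd.read_csv(d / "frames.csv"),
            events=pd.read_csv(d / "events.csv"),
            config=RunConfig.from_yaml(d / "config.yaml"),
            seed=json.loads((d / "meta.json").read_text())["seed"])


SNAPSHOT_COLUMNS = (
    ["time", "id", "phase", "cx", "cz", "area", "min_z", "max_z"]
    + [f"v{i}{c}" for i in range(N_VERTICES) for c in ("x", "z")])

EVENT_COLUMNS = ["time", "event", "nucleus_id", "parent_id", "x", "z"]

FRAME_COLUMNS = ["time", "n_total", "n_G1", "n_S", "n_G2", "n_M",
                 "apical_height", "wall_left", "wall_right"]


def _snapshot_rows(state: SimulationState) -> list:
    rows = []
    for n in state.nuclei:
        v = n.polygon
        c = v.mean(axis=0)
        rows.append([state.t, n.id, n.phase, float(c[0]), float(c[1]),
                     geo.polygon_area(v), float(v[:, 1].min()),
                     float(v[:, 1].max())] + list(v.ravel()))
    return rows


def _frame_row(state: SimulationState) -> list:
    counts = {p: 0 for p in ("G1", "S", "G2", "M")}
    for n in state.nuclei:
        counts[n.phase] += 1
    box = state.box
    inner = ((box.grid_x >= box.wall_left)
             & (box.grid_x <= box.wall_right))
    return [state.t, len(state.nuclei), counts["G1"], counts["S"],
            counts["G2"], counts["M"],
            float(np.mean(box.heights[inner])),
            box.wall_left, box.wall_right]


def seed_initial_state(config: RunConfig,
                       rng: np.random.Generator) -> SimulationState:
    """Seed the box with 10 nuclei: 7 in G1, 3 in S, none in G2.

    Nuclei are regular 20-gons of area π/4 G1∅² (a disc of diameter
    1 G1∅), placed on a jittered two-row grid with rejection of
    overlapping placements.  Each nucleus receives a vertical cable at
    its own lateral position.  Seeded G1 and S nuclei are given a
    random already-elapsed fraction of their phase so the population is
    asynchronous from the start; for S nuclei the birth area is set so
    the growth law reproduces the seeded area at the seeded elapsed
    fraction.
    """
    box = Box.create(width=config.box_width, height=config.box_height,
                     mitotic_zone_depth=config.mitotic_zone_depth,
                     grid_spacing=config.grid_spacing)
    t0 = config.cycle.t_start
    n_total = config.n_seed_nuclei
    radius = np.sqrt(2.0 * SEED_AREA / (N_VERTICES
                                        * np.sin(2 * np.pi / N_VERTICES)))
    n_cols = int(np.ceil(n_total / 2))
    margin = radius * 1.05
    usable_w = config.box_width - 2 * margin
    usable_h = config.box_height - config.mitotic_zone_depth - 2 * margin
    if usable_w <= 0 or usable_h <= 0 or usable_w / (n_cols - 1 + 1e-9) < 0:
        raise ConfigError("box too small to place the seed nuclei")
    centers = None
    for _ in range(200):
        cols = np.linspace(margin, config.box_width - margin, n_cols)
        rows = np.linspace(margin, margin + usable_h, 2)
        pts = []
        for k in range(n_total):
            cx = cols[k % n_cols] + rng.uniform(-0.05, 0.05)
            cz = rows[k // n_cols] + rng.uniform(-0.05, 0.05)
            pts.append((cx, cz))
        pts = np.asarray(pts)
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]
                       ).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        if d.min() > 2 * radius * 0.95:
            centers = pts
            break
    if centers is None:
        raise ConfigError("could not place non-overlapping seed nuclei; "
                          "enlarge the box or reduce the seed count")

    phases = (["G1"] * config.n_seed_G1 + ["S"] * config.n_seed_S
              + ["G2"] * (n_total - config.n_seed_G1 - config.n_seed_S))
    order = rng.permutation(n_total)
    nuclei = []
    for i in range(n_total):
        phase = phases[order[i]]
        c = centers[i]
        poly = geo.regular_polygon(c, SEED_AREA)
        cable = Cable(apical_x=float(c[0]), basal_x=float(c[0]))
        if phase == "G1":
            g1_dur = (g1_duration_at(t0, config.cycle)
                      if config.cycle.mode == "timer" else None)
            f = rng.uniform(0.0, 1.0)
            entry = t0 - f * (g1_dur if g1_dur is not None
                              else config.cycle.G1_start)
            n = Nucleus(id=i, polygon=poly, phase="G1",
                        phase_entry_time=entry, target_area=SEED_AREA,
                        birth_area=SEED_AREA, cable=cable,
                        assigned_G1_duration=g1_dur)
        else:
            dur = draw_S_duration(rng, config.cycle)
            f = rng.uniform(0.0, 1.0)
            if config.cycle.growth_law == "exponential":
                birth = SEED_AREA / 2.0 ** f
            else:
                birth = SEED_AREA / (1.0 + f)
            n = Nucleus(id=i, polygon=poly, phase=phase,
                        phase_entry_time=t0 - f * dur,
                        target_area=SEED_AREA, birth_area=birth,
                        cable=cable, assigned_S_duration=dur)
        nuclei.append(n)
    state = SimulationState(t=t0, box=box, nuclei=nuclei, rng=rng,
                            next_id=n_total)
    # relax the seeded configuration to its first equilibrium
    minimize_state(state.box, state.nuclei, config.dt, config.mechanics)
    return state


def step(state: SimulationState, config: RunConfig):
    """Advance the state by one time step; returns the logged events.

    Cell-cycle updates run before the mechanical relaxation so that
    divisions and re-anchorings equilibrate within the same step.
    """
    # anchor the clock to step_index so long runs carry no float drift
    t_new = config.cycle.t_start + (state.step_index + 1) * config.dt
    events = []
    new_nuclei = []
    for n in state.nuclei:
        if not n.anchored and n.reanchor_time is not None \
                and t_new >= n.reanchor_time:
            events.extend(reanchor(n, t_new, state.box))
        update_target_area(n, t_new, config.cycle)
        evs, divide_now = advance_phase(
            n, t_new, state.box, config.cycle, state.rng,
            contact_tol=config.mechanics.contact_tol,
            gate_frac=config.mechanics.gate_frac)
        events.extend(evs)
        if divide_now:
            d1, d2, dev = divide(n, t_new, state.rng, config.cycle,
                                 state.next_id)
            state.next_id += 2
            events.extend(dev)
            new_nuclei.extend([d1, d2])
        else:
            new_nuclei.append(n)
    state.nuclei = new_nuclei
    info = minimize_state(state.box, state.nuclei, config.dt,
                          config.mechanics)
    if not info["feasible"]:
        warnings.warn(
            f"step at t={t_new:.2f} h left residuals above tolerance: "
            f"{info['residuals']}", stacklevel=2)
    state.t = t_new
    state.step_index += 1
    return events


def run(config: RunConfig, seed: int | None = None,
        output_dir=None, flush_every: int = 100) -> Trajectory:
    """One full simulation from t_start to t_end.

    Deterministic per (config, seed).  When ``output_dir`` is given,
    snapshots/events are flushed to disk periodically and a checkpoint
    of the full state is kept alongside, so an interrupted run can be
    resumed with :func:`resume`.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state = seed_initial_state(config, rng)
    return _run_loop(state, config, seed, [], [], [], output_dir,
                     flush_every)


def _run_loop(state, config, seed, snap_rows, event_rows, frame_rows,
              output_dir, flush_every) -> Trajectory:
    n_steps = int(round((config.cycle.t_end - config.cycle.t_start)
                        / config.dt))
    every = max(1, int(round(config.snapshot_every / config.dt)))
    out = Path(output_dir) if output_dir else None
    if state.step_index == 0:
        snap_rows.extend(_snapshot_rows(state))
        frame_rows.append(_frame_row(state))
    while state.step_index < n_steps:
        event_rows.extend(step(state, config))
        if state.step_index % every == 0 or state.step_index == n_steps:
            snap_rows.extend(_snapshot_rows(state))
            frame_rows.append(_frame_row(state))
        if out and state.step_index % flush_every == 0:
            _write_partial(out, config, seed, state, snap_rows,
                           event_rows, frame_rows)
    # arrest bookkeeping: G2 entries that never reached division
    for n in state.nuclei:
        if n.phase == "G2":
            c = n.polygon.mean(axis=0)
            event_rows.append({"time": state.t, "event": "ARREST",
                               "nucleus_id": n.id, "parent_id":
                               -1 if n.parent_id is None else n.parent_id,
                               "x": float(c[0]), "z": float(c[1])})
    snapshots = pd.DataFrame(snap_rows, columns=SNAPSHOT_COLUMNS)
    frames = pd.DataFrame(frame_rows, columns=FRAME_COLUMNS)
    events = pd.DataFrame(
        [[e["time"], e["event"], e["nucleus_id"], e["parent_id"],
          e["x"], e["z"]] for e in event_rows], columns=EVENT_COLUMNS)
    traj = Trajectory(snapshots=snapshots, frames=frames, events=events,
                      config=config, seed=seed)
    if out:
        traj.save(out)
        ckpt = out / "checkpoint.json"
        if ckpt.exists():
            ckpt.unlink()
    return traj


def _write_partial(out, config, seed, state, snap_rows, event_rows,
                   frame_rows):
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(snap_rows, columns=SNAPSHOT_COLUMNS).to_csv(
        out / "snapshots.csv", index=False)
    pd.DataFrame(
        [[e["time"], e["event"], e["nucleus_id"], e["parent_id"],
          e["x"], e["z"]] for e in event_rows],
        columns=EVENT_COLUMNS).to_csv(out / "events.csv", index=False)
    pd.DataFrame(frame_rows, columns=FRAME_COLUMNS).to_csv(
        out / "frames.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "checkpoint.json").write_text(
        json.dumps(_state_to_dict(state, seed)))


def _state_to_dict(state: SimulationState, seed: int) -> dict:
    return {
        "seed": seed, "t": state.t, "step_index": state.step_index,
        "next_id": state.next_id,
        "rng_state": state.rng.bit_generator.state,
        "box": {"grid_x": state.box.grid_x.tolist(),
                "heights": state.box.heights.tolist(),
                "wall_left": state.box.wall_left,
                "wall_right": state.box.wall_right,
                "rest_height": state.box.rest_height,
                "rest_wall_left": state.box.rest_wall_left,
                "rest_wall_right": state.box.rest_wall_right,
                "mitotic_zone_depth": state.box.mitotic_zone_depth},
        "nuclei": [{
            "id": n.id, "polygon": n.polygon.tolist(), "phase": n.phase,
            "phase_entry_time": n.phase_entry_time,
            "target_area": n.target_area, "birth_area": n.birth_area,
            "cable": (None if n.cable is None else
                      [n.cable.apical_x, n.cable.basal_x,
                       n.cable.active]),
            "anchored": n.anchored, "reanchor_time": n.reanchor_time,
            "assigned_S_duration": n.assigned_S_duration,
            "assigned_G1_duration": n.assigned_G1_duration,
            "parent_id": n.parent_id,
            "division_time_history": n.division_time_history,
        } for n in state.nuclei],
    }


def _state_from_dict(d: dict) -> tuple[SimulationState, int]:
    b = d["box"]
    box = Box(grid_x=np.asarray(b["grid_x"]),
              heights=np.asarray(b["heights"]),
              wall_left=b["wall_left"], wall_right=b["wall_right"],
              rest_height=b["rest_height"],
              rest_wall_left=b["rest_wall_left"],
              rest_wall_right=b["rest_wall_right"],
              mitotic_zone_depth=b["mitotic_zone_depth"])
    nuclei = []
    for nd in d["nuclei"]:
        cable = None
        if nd["cable"] is not None:
            cable = Cable(apical_x=nd["cable"][0], basal_x=nd["cable"][1],
                          active=nd["cable"][2])
        nuclei.append(Nucleus(
            id=nd["id"], polygon=np.asarray(nd["polygon"]),
            phase=nd["phase"], phase_entry_time=nd["phase_entry_time"],
            target_area=nd["target_area"], birth_area=nd["birth_area"],
            cable=cable, anchored=nd["anchored"],
            reanchor_time=nd["reanchor_time"],
            assigned_S_duration=nd["assigned_S_duration"],
            assigned_G1_duration=nd["assigned_G1_duration"],
            parent_id=nd["parent_id"],
            division_time_history=nd["division_time_history"]))
    rng = np.random.default_rng()
    rng.bit_generator.state = d["rng_state"]
    state = SimulationState(t=d["t"], box=box, nuclei=nuclei, rng=rng,
                            step_index=d["step_index"],
                            next_id=d["next_id"])
    return state, d["seed"]


def resume(output_dir, flush_every: int = 100) -> Trajectory:
    """Resume an interrupted run from its last checkpoint."""
    out = Path(output_dir)
    config = RunConfig.from_yaml(out / "config.yaml")
    state, seed = _state_from_dict(
        json.loads((out / "checkpoint.json").read_text()))
    snaps = pd.read_csv(out / "snapshots.csv")
    snaps = snaps[snaps["time"] <= state.t + 1e-9]
    events = pd.read_csv(out / "events.csv")
    events = events[events["time"] <= state.t + 1e-9]
    frames = pd.read_csv(out / "frames.csv")
    frames = frames[frames["time"] <= state.t + 1e-9]
    snap_rows = snaps.values.tolist()
    event_rows = events.to_dict("records")
    frame_rows = frames.values.tolist()
    return _run_loop(state, config, seed, snap_rows, event_rows,
                     frame_rows, out, flush_every)


def run_ensemble(config: RunConfig, n: int | None = None,
                 base_seed: int | None = None, output_dir=None) -> list:
    """Run n independent replicates with seeds base, base+1, ….

    Replicates are mutually independent (results do not depend on
    execution order); per-replicate failures are isolated and reported,
    the remaining replicates still run.
    """
    n = config.n_replicates if n is None else n
    if n < 1:
        raise ConfigError("ensemble size must be >= 1")
    base = config.seed if base_seed is None else base_seed
    out = Path(output_dir) if output_dir else None
    trajectories = []
    failures = []
    for i in range(n):
        try:
            d = out / f"replicate_{i:03d}" if out else None
            trajectories.append(run(config, seed=base + i, output_dir=d))
        except Exception as exc:   # noqa: BLE001 - isolate replicate failure
            failures.append((base + i, repr(exc)))
    if failures:
        warnings.warn(f"{len(failures)} replicate(s) failed: {failures}",
                      stacklevel=2)
    if not trajectories:
        raise RuntimeError(f"all replicates failed: {failures}")
    return trajectories
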