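"""Cell-cycle state machine layered on the nuclear mechanics.

Phases follow the fixed order G1 → S → G2 → M → division → G1.  S and
(in timer mode) G1 durations are assigned a priori; G2 duration is an
*output* of the model: a G2 nucleus only becomes mitotic once it has
physically reached the apical surface (the apical gate), so crowding
lengthens G2.  In ``basal_gate`` mode, G1 duration is also an output:
S entry additionally requires the nucleus to lie within range λ (in
G1∅) of the basal surface, the hypothesized basal signal.

Nuclei double in area during S phase only; at division the mother's
area is split exactly in half, one daughter (chosen by a fair coin)
inherits the mother's apical/basal cable and the other re-establishes
its anchors after a 6- or 12-minute delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as SPolygon
from shapely.geometry.polygon import orient as _orient

from . import geometry as geo
from .mechanics import Box, Cable, apical_contact

PHASES = ("G1", "S", "G2", "M")
#: successor of each phase in the cycle automaton
PHASE_ORDER = {"G1": "S", "S": "G2", "G2": "M", "M": "G1"}


class CycleError(RuntimeError):
    """Inconsistent cell-cycle bookkeeping."""


@dataclass
class CycleParams:
    """Cell-cycle timings and gate configuration (times in hours).

    ``mode`` selects the S-entry rule: ``timer`` assigns G1 a duration
    ramping from ``G1_start`` at the start of the simulation to
    ``G1_end`` at its end; ``basal_gate`` makes S entry conditional on
    basal proximity within ``lam`` (λ, in G1∅).
    """

    mode: str = "timer"
    S_mean: float = 8.0
    S_halfwidth: float = 2.0
    S_distribution: str = "uniform"   # or "gaussian"
    G1_start: float = 2.0
    G1_end: float = 10.0
    lam: float = 2.0
    M_duration: float = 0.5
    reanchor_delay_options: tuple = (0.1, 0.2)   # 6 or 12 min
    t_start: float = 72.0
    t_end: float = 116.0
    growth_law: str = "linear"        # S-phase area growth: linear|exponential

    def __post_init__(self):
        if self.mode not in ("timer", "basal_gate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "basal_gate" and not self.lam > 0:
            raise ValueError("basal_gate mode requires λ > 0")


@dataclass
class Nucleus:
    """One nucleus: geometry plus cell-cycle and lineage bookkeeping."""

    id: int
    polygon: np.ndarray
    phase: str
    phase_entry_time: float
    target_area: float
    birth_area: float
    cable: Cable | None = None
    anchored: bool = True
    reanchor_time: float | None = None
    assigned_S_duration: float | None = None
    assigned_G1_duration: float | None = None
    parent_id: int | None = None
    division_time_history: list = field(default_factory=list)

    def centroid(self) -> np.ndarray:
        return geo.polygon_centroid(self.polygon)

    def copy(self) -> "Nucleus":
        return Nucleus(
            id=self.id, polygon=self.polygon.copy(), phase=self.phase,
            phase_entry_time=self.phase_entry_time,
            target_area=self.target_area, birth_area=self.birth_area,
            cable=self.cable.copy() if self.cable else None,
            anchored=self.anchored, reanchor_time=self.reanchor_time,
            assigned_S_duration=self.assigned_S_duration,
            assigned_G1_duration=self.assigned_G1_duration,
            parent_id=self.parent_id,
            division_time_history=list(self.division_time_history))


def draw_S_duration(rng: np.random.Generator,
                    params: CycleParams) -> float:
    """Draw one S-phase duration, 8 ± 2 h by default.

    ``uniform`` draws on [mean − halfwidth, mean + halfwidth];
    ``gaussian`` draws N(mean, halfwidth/2) truncated to the same
    interval (both readings keep the support strictly positive).
    """
    lo = params.S_mean - params.S_halfwidth
    hi = params.S_mean + params.S_halfwidth
    if params.S_distribution == "uniform":
        return float(rng.uniform(lo, hi))
    if params.S_distribution == "gaussian":
        if params.S_halfwidth == 0:
            return float(params.S_mean)
        for _ in range(100):
            d = rng.normal(params.S_mean, params.S_halfwidth / 2.0)
            if lo <= d <= hi:
                return float(d)
        return float(params.S_mean)
    raise ValueError(f"unknown S_distribution {params.S_distribution!r}")


def g1_duration_at(t: float, params: CycleParams) -> float:
    """Timer-mode G1 duration: linear ramp over the simulated interval."""
    if t < params.t_start or t > params.t_end:
        warnings.warn(f"time {t} outside [{params.t_start}, {params.t_end}]; "
                      "clamping for the G1 ramp", stacklevel=2)
        t = min(max(t, params.t_start), params.t_end)
    frac = (t - params.t_start) / (params.t_end - params.t_start)
    return params.G1_start + frac * (params.G1_end - params.G1_start)


def update_target_area(n: Nucleus, t: float, params: CycleParams) -> float:
    """Grow the target area during S phase only; other phases unchanged.

    Area ramps from the birth area to twice the birth area across the
    assigned S duration (linear in time by default), capped at the
    doubled value.
    """
    if n.phase == "S":
        frac = np.clip((t - n.phase_entry_time) / n.assigned_S_duration,
                       0.0, 1.0)
        if params.growth_law == "linear":
            n.target_area = n.birth_area * (1.0 + frac)
        elif params.growth_law == "exponential":
            n.target_area = n.birth_area * 2.0 ** frac
        else:
            raise ValueError(f"unknown growth_law {params.growth_law!r}")
    return n.target_area


def basal_signal_gate(n: Nucleus, box: Box, lam: float) -> bool:
    """True iff the nucleus lies within λ (G1∅) of the basal surface."""
    return bool(np.min(n.polygon[:, 1]) <= lam)


def _event(t, kind, n, parent_id=None):
    c = n.polygon.mean(axis=0)
    return {"time": float(t), "event": kind, "nucleus_id": int(n.id),
            "parent_id": -1 if parent_id is None else int(parent_id),
            "x": float(c[0]), "z": float(c[1])}


def advance_phase(n: Nucleus, t: float, box: Box, params: CycleParams,
                  rng: np.random.Generator, contact_tol: float = 0.05,
                  gate_frac: float = 0.5):
    """Apply at most one phase transition to a nucleus at time ``t``.

    Returns ``(events, divide_now)``: the list of logged transition
    events and whether the nucleus has completed M and must divide.
    Transitions follow the fixed order of the automaton:

    * G1→S on timer expiry (timer mode) or basal-signal contact
      (basal_gate mode); the S duration is drawn on entry.
    * S→G2 when the assigned S duration has elapsed (the target area is
      then exactly the doubled birth area).
    * G2→M when the nucleus's edge reaches the apical surface (the
      apical gate); the cable is inactivated so the nucleus rounds up.
      G2 has no timer: its duration is an output of the model.
    * M → division after ``M_duration``.
    """
    if n.phase not in PHASES:
        raise CycleError(f"nucleus {n.id} in unknown phase {n.phase!r}")
    events = []
    elapsed = t - n.phase_entry_time
    if n.phase == "G1":
        ready = (elapsed >= n.assigned_G1_duration
                 if params.mode == "timer"
                 else basal_signal_gate(n, box, params.lam))
        if ready:
            n.phase = "S"
            n.phase_entry_time = t
            n.assigned_S_duration = draw_S_duration(rng, params)
            events.append(_event(t, "G1S", n))
    elif n.phase == "S":
        if n.assigned_S_duration is None:
            raise CycleError(f"S nucleus {n.id} has no assigned duration")
        if elapsed >= n.assigned_S_duration:
            n.phase = "G2"
            n.phase_entry_time = t
            n.target_area = 2.0 * n.birth_area
            events.append(_event(t, "SG2", n))
    elif n.phase == "G2":
        if (n.cable is not None and n.cable.active
                and apical_contact(n.polygon, box, contact_tol,
                                   gate_frac)):
            n.phase = "M"
            n.phase_entry_time = t
            n.cable.active = False   # mitotic rounding
            events.append(_event(t, "G2M", n))
    elif n.phase == "M":
        if elapsed >= params.M_duration:
            return events, True
    return events, False


def _half_polygons(poly: np.ndarray):
    """Split a polygon by the vertical line through its centroid.

    The division plane is perpendicular to the apical surface.  Each
    half is re-polygonized to 20 vertices at equal arc length along its
    boundary and rescaled to exactly half the mother's area.
    """
    area = geo.polygon_area(poly)
    sp = geo.to_shapely(poly)
    lo = float(poly[:, 0].min()) - 1.0
    hi = float(poly[:, 0].max()) + 1.0
    zlo = float(poly[:, 1].min()) - 1.0
    zhi = float(poly[:, 1].max()) + 1.0
    # plane through the centroid; fall back to the x-extent midpoint if
    # one half degenerates (centroid grazing the boundary of a highly
    # deformed mother)
    candidates = [float(geo.polygon_centroid(poly)[0]),
                  0.5 * (poly[:, 0].min() + poly[:, 0].max())]
    for cx in candidates:
        left = sp.intersection(SPolygon([(lo, zlo), (cx, zlo), (cx, zhi),
                                         (lo, zhi)]))
        right = sp.intersection(SPolygon([(cx, zlo), (hi, zlo), (hi, zhi),
                                          (cx, zhi)]))
        halves = []
        for h in (left, right):
            if h.geom_type == "MultiPolygon":
                h = max(h.geoms, key=lambda gg: gg.area)
            if h.is_empty or h.area < 1e-3 * area:
                halves = None
                break
            h = _orient(h, 1.0)
            coords = np.asarray(h.exterior.coords)[:-1]
            p20 = geo.resample_to_20(coords)
            halves.append(geo.scale_to_area(p20, area / 2.0))
        if halves is not None:
            return halves[0], halves[1]
    raise geo.GeometryError(
        "division plane produced a degenerate daughter")


def divide(n: Nucleus, t: float, rng: np.random.Generator,
           params: CycleParams, id_start: int):
    """Divide an M-phase nucleus into two G1 daughters.

    The daughters' areas sum exactly to the mother's; exactly one
    (fair coin) inherits the mother's cable and stays anchored, the
    other is unanchored and re-establishes contacts after a delay drawn
    uniformly from the 6/12-minute options.  Basal-ward descent of the
    daughters is passive: no active force is applied.
    """
    if n.phase != "M":
        raise CycleError(f"divide() called on {n.phase} nucleus {n.id}")
    pl, pr = _half_polygons(n.polygon)
    half = geo.polygon_area(n.polygon) / 2.0
    first_inherits = bool(rng.random() < 0.5)
    delay = float(rng.choice(np.asarray(params.reanchor_delay_options)))
    daughters = []
    for k, poly in enumerate((pl, pr)):
        inherits = (k == 0) == first_inherits
        if inherits and n.cable is not None:
            cable = n.cable.copy()
            cable.active = True
        else:
            cable = None
        d = Nucleus(
            id=id_start + k, polygon=poly, phase="G1",
            phase_entry_time=t, target_area=half, birth_area=half,
            cable=cable, anchored=cable is not None,
            reanchor_time=None if cable is not None else t + delay,
            assigned_G1_duration=(g1_duration_at(t, params)
                                  if params.mode == "timer" else None),
            parent_id=n.id,
            division_time_history=n.division_time_history + [t])
        daughters.append(d)
    events = [_event(t, "DIVISION", d, parent_id=n.id) for d in daughters]
    return daughters[0], daughters[1], events


def reanchor(n: Nucleus, t: float, box: Box):
    """Re-establish a vertical cable at the daughter's current position."""
    c = n.polygon.mean(axis=0)
    n.cable = Cable(apical_x=float(c[0]), basal_x=float(c[0]), active=True)
    n.anchored = True
    n.reanchor_time = None
    return [_event(t, "REANCHOR", n)]
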