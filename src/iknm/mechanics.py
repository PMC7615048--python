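"""Energies, constraints and the per-step constrained minimization.

The tissue is a 2D elastic box containing deformable 20-gon nuclei.
Each nucleus is tethered to a virtual apical-to-basal *cable* whose
basal anchor slides freely along the basal surface; G2 nuclei are in
addition pulled apically by a zero-rest-length spring between their
center of mass and the cable's apical anchor.  At every time step the
system is advanced to the next mechanical equilibrium by minimizing a
total energy

    E = E_box + Σ E_deform + Σ E_cable + Σ E_spring + E_gradient_flow
        + stiff penalty terms for the constraints,

subject to (as penalties / projections): no nucleus-nucleus or
nucleus-box overlap, conservation of each nucleus's target area,
nuclear convexity, and exclusion of non-mitotic nuclei from the apical
mitotic zone.  The gradient-flow term ``η/(2 dt) Σ |v − v_prev|²``
makes each step an implicit-Euler gradient flow and bounds per-step
displacements.

Degrees of freedom of one minimization: all nucleus vertices, the basal
anchor x of every active cable, the apical boundary control heights,
and the two lateral wall positions.  Gradients are analytic throughout
(validated against central differences in the test suite) and the
minimization uses L-BFGS-B, which only accepts descent steps, so the
energy of the returned state never exceeds that of the unmoved
candidate — except on the rare steps where an explicit geometric
repair (exact-area projection, un-nesting of deeply overlapping
nuclei, reversion of a collapsed polygon) intervenes; those are
flagged as ``geometry_repaired`` in the solver info.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize as _scipy_minimize

from . import geometry as geo
from .geometry import N_VERTICES, GeometryError


@dataclass
class Cable:
    """Virtual apical-to-basal cable confining one nucleus laterally.

    ``apical_x`` is held at a fixed lateral position (the apical anchor
    sits on the apical boundary at that x); ``basal_x`` is a free
    variable of the minimization, letting nuclei slide past each other.
    """

    apical_x: float
    basal_x: float
    active: bool = True

    def copy(self) -> "Cable":
        return Cable(self.apical_x, self.basal_x, self.active)


@dataclass
class Box:
    """The deformable tissue boundary.

    The basal line ``z = 0`` is rigid.  The apical boundary is a
    piecewise-linear chain of control heights on a fixed lateral grid;
    the lateral walls are elastic about their rest positions.  The
    mitotic zone is the band within ``mitotic_zone_depth`` (G1∅) below
    the apical boundary; only M-phase nuclei may occupy it.
    """

    grid_x: np.ndarray
    heights: np.ndarray
    wall_left: float
    wall_right: float
    rest_height: float
    rest_wall_left: float
    rest_wall_right: float
    mitotic_zone_depth: float = 0.5

    @classmethod
    def create(cls, width: float = 5.0, height: float = 3.0,
               mitotic_zone_depth: float = 0.5, grid_spacing: float = 0.5,
               grid_span: float = 12.0) -> "Box":
        """Box at rest: walls at 0 and ``width``, flat apical boundary.

        The control grid spans ``[-grid_span, width + grid_span]`` so the
        chain keeps covering the tissue as the walls are pushed outward
        by growth.
        """
        lo = -grid_span
        hi = width + grid_span
        n = int(round((hi - lo) / grid_spacing)) + 1
        grid = np.linspace(lo, hi, n)
        return cls(grid_x=grid, heights=np.full(n, float(height)),
                   wall_left=0.0, wall_right=float(width),
                   rest_height=float(height), rest_wall_left=0.0,
                   rest_wall_right=float(width),
                   mitotic_zone_depth=float(mitotic_zone_depth))

    def apical_height(self, x):
        """Apical boundary height at lateral position(s) ``x``."""
        return np.interp(x, self.grid_x, self.heights)

    @property
    def width(self) -> float:
        return self.wall_right - self.wall_left

    def copy(self) -> "Box":
        return replace(self, grid_x=self.grid_x.copy(),
                       heights=self.heights.copy())

    def to_shapely(self):
        """Interior of the box as a shapely polygon (CCW)."""
        from shapely.geometry import Polygon as SPolygon
        xs = self.grid_x
        inner = (xs > self.wall_left) & (xs < self.wall_right)
        top_x = np.concatenate([[self.wall_left], xs[inner], [self.wall_right]])
        top_z = self.apical_height(top_x)
        pts = [(self.wall_left, 0.0), (self.wall_right, 0.0)]
        pts += list(zip(top_x[::-1], top_z[::-1]))
        return SPolygon(pts)


@dataclass
class MechanicalParams:
    """Stiffnesses and solver controls.

    All stiffness units are energy per G1∅² (quadratic forms in lengths
    measured in G1∅).  Defaults are the frozen calibrated configuration
    used for the shipped experiments; every value can be overridden
    through the run configuration.
    """

    k_deform: float = 1.0        # nuclear shape regularization (edge springs)
    k_bend: float = 3.0          # second-neighbor chord springs (anti-buckling)
    k_cable: float = 1.0         # cable-to-nuclei energy
    k_spring: float = 1.5        # apical pulling spring (G2 only)
    k_box_apical: float = 0.02   # apical control-height elasticity (per point)
    k_box_curv: float = 0.5      # second-difference smoothing of the chain
    k_box_lateral: float = 0.25  # lateral wall elasticity
    eta: float = 0.15            # gradient-flow friction coefficient
    k_overlap: float = 1000.0    # quadratic overlap-area penalty
    k_overlap_lin: float = 500.0  # contact pressure (linear overlap term)
    overlap_eps: float = 1e-4    # C¹ smoothing scale of the pressure onset
    k_area: float = 2500.0       # target-area equality penalty
    k_convex: float = 2500.0     # convexity penalty
    convex_margin: float = 0.15  # penalty onset, fraction of rest cross
    k_mz: float = 3.0            # mitotic-zone repulsion of non-M nuclei
    tol_constraint: float = 1e-3  # feasibility tolerance (G1∅²)
    contact_tol: float = 0.05    # apical-contact detection tolerance (G1∅)
    gate_frac: float = 0.5       # zone penetration fraction for the M gate
    max_iter: int = 200          # L-BFGS iterations per minimization
    max_repair_rounds: int = 2   # penalty-stiffening rounds if infeasible


# ---------------------------------------------------------------------------
# public single-object energy operations
# ---------------------------------------------------------------------------

def rest_edge_length(target_area: float) -> float:
    """Edge length of the regular 20-gon with the given area."""
    n = N_VERTICES
    return float(np.sqrt(4.0 * target_area * np.tan(np.pi / n) / n))


def deformation_energy(poly: np.ndarray, target_area: float,
                       k_deform: float) -> float:
    """Edge-spring energy about the regular rest 20-gon of the target area.

    Zero for the regular 20-gon at the target area; grows quadratically
    with edge-length deviations, penalizing both shape distortion and
    area change.
    """
    l0 = rest_edge_length(target_area)
    ell = geo.edge_lengths(poly)
    return 0.5 * k_deform * float(np.sum((ell - l0) ** 2))


def cable_energy(poly: np.ndarray, cable: Cable, box: Box,
                 k_cable: float) -> float:
    """Quadratic attraction of all vertices to the apical-basal cable.

    Returns 0 when the cable is inactive (mitotic rounding).
    """
    if not cable.active:
        return 0.0
    a = np.array([cable.apical_x, float(box.apical_height(cable.apical_x))])
    b = np.array([cable.basal_x, 0.0])
    if np.allclose(a, b):
        raise GeometryError("degenerate cable: coincident anchors")
    d2 = [geo.point_segment_distance(v, a, b) ** 2 for v in poly]
    return 0.5 * k_cable * float(np.sum(d2))


def apical_contact(poly: np.ndarray, box: Box, contact_tol: float,
                   gate_frac: float = 0.5) -> bool:
    """True if the nucleus's edge has reached the apical surface.

    Contact is detected when the highest vertex has pushed a fraction
    ``gate_frac`` of the way through the mitotic zone (within
    ``contact_tol``).  The zone is a *soft* barrier: the apical spring
    must drive the leading edge into it against the zone repulsion and
    the subapical crowd, so the time from G2 entry to contact grows
    with crowding — the mechanism by which crowding lengthens G2.
    """
    x, z = poly[:, 0], poly[:, 1]
    gate = (np.asarray(box.apical_height(x))
            - (1.0 - gate_frac) * box.mitotic_zone_depth)
    return bool(np.any(z >= gate - contact_tol))


def apical_spring_energy(poly: np.ndarray, cable: Cable, box: Box,
                         phase: str, k_spring: float,
                         contact_tol: float = 0.05) -> float:
    """Zero-rest-length spring pulling a G2 nucleus toward its apical anchor.

    Active only in G2 and only until the nucleus reaches the apical
    surface; zero in every other phase.  The nuclear center of mass is
    taken as the vertex mean (indistinguishable from the area centroid
    for the near-regular convex 20-gons the model maintains).
    """
    if phase != "G2" or not cable.active:
        return 0.0
    if apical_contact(poly, box, contact_tol):
        return 0.0
    a = np.array([cable.apical_x, float(box.apical_height(cable.apical_x))])
    c = poly.mean(axis=0)
    return 0.5 * k_spring * float(np.sum((c - a) ** 2))


def box_energy(box: Box, params: MechanicalParams) -> float:
    """Elastic energy of the box about its rest configuration."""
    dh = box.heights - box.rest_height
    e = 0.5 * params.k_box_apical * float(np.sum(dh * dh))
    d2 = box.heights[:-2] - 2.0 * box.heights[1:-1] + box.heights[2:]
    e += 0.5 * params.k_box_curv * float(np.sum(d2 * d2))
    e += 0.5 * params.k_box_lateral * (
        (box.wall_left - box.rest_wall_left) ** 2
        + (box.wall_right - box.rest_wall_right) ** 2)
    return e


def gradient_flow_energy(prev_vertices, cand_vertices, eta: float,
                         dt: float) -> float:
    """Implicit-Euler friction: η/(2 dt) Σ |v − v_prev|² over all vertices."""
    prev = np.asarray(prev_vertices, dtype=float)
    cand = np.asarray(cand_vertices, dtype=float)
    if prev.shape != cand.shape:
        raise GeometryError("state topology mismatch in gradient flow energy")
    return 0.5 * eta / dt * float(np.sum((cand - prev) ** 2))


# ---------------------------------------------------------------------------
# packed full-system energy with analytic gradient
# ---------------------------------------------------------------------------

class _System:
    """Packs (nuclei, box) into one DOF vector and evaluates E, ∇E.

    Layout: [all vertices (N·20·2) | basal anchor x per active cable |
    apical control heights | wall_left | wall_right].
    Built once per minimization; the candidate-pair list for the overlap
    penalty and the spring/contact gating are frozen at build time so
    the objective is smooth during the solve.
    """

    def __init__(self, box: Box, nuclei, prev_vertices: np.ndarray,
                 dt: float, params: MechanicalParams,
                 pair_margin: float = 0.35):
        self.params = params
        self.dt = dt
        self.N = len(nuclei)
        self.grid_x = box.grid_x
        self.K = len(box.grid_x)
        self.dx = float(box.grid_x[1] - box.grid_x[0])
        self.rest_height = box.rest_height
        self.rest_wl = box.rest_wall_left
        self.rest_wr = box.rest_wall_right
        self.d_mz = box.mitotic_zone_depth
        self.V_prev = np.asarray(prev_vertices, dtype=float).reshape(
            self.N, N_VERTICES, 2)

        self.target_areas = np.array([n.target_area for n in nuclei])
        self.l0 = np.sqrt(4.0 * self.target_areas
                          * np.tan(np.pi / N_VERTICES) / N_VERTICES)
        self.phases = [n.phase for n in nuclei]
        self.has_cable = np.array(
            [n.cable is not None and n.cable.active for n in nuclei])
        self.cable_idx = np.flatnonzero(self.has_cable)
        self.apical_x = np.array(
            [nuclei[i].cable.apical_x for i in self.cable_idx])
        # anchor heights and the mitotic-zone reference are frozen at
        # step start: anchors and zone ride on the apical boundary
        # kinematically but do not load it
        self.apical_z = np.asarray(box.apical_height(self.apical_x),
                                   dtype=float).reshape(-1)
        self.h_frozen = box.heights.copy()
        self.n_cables = len(self.cable_idx)
        # M nuclei are exempt from the mitotic-zone repulsion
        self.mz_mask = np.array([p != "M" for p in self.phases])
        # spring gating frozen at step start
        self.spring_idx = []
        for j, i in enumerate(self.cable_idx):
            n = nuclei[i]
            if n.phase == "G2" and not apical_contact(
                    n.polygon, box, params.contact_tol,
                    params.gate_frac):
                self.spring_idx.append((i, j))

        # candidate pairs for the overlap penalty, from the start state
        C = self.V_prev.mean(axis=1)
        r = np.sqrt(((self.V_prev - C[:, None, :]) ** 2).sum(-1)).max(axis=1)
        d = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        close = d < (r[:, None] + r[None, :] + pair_margin)
        iu = np.triu_indices(self.N, k=1)
        sel = close[iu]
        self.pairs = np.column_stack([iu[0][sel], iu[1][sel]])

        self.nv = self.N * N_VERTICES * 2
        self.size = self.nv + self.n_cables + self.K + 2

    # -- packing -----------------------------------------------------------
    def pack(self, box: Box, nuclei) -> np.ndarray:
        x = np.empty(self.size)
        V = np.stack([n.polygon for n in nuclei]) if self.N else \
            np.zeros((0, N_VERTICES, 2))
        x[:self.nv] = V.ravel()
        x[self.nv:self.nv + self.n_cables] = [
            nuclei[i].cable.basal_x for i in self.cable_idx]
        x[self.nv + self.n_cables:self.nv + self.n_cables + self.K] = \
            box.heights
        x[-2] = box.wall_left
        x[-1] = box.wall_right
        return x

    def unpack(self, x: np.ndarray, box: Box, nuclei) -> None:
        V = x[:self.nv].reshape(self.N, N_VERTICES, 2)
        for i, n in enumerate(nuclei):
            n.polygon = V[i].copy()
        for j, i in enumerate(self.cable_idx):
            nuclei[i].cable.basal_x = float(x[self.nv + j])
        box.heights = x[self.nv + self.n_cables:
                        self.nv + self.n_cables + self.K].copy()
        box.wall_left = float(x[-2])
        box.wall_right = float(x[-1])

    # -- apical chain helpers ---------------------------------------------
    def _interp(self, h, xq):
        """Height, slope and hat-weight indices of the chain at xq."""
        idx = np.clip(np.searchsorted(self.grid_x, xq) - 1, 0, self.K - 2)
        w = np.clip((xq - self.grid_x[idx]) / self.dx, 0.0, 1.0)
        hq = h[idx] * (1.0 - w) + h[idx + 1] * w
        slope = (h[idx + 1] - h[idx]) / self.dx
        return hq, slope, idx, w

    # -- energy and gradient ----------------------------------------------
    def energy_grad(self, x: np.ndarray):
        """Total energy and analytic gradient; evaluated by a compiled
        kernel (the hot path of every minimization)."""
        p = self.params
        g = np.zeros_like(x)
        spr_n = np.array([i for (i, _) in self.spring_idx], dtype=np.int64)
        spr_j = np.array([j for (_, j) in self.spring_idx], dtype=np.int64)
        E = _energy_grad_kernel(
            x, g, self.V_prev.ravel(), self.N, self.K, self.n_cables,
            self.l0, self.target_areas,
            self.cable_idx.astype(np.int64), self.apical_x, self.apical_z,
            spr_n, spr_j,
            self.mz_mask.astype(np.bool_),
            self.pairs.astype(np.int64),
            float(self.grid_x[0]), self.dx, self.h_frozen,
            self.rest_height, self.rest_wl, self.rest_wr, self.d_mz,
            self.dt,
            p.k_deform, p.k_bend, p.k_cable, p.k_spring,
            p.k_box_apical, p.k_box_curv, p.k_box_lateral, p.eta,
            p.k_overlap, p.k_overlap_lin, p.overlap_eps,
            p.k_area, p.k_convex, p.convex_margin, p.k_mz)
        return E, g


@njit(cache=True)
def _energy_grad_kernel(x, g, Vprev, N, K, ncab, l0, Astar,
                        cab_nidx, cab_ax, cab_az, spr_n, spr_j,
                        mz_mask, pairs, grid0, dxg, h_frozen,
                        h0, wl0, wr0, dmz, dt,
                        kd, kb, kc, ks, kba, kbc, kbl, eta,
                        kov, klin, oveps, karea, kcx, cmargin, kmz):
    """Compiled total energy + gradient of the packed DOF vector.

    DOF layout: [vertices (N·20·2) | cable basal x (ncab) |
    apical heights (K) | wall_left | wall_right].  See the module
    docstring for the energy terms; the overlap term computes exact
    pairwise intersection areas by parametric edge clipping with
    Reynolds-transport gradients.
    """
    nv = 20
    nvert = N * nv * 2
    ihb = nvert + ncab            # first apical-height DOF
    iwl = nvert + ncab + K
    iwr = iwl + 1
    E = 0.0
    wl = x[iwl]
    wr = x[iwr]
    sin20 = np.sin(2.0 * np.pi / nv)
    cos_half = 2.0 * np.cos(np.pi / nv)
    fric = 0.5 * eta / dt

    for n in range(N):
        b = n * nv * 2
        l0n = l0[n]
        c0n = cos_half * l0n
        margin = cmargin * sin20 * l0n * l0n
        # shoelace area
        A = 0.0
        for j in range(nv):
            jn = (j + 1) % nv
            A += (x[b + 2 * j] * x[b + 2 * jn + 1]
                  - x[b + 2 * jn] * x[b + 2 * j + 1])
        A *= 0.5
        dA = A - Astar[n]
        E += 0.5 * karea * dA * dA
        cA = karea * dA
        for j in range(nv):
            jn = (j + 1) % nv
            j2 = (j + 2) % nv
            jp = (j - 1) % nv
            axv = x[b + 2 * j]
            azv = x[b + 2 * j + 1]
            bxv = x[b + 2 * jn]
            bzv = x[b + 2 * jn + 1]
            cxv = x[b + 2 * j2]
            czv = x[b + 2 * j2 + 1]
            # area gradient (shoelace)
            g[b + 2 * j] += cA * 0.5 * (bzv - x[b + 2 * jp + 1])
            g[b + 2 * j + 1] += cA * 0.5 * (x[b + 2 * jp] - bxv)
            # edge spring
            ex = bxv - axv
            ez = bzv - azv
            ell = np.sqrt(ex * ex + ez * ez)
            if ell < 1e-12:
                ell = 1e-12
            dl = ell - l0n
            E += 0.5 * kd * dl * dl
            f = kd * dl / ell
            g[b + 2 * j] -= f * ex
            g[b + 2 * j + 1] -= f * ez
            g[b + 2 * jn] += f * ex
            g[b + 2 * jn + 1] += f * ez
            # second-neighbor chord spring (anti-buckling)
            e2x = cxv - axv
            e2z = czv - azv
            ell2 = np.sqrt(e2x * e2x + e2z * e2z)
            if ell2 < 1e-12:
                ell2 = 1e-12
            dl2 = ell2 - c0n
            E += 0.5 * kb * dl2 * dl2
            f2 = kb * dl2 / ell2
            g[b + 2 * j] -= f2 * e2x
            g[b + 2 * j + 1] -= f2 * e2z
            g[b + 2 * j2] += f2 * e2x
            g[b + 2 * j2 + 1] += f2 * e2z
            # convexity with margin
            cr = (bxv - axv) * (czv - bzv) - (bzv - azv) * (cxv - bxv)
            neg = cr - margin
            if neg < 0.0:
                E += 0.5 * kcx * neg * neg
                cc = kcx * neg
                g[b + 2 * j] += cc * (bzv - czv)
                g[b + 2 * j + 1] += cc * (cxv - bxv)
                g[b + 2 * jn] += cc * (czv - azv)
                g[b + 2 * jn + 1] += cc * (axv - cxv)
                g[b + 2 * j2] += cc * (azv - bzv)
                g[b + 2 * j2 + 1] += cc * (bxv - axv)
            # gradient flow (friction)
            dvx = axv - Vprev[b + 2 * j]
            dvz = azv - Vprev[b + 2 * j + 1]
            E += fric * (dvx * dvx + dvz * dvz)
            g[b + 2 * j] += 2.0 * fric * dvx
            g[b + 2 * j + 1] += 2.0 * fric * dvz
            # containment and mitotic-zone repulsion
            # basal
            if azv < 0.0:
                E += 0.5 * kov * azv * azv
                g[b + 2 * j + 1] += kov * azv
            # lateral walls
            if axv < wl:
                v = wl - axv
                E += 0.5 * kov * v * v
                g[b + 2 * j] -= kov * v
                g[iwl] += kov * v
            if axv > wr:
                v = axv - wr
                E += 0.5 * kov * v * v
                g[b + 2 * j] += kov * v
                g[iwr] -= kov * v
            # apical chain (uniform grid interpolation)
            fi = (axv - grid0) / dxg
            idx = int(fi)
            if idx < 0:
                idx = 0
            if idx > K - 2:
                idx = K - 2
            w = fi - idx
            if w < 0.0:
                w = 0.0
            if w > 1.0:
                w = 1.0
            hq = x[ihb + idx] * (1.0 - w) + x[ihb + idx + 1] * w
            slope = (x[ihb + idx + 1] - x[ihb + idx]) / dxg
            if azv > hq:
                v = azv - hq
                E += 0.5 * kov * v * v
                g[b + 2 * j + 1] += kov * v
                g[b + 2 * j] -= kov * v * slope
                g[ihb + idx] -= kov * v * (1.0 - w)
                g[ihb + idx + 1] -= kov * v * w
            # mitotic-zone repulsion against the step-start boundary:
            # the zone rides the apical chain kinematically and does
            # not lift it, so the M gate cannot recede from a pushing
            # nucleus within a step
            hqf = h_frozen[idx] * (1.0 - w) + h_frozen[idx + 1] * w
            slopef = (h_frozen[idx + 1] - h_frozen[idx]) / dxg
            if mz_mask[n] and azv > hqf - dmz:
                v = azv - (hqf - dmz)
                E += 0.5 * kmz * v * v
                g[b + 2 * j + 1] += kmz * v
                g[b + 2 * j] -= kmz * v * slopef

    # cable-to-nuclei energy (envelope theorem for the clamped projection)
    for ci in range(ncab):
        n = cab_nidx[ci]
        b = n * nv * 2
        ax_ = cab_ax[ci]
        az_ = cab_az[ci]
        bx_ = x[nvert + ci]
        ddx = bx_ - ax_
        ddz = -az_
        L2 = ddx * ddx + ddz * ddz
        if L2 < 1e-12:
            L2 = 1e-12
        for j in range(nv):
            vxx = x[b + 2 * j]
            vzz = x[b + 2 * j + 1]
            t = ((vxx - ax_) * ddx + (vzz - az_) * ddz) / L2
            if t < 0.0:
                t = 0.0
            if t > 1.0:
                t = 1.0
            px = ax_ + t * ddx
            pz = az_ + t * ddz
            rx = vxx - px
            rz = vzz - pz
            E += 0.5 * kc * (rx * rx + rz * rz)
            g[b + 2 * j] += kc * rx
            g[b + 2 * j + 1] += kc * rz
            g[nvert + ci] += -kc * rx * t

    # apical pulling springs (G2, gated at step start)
    for si in range(len(spr_n)):
        n = spr_n[si]
        jj = spr_j[si]
        b = n * nv * 2
        cx_ = 0.0
        cz_ = 0.0
        for j in range(nv):
            cx_ += x[b + 2 * j]
            cz_ += x[b + 2 * j + 1]
        cx_ /= nv
        cz_ /= nv
        rx = cx_ - cab_ax[jj]
        rz = cz_ - cab_az[jj]
        E += 0.5 * ks * (rx * rx + rz * rz)
        for j in range(nv):
            g[b + 2 * j] += ks * rx / nv
            g[b + 2 * j + 1] += ks * rz / nv

    # box elasticity
    for kk in range(K):
        dh = x[ihb + kk] - h0
        E += 0.5 * kba * dh * dh
        g[ihb + kk] += kba * dh
    for kk in range(K - 2):
        d2 = x[ihb + kk] - 2.0 * x[ihb + kk + 1] + x[ihb + kk + 2]
        E += 0.5 * kbc * d2 * d2
        g[ihb + kk] += kbc * d2
        g[ihb + kk + 1] += -2.0 * kbc * d2
        g[ihb + kk + 2] += kbc * d2
    E += 0.5 * kbl * ((wl - wl0) ** 2 + (wr - wr0) ** 2)
    g[iwl] += kbl * (wl - wl0)
    g[iwr] += kbl * (wr - wr0)

    # exact pairwise overlap areas (parametric clipping + Reynolds)
    if len(pairs) > 0 and N > 0:
        # per-nucleus AABBs
        bb = np.empty((N, 4))
        for n in range(N):
            b = n * nv * 2
            x0 = x[b]
            x1 = x[b]
            z0 = x[b + 1]
            z1 = x[b + 1]
            for j in range(1, nv):
                vxx = x[b + 2 * j]
                vzz = x[b + 2 * j + 1]
                if vxx < x0:
                    x0 = vxx
                if vxx > x1:
                    x1 = vxx
                if vzz < z0:
                    z0 = vzz
                if vzz > z1:
                    z1 = vzz
            bb[n, 0] = x0
            bb[n, 1] = x1
            bb[n, 2] = z0
            bb[n, 3] = z1
        wa = np.zeros((2, nv))
        wb = np.zeros((2, nv))
        ts = np.empty(64)
        for pp in range(len(pairs)):
            na = pairs[pp, 0]
            nb = pairs[pp, 1]
            if (bb[na, 1] < bb[nb, 0] or bb[nb, 1] < bb[na, 0]
                    or bb[na, 3] < bb[nb, 2] or bb[nb, 3] < bb[na, 2]):
                continue
            A_int = 0.0
            for dirn in range(2):
                P = na if dirn == 0 else nb
                Q = nb if dirn == 0 else na
                bp = P * nv * 2
                bq = Q * nv * 2
                for j in range(nv):
                    wa[dirn, j] = 0.0
                    wb[dirn, j] = 0.0
                for j in range(nv):
                    jn = (j + 1) % nv
                    pax = x[bp + 2 * j]
                    paz = x[bp + 2 * j + 1]
                    pbx = x[bp + 2 * jn]
                    pbz = x[bp + 2 * jn + 1]
                    pdx = pbx - pax
                    pdz = pbz - paz
                    # vertex-in-host even-odd test for vertex j
                    cnt = 0
                    for e in range(nv):
                        en = (e + 1) % nv
                        qay = x[bq + 2 * e + 1]
                        qby = x[bq + 2 * en + 1]
                        if (qay > paz) != (qby > paz):
                            qax = x[bq + 2 * e]
                            qbx = x[bq + 2 * en]
                            xc = qax + (paz - qay) * (qbx - qax) \
                                / (qby - qay)
                            if pax < xc:
                                cnt += 1
                    inside = (cnt % 2) == 1
                    # crossings of this edge with the host boundary
                    m = 0
                    for e in range(nv):
                        en = (e + 1) % nv
                        qax = x[bq + 2 * e]
                        qaz = x[bq + 2 * e + 1]
                        qdx = x[bq + 2 * en] - qax
                        qdz = x[bq + 2 * en + 1] - qaz
                        denom = pdx * qdz - pdz * qdx
                        if denom > 1e-14 or denom < -1e-14:
                            relx = qax - pax
                            relz = qaz - paz
                            t = (relx * qdz - relz * qdx) / denom
                            u = (relx * pdz - relz * pdx) / denom
                            if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0 \
                                    and m < 64:
                                ts[m] = t
                                m += 1
                    # insertion sort of the m crossing parameters
                    for a1 in range(1, m):
                        key = ts[a1]
                        a2 = a1 - 1
                        while a2 >= 0 and ts[a2] > key:
                            ts[a2 + 1] = ts[a2]
                            a2 -= 1
                        ts[a2 + 1] = key
                    # walk the sub-intervals, flipping parity
                    t_prev = 0.0
                    par = inside
                    for c in range(m + 1):
                        t_next = ts[c] if c < m else 1.0
                        if par and t_next > t_prev + 1e-14:
                            I0 = t_next - t_prev
                            I1 = 0.5 * (t_next * t_next
                                        - t_prev * t_prev)
                            A_int += pdz * (pax * I0 + pdx * I1)
                            wa[dirn, j] += I0 - I1
                            wb[dirn, j] += I1
                        par = not par
                        t_prev = t_next
            if A_int <= 0.0:
                continue
            root = np.sqrt(A_int * A_int + oveps * oveps)
            E += klin * (root - oveps) + 0.5 * kov * A_int * A_int
            coef = klin * A_int / root + kov * A_int
            for dirn in range(2):
                P = na if dirn == 0 else nb
                bp = P * nv * 2
                for j in range(nv):
                    if wa[dirn, j] == 0.0 and wb[dirn, j] == 0.0:
                        continue
                    jn = (j + 1) % nv
                    pdx = x[bp + 2 * jn] - x[bp + 2 * j]
                    pdz = x[bp + 2 * jn + 1] - x[bp + 2 * j + 1]
                    g[bp + 2 * j] += coef * wa[dirn, j] * pdz
                    g[bp + 2 * j + 1] += coef * wa[dirn, j] * (-pdx)
                    g[bp + 2 * jn] += coef * wb[dirn, j] * pdz
                    g[bp + 2 * jn + 1] += coef * wb[dirn, j] * (-pdx)
    return E


def total_energy(box: Box, nuclei, prev_vertices, dt: float,
                 params: MechanicalParams) -> float:
    """Total system energy (including constraint penalties) of a candidate
    state, with the gradient-flow term measured against ``prev_vertices``."""
    sys_ = _System(box, nuclei, prev_vertices, dt, params)
    E, _ = sys_.energy_grad(sys_.pack(box, nuclei))
    return E


def total_energy_grad(box: Box, nuclei, prev_vertices, dt: float,
                      params: MechanicalParams):
    """Energy and its analytic gradient in the packed DOF vector."""
    sys_ = _System(box, nuclei, prev_vertices, dt, params)
    x = sys_.pack(box, nuclei)
    return sys_.energy_grad(x)


# ---------------------------------------------------------------------------
# constraints and minimization
# ---------------------------------------------------------------------------

@njit(cache=True)
def _poly_intersection_area(P, Q):
    """Intersection area of two simple polygons by parametric clipping.

    Same Green's-theorem construction as the overlap energy; shares its
    conventions (CCW input).  Used for fast post-step feasibility
    checks; agrees with shapely on valid input (asserted in tests).
    """
    A_int = 0.0
    ts = np.empty(64)
    for dirn in range(2):
        U = P if dirn == 0 else Q
        W = Q if dirn == 0 else P
        m_u = len(U)
        m_w = len(W)
        for j in range(m_u):
            jn = (j + 1) % m_u
            pax = U[j, 0]
            paz = U[j, 1]
            pdx = U[jn, 0] - pax
            pdz = U[jn, 1] - paz
            cnt = 0
            for e in range(m_w):
                en = (e + 1) % m_w
                qay = W[e, 1]
                qby = W[en, 1]
                if (qay > paz) != (qby > paz):
                    xc = W[e, 0] + (paz - qay) * (W[en, 0] - W[e, 0]) \
                        / (qby - qay)
                    if pax < xc:
                        cnt += 1
            inside = (cnt % 2) == 1
            m = 0
            for e in range(m_w):
                en = (e + 1) % m_w
                qax = W[e, 0]
                qaz = W[e, 1]
                qdx = W[en, 0] - qax
                qdz = W[en, 1] - qaz
                denom = pdx * qdz - pdz * qdx
                if denom > 1e-14 or denom < -1e-14:
                    relx = qax - pax
                    relz = qaz - paz
                    t = (relx * qdz - relz * qdx) / denom
                    u = (relx * pdz - relz * pdx) / denom
                    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0 and m < 64:
                        ts[m] = t
                        m += 1
            for a1 in range(1, m):
                key = ts[a1]
                a2 = a1 - 1
                while a2 >= 0 and ts[a2] > key:
                    ts[a2 + 1] = ts[a2]
                    a2 -= 1
                ts[a2 + 1] = key
            t_prev = 0.0
            par = inside
            for c in range(m + 1):
                t_next = ts[c] if c < m else 1.0
                if par and t_next > t_prev + 1e-14:
                    I0 = t_next - t_prev
                    I1 = 0.5 * (t_next * t_next - t_prev * t_prev)
                    A_int += pdz * (pax * I0 + pdx * I1)
                par = not par
                t_prev = t_next
    # the intersection cannot exceed either polygon; this also bounds
    # the degenerate exactly-coincident case, where on-boundary parity
    # tests are ill-defined
    a_p = 0.0
    a_q = 0.0
    for j in range(len(P)):
        jn = (j + 1) % len(P)
        a_p += P[j, 0] * P[jn, 1] - P[jn, 0] * P[j, 1]
    for j in range(len(Q)):
        jn = (j + 1) % len(Q)
        a_q += Q[j, 0] * Q[jn, 1] - Q[jn, 0] * Q[j, 1]
    bound = min(abs(a_p), abs(a_q)) * 0.5
    return min(max(A_int, 0.0), bound)


def _box_polygon_vertices(box: Box) -> np.ndarray:
    """CCW vertex array of the box interior for clipping checks."""
    xs = box.grid_x
    inner = (xs > box.wall_left) & (xs < box.wall_right)
    top_x = np.concatenate([[box.wall_left], xs[inner], [box.wall_right]])
    top_z = np.asarray(box.apical_height(top_x))
    pts = [(box.wall_left, 0.0), (box.wall_right, 0.0)]
    pts += list(zip(top_x[::-1], top_z[::-1]))
    return np.asarray(pts)


def constraint_residuals(box: Box, nuclei) -> dict:
    """Exact constraint residuals of a state.

    Returns the worst-case residuals: max pairwise overlap area, max
    protrusion area outside the box, max relative area deviation from
    target, worst convexity cross-product deficit (scale-free), and the
    box deformation magnitudes.
    """
    N = len(nuclei)
    max_overlap = 0.0
    if N > 1:
        C = np.stack([n.polygon.mean(axis=0) for n in nuclei])
        r = np.array([np.max(np.hypot(*(n.polygon - C[i]).T))
                      for i, n in enumerate(nuclei)])
        for i in range(N):
            for j in range(i + 1, N):
                if np.hypot(*(C[i] - C[j])) < r[i] + r[j]:
                    ov = _poly_intersection_area(nuclei[i].polygon,
                                                 nuclei[j].polygon)
                    max_overlap = max(max_overlap, ov)
    max_protrusion = 0.0
    max_area_dev = 0.0
    worst_convexity = 0.0
    if N:
        box_verts = _box_polygon_vertices(box)
        for n in nuclei:
            a = geo.polygon_area(n.polygon)
            inside_area = _poly_intersection_area(n.polygon, box_verts)
            max_protrusion = max(max_protrusion, max(a - inside_area, 0.0))
            max_area_dev = max(max_area_dev,
                               abs(a - n.target_area) / n.target_area)
            # convexity deficit in area units (cross product = twice
            # the signed triangle area), same units as tol_constraint
            deficit = max(-float(np.min(geo.cross_products(n.polygon)))
                          / 2.0, 0.0)
            worst_convexity = max(worst_convexity, deficit)
    return {
        "max_overlap": max_overlap,
        "max_protrusion": max_protrusion,
        "max_area_dev": max_area_dev,
        "worst_convexity": worst_convexity,
        "box_height_dev": float(np.max(np.abs(box.heights
                                              - box.rest_height))),
        "box_wall_dev": max(abs(box.wall_left - box.rest_wall_left),
                            abs(box.wall_right - box.rest_wall_right)),
    }


def _deep_overlap_pairs(nuclei, frac: float = 0.25):
    """Pairs whose overlap exceeds ``frac`` of the smaller nucleus.

    Deep interpenetration up to full containment is a gradient-dead
    state of the overlap-area penalty (translating a fully contained
    polygon does not change the intersection area), so it must be
    repaired geometrically rather than by stiffening penalties.
    """
    out = []
    N = len(nuclei)
    if N < 2:
        return out
    C = np.stack([n.polygon.mean(axis=0) for n in nuclei])
    r = np.array([np.max(np.hypot(*(n.polygon - C[i]).T))
                  for i, n in enumerate(nuclei)])
    for i in range(N):
        for j in range(i + 1, N):
            if np.hypot(*(C[i] - C[j])) < r[i] + r[j]:
                ov = _poly_intersection_area(nuclei[i].polygon,
                                             nuclei[j].polygon)
                amin = min(geo.polygon_area(nuclei[i].polygon),
                           geo.polygon_area(nuclei[j].polygon))
                if ov > frac * amin:
                    out.append((i, j))
    return out


def _unnest(nuclei, pairs):
    """Translate the smaller of each deeply overlapping pair so the
    bounding circles just touch (deterministic direction)."""
    for (i, j) in pairs:
        a, b = nuclei[i], nuclei[j]
        small, big = (a, b) if geo.polygon_area(a.polygon) <= \
            geo.polygon_area(b.polygon) else (b, a)
        cs = small.polygon.mean(axis=0)
        cb = big.polygon.mean(axis=0)
        d = cs - cb
        dist = float(np.hypot(*d))
        direction = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
        rs = float(np.max(np.hypot(*(small.polygon - cs).T)))
        rb = float(np.max(np.hypot(*(big.polygon - cb).T)))
        shift = (rs + rb - dist) * direction
        small.polygon = small.polygon + shift
        if small.cable is not None:
            small.cable.basal_x += float(shift[0])


def feasible(residuals: dict, tol: float) -> bool:
    """Feasibility verdict against ``tol_constraint`` (areas in G1∅²)."""
    return (residuals["max_overlap"] <= tol
            and residuals["max_protrusion"] <= tol
            and residuals["max_area_dev"] <= tol
            and residuals["worst_convexity"] <= tol)


def minimize_state(box: Box, nuclei, dt: float, params: MechanicalParams):
    """Advance (box, nuclei) to the next constrained energy minimum.

    Mutates ``box`` and the nuclei in place (polygons, cable basal
    anchors, box heights/walls) and returns an info dict with the
    solver diagnostics and final constraint residuals.  If the
    feasibility check fails after the first solve, the constraint
    penalties are stiffened and the solve repeated (up to
    ``max_repair_rounds``); persistent infeasibility is reported in the
    info dict, never raised, so long runs survive isolated stiff steps.
    """
    if not nuclei:
        return {"converged": True, "n_iter": 0,
                "residuals": constraint_residuals(box, nuclei),
                "feasible": True, "repair_rounds": 0,
                "geometry_repaired": False}
    prev = np.stack([n.polygon for n in nuclei])
    p = params
    info = {}
    repaired = False   # any geometric repair (projection/revert/unnest)
    for round_ in range(p.max_repair_rounds + 1):
        sys_ = _System(box, nuclei, prev, dt, p)
        x0 = sys_.pack(box, nuclei)
        res = _scipy_minimize(sys_.energy_grad, x0, jac=True,
                              method="L-BFGS-B",
                              options={"maxiter": p.max_iter,
                                       "ftol": 1e-12, "gtol": 1e-8})
        # guard: a diverged line search must not corrupt the state
        if not np.all(np.isfinite(res.x)):
            sys_.unpack(x0, box, nuclei)
            info = {"converged": False, "n_iter": int(res.nit),
                    "residuals": constraint_residuals(box, nuclei),
                    "feasible": False, "energy": np.nan,
                    "repair_rounds": round_, "geometry_repaired": True}
            break
        sys_.unpack(res.x, box, nuclei)
        # area projection: uniform rescale about the centroid, applied
        # only when the penalty equilibrium misses the tolerance (the
        # rescale can re-open small contacts, so it is a repair, not a
        # routine post-processing step)
        for i, n in enumerate(nuclei):
            a = geo.polygon_area(n.polygon) \
                if np.all(np.isfinite(n.polygon)) else np.nan
            if not np.isfinite(a) or a <= 1e-9:
                # collapsed or inverted under extreme local stress:
                # revert this nucleus to its pre-step shape
                n.polygon = prev[i].copy()
                a = geo.polygon_area(n.polygon)
                repaired = True
            if abs(a - n.target_area) > 0.95 * p.tol_constraint \
                    * n.target_area:
                n.polygon = geo.scale_to_area(n.polygon, n.target_area)
                repaired = True
        residuals = constraint_residuals(box, nuclei)
        ok = feasible(residuals, p.tol_constraint)
        info = {"converged": bool(res.success) or res.status == 1,
                "n_iter": int(res.nit), "residuals": residuals,
                "feasible": ok, "energy": float(res.fun),
                "repair_rounds": round_,
                "geometry_repaired": repaired}
        if ok or round_ == p.max_repair_rounds:
            break
        # deep interpenetration is gradient-dead for the area penalty:
        # repair geometrically before stiffening anything
        deep = _deep_overlap_pairs(nuclei)
        if deep:
            _unnest(nuclei, deep)
            repaired = True
            continue
        # stiffen only the violated constraints, so repairing one does
        # not escalate the forces that caused another
        tol = p.tol_constraint
        kw = {}
        if residuals["max_overlap"] > tol \
                or residuals["max_protrusion"] > tol:
            kw["k_overlap"] = p.k_overlap * 5.0
            kw["k_overlap_lin"] = p.k_overlap_lin * 5.0
        if residuals["max_area_dev"] > tol:
            kw["k_area"] = p.k_area * 5.0
        if residuals["worst_convexity"] > tol:
            kw["k_convex"] = p.k_convex * 5.0
        p = replace(p, **kw)
    return info
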