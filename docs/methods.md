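# Methods

## The model

`iknm` simulates interkinetic nuclear migration (IKNM) in a growing
pseudostratified epithelium — the *Drosophila* wing imaginal disc is the
motivating system — as an individual-based mechanical model in a 2D
cross-section. Nuclei are deformable convex 20-sided polygons inside an
elastic box whose basal line is rigid (z = 0), whose apical boundary is
a piecewise-linear elastic chain, and whose lateral walls are elastic.
All lengths are measured in G1∅, the diameter of a spherical G1-phase
nucleus (a seeded nucleus is a regular 20-gon of area π/4 G1∅²); time
is measured in hours AEL (after egg laying), and simulations span
72 → 116 h AEL.

Each nucleus is confined laterally by a virtual apical-to-basal
**cable** — a proxy for the cell membrane and cortex, which in a
pseudostratified epithelium connect both surfaces. The cable-to-nuclei
energy attracts all 20 vertices to the cable segment; the basal anchor
of the cable is a free variable of the minimization (nuclei can slide
past one another), while the apical anchor keeps a fixed lateral
position. G2 nuclei are additionally pulled apically by a
zero-rest-length spring from their center of mass to the cable's apical
anchor — an effective description of the active, actomyosin-driven
apical migration — inactivated when the edge of the nucleus reaches the
apical surface. A narrow apical **mitotic zone** (depth `d_mz`,
default 0.5 G1∅) repels all non-mitotic nuclei.

### Energies

At every time step the state (all nucleus vertices, cable basal
anchors, apical control heights, wall positions) is advanced to the
next constrained minimum of

E = E_box + Σ E_deform + Σ E_cable + Σ E_spring + E_flow + penalties

* **E_deform** — shape regularization of each nucleus about the regular
  20-gon of its current target area: linear springs on the 20 edges
  plus second-neighbor chord springs. Edge springs alone leave local
  buckling (dimple) modes soft; the chord springs make the convexity
  constraint hold at equilibrium instead of being an active penalty.
* **E_cable** — ½ k_cable Σ_v dist(v, cable)².
* **E_spring** — ½ k_spring |centroid − apical anchor|², G2 only, off
  after apical contact. The centroid here is the vertex mean; for the
  near-regular convex 20-gons the model maintains it differs from the
  area centroid by ≪ 10⁻³ G1∅, and it keeps the gradient exact.
* **E_box** — quadratic penalties on apical control heights about the
  rest height, a second-difference (curvature) smoothing term on the
  chain, and quadratic wall terms about the rest width.
* **E_flow** — the gradient-flow term η/(2 dt) Σ |v − v_prev|², which
  makes each step an implicit-Euler gradient flow and prevents large
  per-step movements; η sets the effective migration speed
  (free-climb speed ≈ k_spring·d/(20 η) per unit centroid-anchor
  distance d).

### Constraints

1. *No overlaps.* Nucleus-nucleus overlap is penalized by the **exact
   intersection area**: E = k_lin·A + ½ k·A² per close pair, with A
   computed by parametric edge clipping (Green's theorem over the
   boundary arcs of the intersection) and gradients from the Reynolds
   transport theorem. The linear term acts as a contact pressure that
   closes any overlap whose opposing forces are weaker than it; the
   smoothing scale `overlap_eps` makes the pressure C¹ at contact
   onset. Vertex-probe penalties were tried first and rejected: the
   minimizer learns to interdigitate vertices along the contact line or
   dent the host slightly concave, leaving large true overlap invisible
   to point probes. Nucleus-box containment uses one-sided quadratic
   penalties on protruding vertices (the box boundary is locally a
   half-plane, where probe penalties are sound).
2. *Area conservation.* Each nucleus's area is tied to its target by a
   stiff quadratic penalty; if the equilibrium still misses the
   tolerance the polygon is rescaled uniformly about its centroid
   (a repair, since rescaling can re-open small contacts).
3. *Convexity.* One-sided quadratic penalty on consecutive-edge cross
   products, switching on at a safety margin (`convex_margin`, a
   fraction of the rest-shape cross product) so equilibria stay
   strictly convex.
4. *Box deformation* is limited by E_box itself.

A feasibility check after every step verifies max pairwise overlap
area, protrusion area, relative area deviation and the convexity
deficit (worst negative cross product over two, i.e. the concave
triangle area) against `tol_constraint` (10⁻³; G1∅² except the
relative area deviation). On failure the violated constraint's
stiffness is multiplied by 5 and the step re-minimized (up to
`max_repair_rounds`); persistent failure is logged as a warning and
the best iterate kept, so long stochastic runs survive isolated stiff
steps.

The minimizer is L-BFGS-B with an analytic gradient (validated against
central differences in the test suite; the energy has measure-zero
kinks at contact changes and clamped cable projections). Per-step
energy descent is guaranteed by the line search; the explicit
geometric repairs (exact-area projection, un-nesting, collapse
reversion) may raise the energy by a bounded correction and are
flagged in the solver diagnostics, and the descent property is checked
on unrepaired steps. The energy and
gradient are evaluated by a numba-compiled kernel; a pure-numpy
evaluation was ~40× slower and made full-horizon ensembles impractical.
One deliberate simplification: the cable and spring **anchor heights
are frozen at step start**. If the anchors load the apical chain
through the energy gradient, the cables drag the apical boundary down
onto the nuclei and the box collapses; freezing makes the anchors ride
the boundary kinematically with a one-step lag (dt = 3 min).

## Cell cycle

Phases follow G1 → S → G2 → M → division. S lasts 8 ± 2 h (uniform on
[6, 10] h; a truncated-Gaussian reading is available via
`S_distribution`). In **timer** mode G1 lasts a pre-assigned duration
ramping linearly from 2 h at 72 h AEL to 10 h at 116 h AEL. In
**basal_gate** mode G1 has no timer: S entry requires the nucleus to
lie within λ (G1∅) of the basal surface, the hypothesized basal signal;
λ is expressed in G1 nuclear diameters. G2 has no timer in either mode:
a G2 nucleus becomes mitotic only when its edge reaches the apical
surface, so G2 duration is an output of the model.

The apical gate is implemented as penetration of the mitotic zone:
contact is declared when the nucleus's highest vertex has pushed a
fraction `gate_frac` (default ½) of the way through the zone. The zone
penalty is deliberately *soft* (`k_mz` of order the spring stiffness),
so the time from G2 entry to contact is set by how hard the leading
edge can grind through the zone against the subapical crowd — the
channel through which crowding lengthens G2 and slows the terminal
approach. Two related discretization choices matter here. First, the
zone is evaluated against the apical heights frozen at step start; if
the zone penalty loads the live chain, pushing nuclei lift the apical
boundary and the gate recedes indefinitely (a chase), whereas the
frozen zone lets contact resolve within a step while the boundary
still thickens through genuine containment contact. Second, the same
freezing applies to the cable and spring anchor heights (see above).

Nuclei double in target area during S only, linearly in time
(exponential growth available behind `growth_law`). On M entry the
cable is inactivated (mitotic rounding). After `M_duration` (default
30 min) the mother splits along the vertical line through its centroid
(perpendicular to the apical surface); each half is re-polygonized to
20 vertices at equal arc length and rescaled so the daughters' areas
sum exactly to the mother's. One daughter (fair coin) inherits the
mother's cable; the other re-establishes anchors after a delay drawn
uniformly from {6, 12} min and experiences no cable or spring force
until then. Basal-ward descent after division is passive: no downward
force is applied; daughters are displaced by incoming nuclei.

## Seeding and recording

A run seeds 10 nuclei (7 G1, 3 S, 0 G2 — the phase ratios of young
discs) on a jittered two-row grid in a box of rest width 5 G1∅ and
rest height 3 G1∅ (≈1–2 nuclear layers, the configuration of a young
disc; no reference values exist for them, so they are part of the
calibration). Seeded nuclei receive a random already-elapsed fraction
of their phase so the population starts asynchronous; for S nuclei the
birth area is set so the growth law reproduces the seeded area π/4 at
the seeded elapsed fraction. A single RNG stream per replicate feeds
every draw in documented order (placement jitter, phase assignment,
elapsed fractions, S durations, daughter coin, re-anchor delay), making
runs bit-reproducible from (config, seed).

Snapshots (one row per nucleus: time, id, phase, centroid, area,
min/max z, 20 serialized vertices) are recorded every 0.25 h — four
frames per hour, the cadence the terminal-velocity window requires —
together with per-frame summaries and a discrete event log (G1S, SG2,
G2M, DIVISION, REANCHOR, ARREST). Interrupted runs resume from a JSON
checkpoint containing the full state including the RNG.

## Statistics

All statistics are pure functions of (snapshots, events). Depth is
reported from the apical side (apical height − centroid z). The
three-way phase census counts M with G2 (a two-color cell-cycle
reporter cannot resolve M; switchable). Apical-basal distributions bin
centroid depths in half-open ½ G1∅ slices normalized by total nuclei.
The 2D crowding index expands a nucleus's bounding rectangle by
0.75 G1∅ laterally and 0.25 G1∅ apico-basally (mirroring the
anisotropic neighborhood of the 3D imaging analog), clips it to the
box, and divides the summed overlap area of other nuclei by the
rectangle area not occupied by the focal nucleus; nuclei whose expanded
rectangle crosses a lateral wall are excluded, as border nuclei are in
imaging. G2 durations pair each division with the mother's G2 entry;
G2 entries with no division by the end of the run are the cumulative
"G2-arrested" series (12 h bins); the two sets partition the G2 entries
exactly. Terminal velocity is the apical-ward centroid displacement of
the mother over the hour preceding each division, with a degree-3
least-squares polynomial trend for the begin/end ratio.

## Calibration

The stiffness ratios and friction are not stated in the source
material; the defaults were frozen by a one-time documented grid search
(`scripts/calibrate.py`) over the two dominant knobs — η (friction,
which sets migration speed) and k_spring (apical pull, which sets how
reliably deep nuclei climb through the crowd) — scoring full-horizon
runs against the model's operating point: beginning G2 fraction
≈ 17.9%, end ≈ 40.7%, rising G2 durations, terminal-velocity slowdown
≈ 1.5×. Strong springs make shallow G2 entries divide instantly and
deep ones arrest (falling G2-duration curves); weak springs lengthen
transits. The frozen defaults are in `MechanicalParams`; every value is
overridable through the run configuration.

## Problem sizes

Full-scale experiments are 20 replicates of 72 → 116 h (dt = 3 min),
matching the reference ensemble size; a full replicate takes minutes of CPU
and grows from 10 to ≈ 40–50 nuclei. The test suite and the acceptance
script use scaled study conditions, chosen as the smallest ensembles
whose sampling error still brackets the quantities under test: the
early-window ensembles use 5 replicates over 72 → 84 h (the
acceptance script uses the full 20), the full-horizon test ensemble
uses 2 replicates, and the two-gate λ-ordering comparison uses one
replicate per λ at the full horizon — the basal gate only
differentiates once the tissue outgrows the smaller λ, and the
full-horizon separation dwarfs the replicate-to-replicate spread.
Scaled replicate counts widen the ensemble SD used in the tolerance
checks accordingly.

## Known limitations

* 2D cross-section: out-of-plane neighbor exchange and 3D packing are
  absent, so absolute crowding values are not comparable to volumetric
  measurements; trends are.
* The supplementary formal model underlying the original simulator was
  not available; functional forms here are the simplest consistent
  with the stated energies and constraints, and quantitative agreement
  beyond the calibrated operating point is not guaranteed.
* The apical boundary is a height field (no folding or curvature of the
  disc), and the basal line is perfectly rigid and straight.
* Late in crowded runs the completed-G2-duration statistic is
  right-censored: deep G2 entries that would complete after the horizon
  are counted as arrested, biasing the last time bin downward. The
  reference statistic is subject to the same censoring.
* No apoptosis, no cell-size checkpoint, no explicit cytokinesis
  mechanics.
* In late, heavily crowded stretches of full-horizon runs a minority of
  steps end with the worst pairwise overlap marginally above the
  feasibility tolerance (typically 1–3× tol, ≈0.1–0.3% of a nucleus
  area): the growth forcing outpaces the per-step solver budget. The
  repair loop keeps these bounded; they do not accumulate or destabilize
  the run. Two hard failure modes are guarded explicitly: deeply nested
  nuclei (a gradient-dead state of the intersection-area penalty) are
  translated apart geometrically, and a diverged line search reverts
  the step.
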