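# iknm — interkinetic nuclear migration in a growing pseudostratified epithelium

`iknm` is an individual-based mechanical simulator of interkinetic
nuclear migration (IKNM): the apical-basal shuttling of nuclei in
pseudostratified epithelia, where mitosis is confined to the apical
surface. It is built for the *Drosophila* wing imaginal disc during
larval growth (72–116 h after egg laying), and for anyone asking how
nuclear crowding feeds back on cell-cycle progression: as the tissue
fills with nuclei, G2 nuclei take longer to reach the apical surface,
the G2 population swells, and some nuclei never divide at all.

## The model

Nuclei are deformable convex 20-gons in a 2D elastic box (rigid basal
line at z = 0, elastic apical chain, elastic lateral walls). All
lengths are in G1∅ — the diameter of a spherical G1 nucleus — and a
seeded nucleus is a regular 20-gon of area π/4 G1∅². Each time step
advances the state to the next constrained minimum of

```
E = E_box + Σ E_deform + Σ E_cable + Σ E_spring + η/(2Δt) Σ‖v − v_prev‖²
```

subject to: no nucleus-nucleus or nucleus-box overlap (exact
intersection-area penalties), conservation of each nucleus's target
area, convexity, and exclusion of non-mitotic nuclei from the apical
mitotic zone. The *cable* energy pulls a nucleus's vertices toward a
virtual apical-to-basal segment (the confining cell cortex; the basal
anchor slides freely); the *spring* pulls G2 nuclei apically until
their edge reaches the apical surface; the gradient-flow term makes
each step an implicit-Euler relaxation.

On the mechanics rides a cell-cycle state machine,
G1 → S → G2 → M → division: S lasts 8 ± 2 h, G1 ramps from 2 h to 10 h
(timer mode), nuclei double in area during S, and G2 ends only on
apical contact — its duration is an output, not an input. Division
splits the mother perpendicular to the apical surface; one daughter
keeps the mother's cable, the other re-anchors 6 or 12 min later. In
the two-gate variant (`basal_gate` mode) S entry additionally requires
the nucleus to come within range λ (in G1∅) of the basal surface, the
hypothesized basal signal; then G1 duration is an output too.

See `docs/methods.md` for the full formulation, parameter table,
calibration procedure and known limitations.

## Worked example

```python
import numpy as np
from iknm import RunConfig, run
from iknm import analysis

cfg = RunConfig.from_dict({"cycle": {"t_end": 84.0}})   # 72 -> 84 h AEL
traj = run(cfg, seed=1)

frames = traj.frames
last = frames.iloc[-1]
print(f"t = {last['time']:.1f} h: {int(last['n_total'])} nuclei, "
      f"apical height {last['apical_height']:.2f} G1-diam")

census = analysis.phase_fractions(traj, [72.0, 84.0])
print(census[["time", "fraction_G1", "fraction_S", "fraction_G2"]]
      .round(3).to_string(index=False))

per, series = analysis.g2_durations(traj.events)
print(f"{len(per)} completed G2 transits, "
      f"mean duration {per['duration'].mean():.2f} h")
```

prints

```
t = 84.0 h: 16 nuclei, apical height 3.00 G1-diam
 time  fraction_G1  fraction_S  fraction_G2
 72.0         0.70         0.3         0.00
 84.0         0.75         0.0         0.25
6 completed G2 transits, mean duration 3.03 h
```

The box was seeded with 10 nuclei (7 G1, 3 S, 0 G2 — the phase ratios
of young discs). Twelve simulated hours later the tissue has grown to
16 nuclei and G2 — absent at seeding — holds a quarter of them: the
crowding-driven shift the model exists to study. Each completed G2
transit lasted about 3 h at this early, still-uncrowded stage (by the
end of a full run the tissue is several layers deep and a growing
fraction of G2 nuclei never reach the apical surface at all).

The same machinery is scriptable from the shell:

```bash
iknm run --seed 1 --out out/run1            # one replicate, full horizon
iknm ensemble -n 20 --out out/ens           # the 20-replicate ensemble
iknm analyze out/run1 --out out/stats       # tidy statistic tables
iknm validate                                # property-based invariants
iknm reproduce timer --scaled --out report.json
iknm run --config my.yaml --mode basal_gate --lam 4 --seed 2 --out out/bg
```

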