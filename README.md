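# cutsim

Mesh-free simulation of migration and **cut-out** of proximal femoral
fixation devices — sliding hip screws and helical blades — in porous
polyurethane bone-surrogate foam, for biomechanics researchers comparing
implant designs on standardized bench models.

Cut-out (the head element of a fixation device penetrating through the
femoral head, operationalized as 7 mm of vertical construct displacement)
is a major failure mode of intertrochanteric fracture fixation in
osteoporotic bone. The package reproduces a standard benchtop rig in
silico: a machined 10 PCF polyurethane proximal femur (70 mm, Ø 40 mm
head, BV/TV 0.14) in a polished steel cortical shell that leaves the
distal 7.5 mm exposed for varus collapse, seated on a 28°-inclined base
so the implant axis sits 62° from vertical, loaded through a sliding
acetabulum by a plate until cut-out.

The model core:

* **Porous cloud** — the foam is a quasi-random cloud of uniform cubic
  particles (nominal 400 µm) at volume fraction BV/TV = 0.14; particle
  volume is cubic, V = count · r³. The implant cavity is carved by
  centroid membership (insertion is not simulated).
* **Material** — compressible neo-Hookean,
  W = (µ/2)(I₁−3) − µ ln J + (λ/2)(ln J)², with compact-polymer
  properties obtained from the overall foam values by the 8.5×
  bench-calibration coefficient (E_sd = 493 MPa, σ_ys = 18.70 MPa,
  σ_us = 19.64 MPa), derated 10 % for dynamic runs
  (σ_yd = 16.83 MPa, σ_ud = 17.67 MPa). Damage is a one-way
  elastic → yielding → failed machine on principal Cauchy stress with
  crush plasticity past yield.
* **Solver** — explicit total-Lagrangian mesh-free scheme with
  linear-completeness-corrected kernel gradients, penalty contact with
  Coulomb friction between the foam and the rigid metallic bodies, a
  prismatic (slide, no rotation) implant joint, and a prescribed 2 m/s
  plate ramp; the reaction is read at the fixed base like the bench
  load cell.
* **Analysis** — toe-in normalization, force at cut-out (linear
  extrapolation from the 3 mm slope for short records), damage volumes
  and 6 mm-radius density heatmaps, Lin's concordance correlation
  coefficient ρ_c = ρ·C_b for physical-vs-simulated curve pairs, and
  group statistics (pooled t-test / one-way ANOVA) from summary data.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

Run a reduced-resolution cut-out simulation of a screw-type proxy (scale
5 ⇒ 2 mm particles, about 10³ foam particles; a few minutes on one CPU):

```bash
cutsim simulate --implant screw --materials dynamic --scale 5 --seed 7 \
    --out runs/screw-demo
```

which logs, for this configuration:

```
assembled screw model: 977 foam particles
force at cut-out 2181.3 N; yielding 23 failed 536
```

(559 of 977 particles damaged: 23 still in the yielding state, 536
crushed past the ultimate stress) and writes `run_record.csv` (time,
plate displacement, base reaction force, yielding/failed counts),
damage-heatmap point clouds (`damage_heatmap.ply/.vtk`, neighbor counts
within 6 mm), and `damage_summary.json`. The force–displacement record
shows the cut-out phenomenology: a monotone loading phase, progressive
yielding and crushing around the implant, then migration at falling
force; at this coarse resolution the final half-millimeter of travel
shows a compaction artifact (documented in the methods note).

Compare physical force–displacement logs against a simulated record:

```bash
cutsim analyze --physical 'bench/*.csv' --simulated runs/screw-demo/run_record.csv
```

which prints per-specimen Lin concordance (ρ_c, ρ, C_b, 95 % CI) and the
group force-at-cut-out summary. `cutsim report` rebuilds the
device-comparison tables (simulated-vs-physical percent errors, damage
volumes and percent-vs-reference rows) from the packaged reference data;
`cutsim fixtures` writes small synthetic inputs.

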