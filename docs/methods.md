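# Methods

`cutsim` simulates migration and cut-out of proximal femoral fixation
devices (sliding hip screws and helical blades) in a porous polyurethane
bone surrogate, reproducing a standard benchtop rig: a machined foam
proximal femur (70 mm long, Ø 40 mm head) enclosed in a polished steel
cortical shell that leaves the distal 7.5 mm exposed for varus collapse,
seated on a steel base block whose top surface is inclined 28° above
horizontal so that the implant axis sits 62° from vertical — the
configuration in which a 135° sliding-hip-screw construct sees a
clinically representative walking force direction.  A hydraulic plate
loads the construct through a sliding acetabulum until cut-out, defined
as 7 mm of vertical displacement.

## Bone surrogate model

The foam is a cloud of uniform cubic particles of compact polymer and
void space.  The sampler is a stratified jittered lattice: one candidate
per cubic cell of edge `r` (nominal 400 µm), jittered by at most 0.25 r,
accepted with probability equal to the target volume fraction (BV/TV
0.14, the 10 PCF grade).  The measured volume fraction recovers the
target within binomial noise (±0.005 over seeds on a 20 mm cube);
placement is reproducible for a fixed seed; at volume fraction 1 the
sampler degenerates to the dense regular lattice used by the validation
benchmarks.  Particle volume is cubic (`r³`) — the convention all damage
volume reporting uses.  The direction-of-rise anisotropy of physical
foam is not modeled; the cloud is statistically isotropic.

Published foam properties (E = 58 MPa, σ_y = 2.2 MPa) describe the
porous structure as a whole.  Particles are assigned compact-polymer
properties instead: the overall values scaled by the bench-calibrated
8.5× correction coefficient (E_sd = 493 MPa, σ_ys = 18.70 MPa,
σ_us = 19.64 MPa; the overall ultimate stress is carried as 2.31 MPa so
the full-precision chain reproduces the tabulated static and dynamic
strengths under half-up rounding).  Dynamic (cyclic-equivalent) runs
derate yield and ultimate stress by 10 % (σ_yd = 16.83, σ_ud = 17.67);
the solver then applies a single monotone ramp — the cyclic schedule
exists for physical-data bookkeeping (cycle ↔ peak-force conversion,
double-peak waveform synthesis), not for time-domain cycling.

### Network compensation at reduced resolution

At the coarse desk-scale resolutions this package runs at (a global
`scale` factor multiplies every particle size; the test suite and the
acceptance script use scale 5, i.e. 2 mm foam particles, ≈10³
particles), the stratified-jitter cloud's bond network is markedly
softer than the published discretization: it retains only a few percent
of the compact-polymer stiffness, while the 8.5× coefficient implies
~12 % (58/493) at the published 400 µm resolution.  The assembly
pipeline therefore applies the same calibration logic as the original
coefficient, at its own discretization: particle modulus and strengths
are scaled by a factor computed once per (resolution, volume fraction,
support) so that the porous cloud's confined effective modulus matches
the overall-foam target M = E(1−ν)/((1+ν)(1−2ν)) with E = 58 MPa,
ν = 0.30.  The factor is measured from the confined-crush benchmark on a
small block, cached, and deterministic.  Yield strain is unaffected, so
relative strength is preserved.  The tabulated material values and the
8.5×/0.9× identities in `cutsim.materials` are untouched.

## Mesh-free solver

Total-Lagrangian nodal-integration scheme.  Reference neighborhoods use
a cubic-spline kernel with support 2.4× the mean particle spacing
(`r·VF^(−1/3)`); kernel gradients carry a linear-completeness correction
(the inverse moment matrix), so affine motions reproduce their
deformation gradient exactly, one-sided boundary neighborhoods included.
Internal nodal forces are the exact negative gradient of the discrete
strain energy for the compressible neo-Hookean law
W = (µ/2)(I₁−3) − µ ln J + (λ/2)(ln J)², hence momentum-conserving.  A
Ganzenmüller-style pairwise term (α = 10, deviation clamped at half the
reference pair length) suppresses the zero-energy modes of nodal
integration.

Integration is explicit symplectic Euler with a stable step taken as the
minimum of a CFL bound (spacing over wave speed), a contact-stiffness
bound, and a travel bound for prescribed bodies, with safety factor 0.5.
Light mass-proportional damping (1 % of critical at the characteristic
pair frequency) conditions the foam; rigid bodies are damped through
their contact dashpots only, because mass damping would resist the rigid
convection that the 2 m/s plate rate imposes.

### Damage model

Foam damage is a one-way three-state machine driven by principal Cauchy
stress (tension and compression both damaging — cut-out loads the foam
mainly in compression):

* **elastic → yielding** when the maximum-magnitude principal value of
  the trial elastic stress reaches σ_y;
* past yield the response is crush plasticity with H = 0: the deviatoric
  stress is capped on the von Mises surface while the hydrostatic part
  keeps building, so confined material densifies;
* **yielding → failed** when the maximum-magnitude principal value of
  the *capped* stress reaches σ_u;
* failed particles carry compressive principal components only (no
  tension or shear across open cracks), with a densification plateau cap
  at 3 σ_u so a single particle at the resolution limit cannot inject
  unbounded force; additionally, particle pairs involving a failed
  particle interact by short-range grain contact (penalty at 0.8 r with
  near-critical dashpot and Coulomb friction), which lets crushed
  regions keep transmitting compaction loads.

A simple trial-stress threshold is *not* viable here: the yield-to-
ultimate band (18.70 → 19.64 MPa) is only 5 % wide, so any continued
deformation would cross it within one step and granulate the cloud.
Metallic bodies are rigid; the maximum-principal-strain criterion of the
metal material models is exposed for post-processing, not used in the
dynamics.

### Rigid bodies, contacts and joints

Metallic components (implant proxy, shell, acetabulum, plate, base) are
rigid particle sets with translational dynamics only; varus motion
appears as foam shear plus shell translation rather than rigid rotation.
The base is fixed (the load cell — the recorded force channel is the
vertical reaction here); the plate is velocity-prescribed (2 m/s with a
0.25 ms smooth start); the implant is a prismatic joint along its own
axis (slide without rotation, mirroring the cannulated anti-rotation
insert), whose off-axis reaction is carried by the base; acetabulum and
shell float between penalty contacts.

Contact surfaces of rigid bodies are dense deterministic surface samples
(spacing 0.6 r).  Penalty contact acts between nearest point pairs:
normal force linear in overlap minus a near-critical dashpot (clamped
non-adhesive), friction as regularized Coulomb (µ = 0.3 steel–foam,
0.1 polished steel–steel; friction values are a modeling choice, not a
measured input).  Foam-side contacts carry one force per foam particle
with stiffness E·r; rigid–rigid interfaces carry one force per surface
sample with patch stiffness (E/r)·s², making interface stiffness
area-consistent regardless of sampling density.  Conforming interfaces —
the carved implant cavity (centroid rule: particles with centroids
inside the implant solid are removed, insertion is not simulated) and
the snug shell — start with interference up to half a particle; the
per-point initial overlaps are recorded at assembly and subtracted
(shrink-fit removal), with a 0.25 ms contact soft-start.

The kinetic-to-internal energy ratio is sampled at every record row and
a warning is logged above 5 % once the internal energy is appreciable:
at the 2 m/s surrogate rate the reduced-resolution runs are genuinely
semi-dynamic, and the warning marks that context on every record.

## Validation benchmarks

* **Confined crush.**  A volume-fraction-1 lattice block between rigid
  platens, laterally confined (uniaxial strain), driven quasi-statically
  with strong damping.  The transmitted force is compared with the
  closed-form confined neo-Hookean stress
  σ_zz = (µ(λ²−1) + Λ ln λ)/λ evaluated at the *measured bulk stretch*
  (mean F_zz over the mid-slab): nodal-integration discretizations carry
  a stiffened boundary row about one particle deep, so the platen
  displacement overstates the bulk strain by a resolution-dependent
  margin while the stress–stretch relation itself is reproduced to
  within ~2 % (tolerance 5 %) up to 5 % strain.
* **Effective modulus vs volume fraction.**  Small-strain confined
  stiffness of porous blocks grows monotonically over VF ∈ {0.07, 0.14,
  0.28}.
* **Oscillator and free-particle checks.**  A bonded particle pair
  oscillates at the frequency implied by the numerically differentiated
  pair stiffness (2 %); a free particle obeys F = ma to 10⁻⁶.

## End-to-end demonstrations

The demo runs (screw proxy vs blade proxy, scale 5, ~10³ foam particles,
single 2 m/s ramp to 7 mm) reproduce the cut-out phenomenology: a
monotone loading phase, progressive yielding/failure around the implant,
a force peak followed by migration at falling force.  Two
coarse-resolution artifacts are documented rather than hidden: (i) near
7 mm the shell rim (7.5 mm exposure) approaches the base plane and 2 mm
particles bridge the gap, producing a terminal compaction spike that the
400 µm discretization would not show; (ii) by 7 mm a large,
seed-dependent fraction of the small cloud (half to nearly all) has
damaged, so the screw-vs-blade spatial contrast (damage concentrated at
the short threaded region vs distributed along the long blade) is
evaluated at an equal-damage-budget snapshot taken at cut-out onset
(the first 120 damaged particles) rather than at the end state; the
compared quantities are the near-implant damaged count and the occupied
axial extent of the engagement band.  Implant proxies are parametric stand-ins — a threaded solid of
revolution and a shaft with two helical fins — not vendor geometry;
their engagement lengths (22 mm screw thread vs 45 mm blade) carry the
contrast that matters for damage distribution.

## Statistics

Force–displacement records are trimmed of toe-in artifacts (origin at
the first sample ≥ 50 N, the static ramp endpoint); force at cut-out is
interpolated at 7 mm, or extrapolated with the least-squares slope of
the ≥ 3 mm segment when a record stops short.  Curve pairs matched on a
0.05 mm displacement grid are compared with Lin's concordance
correlation coefficient ρ_c = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²) using
population (1/n) moments; ρ_c = ρ·C_b with ρ the Pearson coefficient
(precision) and C_b the bias factor (accuracy).  The 95 % CI uses a
Fisher z-transform of ρ_c with SE 1/√(n−3) — the CI convention is a
package choice.  Group comparisons reconstruct the two-sample
equal-variance t-test and one-way ANOVA from summary statistics
(n, mean, SD).

## Known limitations

* Rigid-body rotation is not integrated; varus rotation of the shell is
  approximated by translation plus foam shear.
* The solver kernel, integrator, damping, contact law and friction
  coefficients are package choices; published counterparts for this rig
  are not available for comparison.
* Coarse desk-scale resolutions damage most of the small cloud by 7 mm
  and bottom out near the end of travel (see above); absolute forces and
  damage volumes at reduced resolution are not calibrated against the
  full-resolution study, only the phenomenology and the relative
  contrasts are.
* The steel hardening modulus is carried as printed in its source
  transcription (500 Pa); it is configurable and unused by the rigid
  metallic bodies.
* Implant insertion (pre-compaction of foam around blades) is not
  simulated, which in the physical study is the suspected cause of the
  blades' higher early migration resistance.
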