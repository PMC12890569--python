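# Material property table for the cut-out simulation models.
# Units: MPa for moduli/stresses unless noted, dimensionless ratios.
# version: 1
#
# Notes:
# - steel hardening modulus is carried as printed in its source standard
#   transcription (500 Pa = 5.0e-4 MPa); physically a value in MPa is more
#   plausible.  It is configurable at lookup time and irrelevant to the
#   solver (metallic bodies are treated as rigid).
# - foam "overall" entries describe the porous structure as a whole;
#   "compact" entries describe the solid polymer assigned to individual
#   particles.  Compact static values are overall values scaled by the
#   8.5x bench-calibration coefficient; dynamic strengths are the static
#   strengths derated by 10%.
# - densities (g/mm^3) are handbook values for the base materials; they
#   only set particle inertia in the explicit solver.

steel-316L:
  behavior: rigid
  E: 193000.0          # 193 GPa
  nu: 0.27
  yield_stress: 800.0
  elongation_at_break: 0.6
  hardening_modulus: 5.0e-4   # "500 Pa" as printed; see note above
  failure_criterion: max-principal-strain
  density: 7.95e-3

titanium-Ti6Al4V:
  behavior: rigid
  E: 110000.0          # 110 GPa
  nu: 0.31
  yield_stress: 860.0
  elongation_at_break: 0.1
  hardening_modulus: 3300.0   # 3.3 GPa
  failure_criterion: max-principal-strain
  density: 4.43e-3

foam-10PCF-overall:
  behavior: neo-hookean
  E: 58.0
  nu: 0.30
  yield_stress: 2.2
  ultimate_stress: 2.31       # chosen so that 8.5x scaling lands on the
                              # tabulated static ultimate stress (19.64)
  volume_fraction: 0.14
  hardening_modulus: 0.0
  failure_criterion: max-principal-stress
  density: 1.20e-3            # compact PU polymer
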