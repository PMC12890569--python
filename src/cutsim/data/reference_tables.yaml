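# Published benchmark results of the physical and full-scale simulated
# cut-out study, used as inputs for the comparison/concordance reports and
# as cross-checks of the bookkeeping conventions.
# version: 1

# Force at cut-out (N): physical group summaries and full-scale simulated
# single-run values per device and loading mode.
force_at_cutout:
  physical:
    - {device: DHS,     mode: static,  n: 5, mean_N: 2294, sd_N: 174}
    - {device: Gamma3,  mode: static,  n: 4, mean_N: 2314, sd_N: 187}
    - {device: DHS,     mode: dynamic, n: 7, mean_N: 2219, sd_N: 98}
    - {device: Gamma3,  mode: dynamic, n: 6, mean_N: 1959, sd_N: 53}
    - {device: PFNA-II, mode: dynamic, n: 4, mean_N: 2161, sd_N: 81}
    - {device: TFNA,    mode: dynamic, n: 4, mean_N: 2267, sd_N: 94}
  simulated:
    - {device: DHS,     mode: static,  force_N: 2274}
    - {device: Gamma3,  mode: static,  force_N: 2390}
    - {device: DHS,     mode: dynamic, force_N: 2132}
    - {device: Gamma3,  mode: dynamic, force_N: 2194}
    - {device: PFNA-II, mode: dynamic, force_N: 2354}
    - {device: TFNA,    mode: dynamic, force_N: 2187}

# Yielding/failed particle counts of the full-scale dynamic simulations
# (uniform 400 um particles; volumes follow the cubic r^3 convention).
damage_counts:
  resolution_um: 400
  devices:
    DHS:     {yielding: 26490, failed: 3502}
    Gamma3:  {yielding: 30179, failed: 4171}
    PFNA-II: {yielding: 35978, failed: 3563}
    TFNA:    {yielding: 34188, failed: 3257}

# Cycle range observed before cut-out in physical dynamic testing.
physical_dynamic_cycle_range: [9500, 12750]
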