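# Benzene biofiltration base case: 1.5 m bed, EBRT 60 s, inlet 0.13 g/m3.
# Sections mirror the model's parameter groups: compound-specific constants,
# biofilm properties and bed operation.
compound:
  henry_dimensionless: 0.23      # H' = Cg/Cl at equilibrium
  mu_max_per_hour: 0.68          # Monod maximum specific growth rate
  monod_K: 12.22                 # g/m3
  yield_Y: 0.708
  diffusivity_water: 1.04e-9     # m2/s
biofilm:
  density_Xv: 100.0              # kg/m3
  area_As: 40.0                  # biofilm area per bed volume, 1/m
  thickness_delta: 5.0e-5        # m
bed:
  height_H: 1.5                  # m
  n_segments: 10
  void_fraction_eps: 0.35        # affects transients only, not steady state
  ebrt: 60.0                     # s (alternatively superficial_velocity_ug)
  inlet_conc_Cg0: 0.13           # g/m3
run:
  solver: oracle
  seed: 1
  t_end_s: 400.0
  ebrt_sweep: [60, 78, 84, 90, 120, 186]
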