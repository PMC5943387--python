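# A. aromaticum EbN1, denitrifying, 70 uM toluene, v = 1.8 m/day.
# Single-Monod in toluene (K_ox = f_ox = 0 disables the acceptor factor);
# no acceptor half-saturation or stoichiometry was published for this run.
experiment_id: exp_F
geometry: {length_cm: 1.6, diameter_cm: 1.34, porosity: 0.3, dispersion_m2_s: 1.95e-8}
flow: {rate_ml_h: 3.2, inlet_toluene_uM: 85.4, inlet_oxygen_uM: 0.0}
params:
  mu_max: 2.0
  K_tol: 21.7
  K_ox: 0.0
  yield_Y: 3.0e+8
  f_ox: 0.0
  k_att: 50.0
  X_att_max: 5.4e+8
solver: {dx_mm: 0.5, dt_max_s: 600, seed: 0}
duration_h: 216
inoculum_cells: 1.0e+5
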