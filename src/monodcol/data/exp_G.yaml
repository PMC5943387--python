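# Natural aquifer community, oxic groundwater, 70 uM toluene, v = 1.8 m/day.
# inlet_oxygen raised to cover the fitted f_ox demand at full removal.
experiment_id: exp_G
geometry: {length_cm: 1.6, diameter_cm: 1.34, porosity: 0.3, dispersion_m2_s: 1.95e-8}
flow: {rate_ml_h: 3.2, inlet_toluene_uM: 73.1, inlet_oxygen_uM: 280.0}
params:
  mu_max: 0.5
  K_tol: 1.1
  K_ox: 10.0
  yield_Y: 3.5e+7
  f_ox: 3.7
  k_att: 50.0
  X_att_max: 3.4e+8
solver: {dx_mm: 0.5, dt_max_s: 600, seed: 0}
duration_h: 216
inoculum_cells: 1.0e+6
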