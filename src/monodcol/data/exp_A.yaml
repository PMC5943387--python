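# P. putida F1, 70 uM toluene, v = 0.6 m/day
experiment_id: exp_A
geometry: {length_cm: 1.6, diameter_cm: 1.34, porosity: 0.3, dispersion_m2_s: 1.95e-8}
flow: {rate_ml_h: 1.067, inlet_toluene_uM: 66.9, inlet_oxygen_uM: 207.0}
params:
  mu_max: 4.5
  K_tol: 1.1
  K_ox: 10.0
  yield_Y: 3.6e+7
  f_ox: 2.6
  k_att: 50.0
  X_att_max: 9.0e+7
solver: {dx_mm: 0.5, dt_max_s: 600, seed: 0}
duration_h: 192
inoculum_cells: 1.0e+5
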