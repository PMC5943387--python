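# P. putida F1, 70 uM toluene, v = 3.6 m/day
experiment_id: exp_C
geometry: {length_cm: 1.6, diameter_cm: 1.34, porosity: 0.3, dispersion_m2_s: 1.95e-8}
flow: {rate_ml_h: 6.4, inlet_toluene_uM: 73.5, inlet_oxygen_uM: 261.0}
params:
  mu_max: 3.0
  K_tol: 1.1
  K_ox: 10.0
  yield_Y: 5.3e+7
  f_ox: 4.9
  k_att: 50.0
  X_att_max: 2.7e+8
solver: {dx_mm: 0.5, dt_max_s: 600, seed: 0}
duration_h: 192
inoculum_cells: 1.0e+5
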