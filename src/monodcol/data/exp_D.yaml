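# P. putida F1, 30 uM toluene, v = 1.8 m/day.
# No fitted parameter column was published for this run: kinetics are
# carried over from exp_B, f_ox/yield from the empirical summaries, and
# X_att_max scaled with the toluene turnover (uncertain).
experiment_id: exp_D
geometry: {length_cm: 1.6, diameter_cm: 1.34, porosity: 0.3, dispersion_m2_s: 1.95e-8}
flow: {rate_ml_h: 3.2, inlet_toluene_uM: 26.3, inlet_oxygen_uM: 150.0}
params:
  mu_max: 4.5
  K_tol: 1.1
  K_ox: 10.0
  yield_Y: 5.8e+7
  f_ox: 3.95
  k_att: 50.0
  X_att_max: 1.0e+8
solver: {dx_mm: 0.5, dt_max_s: 600, seed: 0}
duration_h: 192
inoculum_cells: 1.0e+5
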