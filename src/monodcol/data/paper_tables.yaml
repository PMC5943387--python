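# Transcription of the published empirical summaries (table 1), fitted
# model parameters (table 2) and batch-fit values (results text) for the
# mini-column study this package models.  Every block carries a `source`
# tag; entries whose printed table cells were ambiguous in the source
# document are flagged `uncertain: true`.

table1_empirical:
  source: "Table 1 - empirical summaries of the column experiments"
  columns:
    c_tol_in_target_uM: target inflow toluene
    c_tol_in_actual_uM: measured inflow toluene
    v_m_day: pore velocity
    delta_tol_uM: toluene removed (in - out) at steady state
    delta_tol_pct: toluene removal efficiency
    delta_o2_uM: oxygen consumed (in - out)
    f_ox: empirical stoichiometric ratio dO2/dTol
    new_cells_1e8: newly grown cells over the run, x1e8
    cells_flushed_pct: fraction of new cells exported
    yield_1e7_cells_per_umol: count-based growth yield, x1e7
    cells_attached_pct: fraction of cells attached
  rows:
    exp_A: {organism: P_putida_F1, c_tol_in_target_uM: 70, c_tol_in_actual_uM: 66.9,
            v_m_day: 0.6, delta_tol_uM: 66.9, delta_tol_pct: 100, delta_o2_uM: 207,
            f_ox: 3.1, new_cells_1e8: 4.4, cells_flushed_pct: 70,
            yield_1e7_cells_per_umol: 3.6, cells_attached_pct: 99}
    exp_B: {organism: P_putida_F1, c_tol_in_target_uM: 70, c_tol_in_actual_uM: 65,
            v_m_day: 1.8, delta_tol_uM: 59.6, delta_tol_pct: 92, delta_o2_uM: 203,
            f_ox: 3.4, new_cells_1e8: 14, cells_flushed_pct: 76,
            yield_1e7_cells_per_umol: 4.0, cells_attached_pct: 99}
    exp_C: {organism: P_putida_F1, c_tol_in_target_uM: 70, c_tol_in_actual_uM: 73.5,
            v_m_day: 3.6, delta_tol_uM: 51, delta_tol_pct: 69, delta_o2_uM: 261,
            f_ox: 5.1, new_cells_1e8: 28, cells_flushed_pct: 79,
            yield_1e7_cells_per_umol: 5.3, cells_attached_pct: 99}
    exp_D: {organism: P_putida_F1, c_tol_in_target_uM: 30, c_tol_in_actual_uM: 26.3,
            v_m_day: 1.8, delta_tol_uM: 26.3, delta_tol_pct: 100, delta_o2_uM: 104,
            f_ox: 3.95, new_cells_1e8: 6.6, cells_flushed_pct: 72,
            yield_1e7_cells_per_umol: 5.8, cells_attached_pct: 99,
            uncertain: true}   # printed row is mangled; reading reconstructed
    exp_E: {organism: P_putida_F1, c_tol_in_target_uM: 100, c_tol_in_actual_uM: 113,
            v_m_day: 1.8, delta_tol_uM: 67.2, delta_tol_pct: 59, delta_o2_uM: 247,
            f_ox: 3.7, new_cells_1e8: 53, cells_flushed_pct: 93,
            yield_1e7_cells_per_umol: 11.7, cells_attached_pct: 98}
    exp_F: {organism: A_aromaticum_EbN1, c_tol_in_target_uM: 70, c_tol_in_actual_uM: 85.4,
            v_m_day: 1.8, delta_tol_uM: 63.1, delta_tol_pct: 73, delta_o2_uM: null,
            f_ox: null, new_cells_1e8: 10, cells_flushed_pct: 20,
            yield_1e7_cells_per_umol: 3.0, cells_attached_pct: 99}
    exp_G: {organism: natural_community, c_tol_in_target_uM: 70, c_tol_in_actual_uM: 73.1,
            v_m_day: 1.8, delta_tol_uM: 73.1, delta_tol_pct: 100, delta_o2_uM: 256,
            f_ox: 3.5, new_cells_1e8: 11, cells_flushed_pct: 50,
            yield_1e7_cells_per_umol: 3.5, cells_attached_pct: 99}

table2_model:
  source: "Table 2 - reactive-transport model parameters (bold = fitted)"
  note: >
    X_att_max was set to the highest attached-cell count measured in each
    experiment; Y was computed from new cells per toluene degraded; K_tol
    came from the batch fits; K_ox from literature.
  rows:
    exp_A: {mu_max_per_day: 4.5, K_tol_uM: 1.1, K_ox_uM: 10, f_ox: 2.6,
            k_att_per_day: 50, X_att_max_per_ml_sed: 9.0e+7, yield_cells_per_umol: 3.6e+7}
    exp_B: {mu_max_per_day: 4.5, K_tol_uM: 1.1, K_ox_uM: 10, f_ox: 4.0,
            k_att_per_day: 50, X_att_max_per_ml_sed: 2.0e+8, yield_cells_per_umol: 4.0e+7}
    exp_C: {mu_max_per_day: 3.0, K_tol_uM: 1.1, K_ox_uM: 10, f_ox: 4.9,
            k_att_per_day: 50, X_att_max_per_ml_sed: 2.7e+8, yield_cells_per_umol: 5.3e+7}
    exp_F: {mu_max_per_day: 2.0, K_tol_uM: 21.7, K_ox_uM: null, f_ox: null,
            k_att_per_day: 50, X_att_max_per_ml_sed: 5.4e+8, yield_cells_per_umol: 3.0e+8,
            uncertain: true}   # yield conflicts with the 3.0e7 empirical value
    exp_G: {mu_max_per_day: 0.5, K_tol_uM: 1.1, K_ox_uM: 10, f_ox: 3.7,
            k_att_per_day: 50, X_att_max_per_ml_sed: 3.4e+8, yield_cells_per_umol: 3.5e+7}

batch_fits:
  source: "Results - batch experiments (fitted values +/- reported SE)"
  F1_monod:
    organism: P_putida_F1
    mu_max_per_day: 4.25
    mu_max_se: 0.24
    mu_max_discussion_per_day: 4.5    # discussion text quotes 4.5 for the same fit
    K_tol_uM: 10.9
    K_tol_se: 2.83
    yield_cells_per_umol: 2.83e+8
    uncertain: true                   # two printed mu_max readings
  F1_metabolite:
    organism: P_putida_F1
    r_tol_max_over_Y_per_day: 24.06
    r_tol_max_over_Y_se: 0.01
    r_met_max_over_Y_per_day: 4.19
    r_met_max_over_Y_se: 0.03
    K_tol_uM: 1.45
    K_tol_se: 0.002
    yield_cells_per_umol: 2.83e+8
    K_met_uM: null                    # never reported; treated as free nuisance
  EbN1_monod:
    organism: A_aromaticum_EbN1
    mu_max_per_day: 0.35
    K_tol_uM: 21.7
    yield_cells_per_umol: 1.38e+8
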