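import numpy as np
import pytest

import monodcol as mc
from monodcol.column import _ColumnModel, column_objective
from monodcol.geometry import ValidationError


def make_state(N=8, c_tol=10.0, c_ox=100.0, x_mob=0.0, x_att=1e7):
    x = (np.arange(N) + 0.5) * (0.016 / N)
    return mc.ColumnState(x, np.full(N, c_tol), np.full(N, c_ox),
                          np.full(N, x_mob), np.full(N, x_att))


PARAMS = mc.BiokineticParams(mu_max=4.5, K_tol=1.1, K_ox=10.0, yield_Y=4.0e7,
                             f_ox=4.0, k_att=50.0, X_att_max=2.0e8)


class TestRateLaws:
    def test_half_saturation_quarters_the_rate(self):
        s = make_state(c_tol=PARAMS.K_tol, c_ox=PARAMS.K_ox, x_att=1e8)
        r_att, r_mob = mc.growth_rates(s, PARAMS)
        assert r_att == pytest.approx(PARAMS.mu_max * 1e8 / 4)
        assert np.all(r_mob == 0.0)  # mobile growth off by default

    def test_acceptor_limitation_and_saturation(self):
        assert np.all(mc.growth_rates(make_state(c_ox=0.0), PARAMS)[0] == 0.0)
        s = make_state(c_tol=1e5, c_ox=1e5, x_att=1e8)
        r_att, _ = mc.growth_rates(s, PARAMS)
        assert r_att == pytest.approx(PARAMS.mu_max * 1e8, rel=1e-3)

    def test_mobile_growth_flag(self):
        s = make_state(c_tol=1e5, c_ox=1e5, x_mob=1e6)
        _, r_mob = mc.growth_rates(s, PARAMS, mobile_growth=True)
        assert r_mob == pytest.approx(PARAMS.mu_max * 1e6, rel=1e-3)

    @pytest.mark.parametrize("frac,expected_factor", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_daughter_release_scales_with_occupancy(self, frac, expected_factor):
        s = make_state(c_tol=1e5, c_ox=1e5, x_att=frac * PARAMS.X_att_max)
        r_att, _ = mc.growth_rates(s, PARAMS)
        assert mc.daughter_release_rate(s, PARAMS) == pytest.approx(
            expected_factor * r_att)

    def test_attachment_blocked_at_capacity(self):
        s_full = make_state(x_mob=1e6, x_att=PARAMS.X_att_max)
        assert np.all(mc.attachment_rate(s_full, PARAMS) == 0.0)
        s_empty = make_state(x_mob=1e6, x_att=0.0)
        assert mc.attachment_rate(s_empty, PARAMS) == pytest.approx(50.0 * 1e6)
        s_half = make_state(x_mob=1e6, x_att=0.5 * PARAMS.X_att_max)
        assert mc.attachment_rate(s_half, PARAMS) == pytest.approx(2.5e7)


class TestStepper:
    def test_zero_kinetics_transports_inlet_signal(self, bench_geometry):
        """With all rate parameters zero the step is pure transport: the
        inlet concentration invades, nothing else changes."""
        p = mc.BiokineticParams(X_att_max=1.0)
        flow = mc.FlowCondition(3.2, 50.0, 100.0)
        s0 = make_state(N=32, c_tol=0.0, c_ox=0.0, x_mob=0.0, x_att=0.0)
        # one 60 s step advects the feed ~1-2 cells into the column
        s1 = mc.step_implicit_euler(s0, 60 / 86400, p, bench_geometry, flow)
        assert s1.c_tol[0] > 1.0            # inlet cell picked up the feed
        assert s1.c_tol[-1] < 0.01 * 50     # far end essentially untouched
        assert np.all(s1.X_att == 0.0)

    def test_capacity_steady_state_step(self, bench_geometry):
        """At carrying capacity with saturating substrate the attached pool
        does not change and every new cell leaves via the mobile phase."""
        flow = mc.FlowCondition(3.2, 1e4, 1e4)
        s0 = make_state(N=32, c_tol=1e4, c_ox=1e4, x_mob=0.0, x_att=PARAMS.X_att_max)
        s1 = mc.step_implicit_euler(s0, 300 / 86400, PARAMS, bench_geometry, flow)
        assert s1.X_att == pytest.approx(PARAMS.X_att_max, rel=1e-8)
        assert s1.X_mob[-1] > 0.0

    def test_dt_above_cap_rejected(self, bench_geometry):
        flow = mc.FlowCondition(3.2, 50.0, 100.0)
        with pytest.raises(ValidationError):
            mc.step_implicit_euler(make_state(), 0.5, PARAMS, bench_geometry, flow)


class TestSimulateColumn:
    def test_nonnegativity_and_capacity_bound(self, exp_b_record_96h, exp_b_config):
        rec = exp_b_record_96h
        for arr in (rec.c_tol, rec.c_ox, rec.X_mob, rec.X_att):
            assert np.all(arr >= 0.0)
        assert np.all(rec.X_att <= exp_b_config.params.X_att_max * (1 + 1e-9))

    def test_toluene_and_cell_balances_close(self, exp_b_record_96h, exp_b_config):
        """Cumulative inlet − outlet − consumption equals storage change,
        and growth equals pool change plus export, at every output time."""
        rec, cfg = exp_b_record_96h, exp_b_config
        n_cells = rec.c_tol.shape[1]
        water_l = mc.pore_volume(cfg.geometry) / n_cells / 1e3
        bulk_ml = mc.bulk_volume(cfg.geometry) / n_cells
        b = rec.balance
        tol_storage = rec.c_tol.sum(axis=1) * water_l
        resid = b["tol_in"] - b["tol_out"] - b["tol_consumed"] - tol_storage
        assert np.max(np.abs(resid)) < 1e-6 * max(b["tol_in"][-1], 1.0)
        att_pool = rec.X_att.sum(axis=1) * bulk_ml
        mob_pool = rec.X_mob.sum(axis=1) * water_l * 1e3
        cell_resid = (b["cells_grown"] + b["cells_in"] - b["cells_out"]
                      - (att_pool - att_pool[0]) - mob_pool)
        assert np.max(np.abs(cell_resid)) < 1e-6 * b["cells_grown"][-1]

    def test_oxygen_follows_fox_stoichiometry(self, exp_b_record_96h, exp_b_config):
        """ΔO₂ = f_ox·ΔTol whenever outlet oxygen is not exhausted (here
        checked on the cumulative consumption bookkeeping)."""
        b = exp_b_record_96h.balance
        assert b["ox_consumed"][-1] == pytest.approx(
            exp_b_config.params.f_ox * b["tol_consumed"][-1], rel=1e-9)

    def test_steady_state_summary_exp_b(self, exp_b_record_96h, exp_b_config):
        s = mc.steady_state_summary(exp_b_record_96h)
        assert s["steady"]
        assert s["removal_pct"] == pytest.approx(92.0, abs=5.0)
        assert s["f_ox_empirical"] == pytest.approx(exp_b_config.params.f_ox, abs=0.25)
        # outlet cells in the observed few-1e6/mL range for the 70 µM runs
        assert 1e6 < s["outlet_X_mob"] < 1e7

    def test_zero_biomass_run_removes_nothing(self, exp_b_config):
        cfg = exp_b_config.replace(inoculum_cells=0.0, duration_h=6.0)
        rec = mc.simulate_column(cfg)
        s = mc.steady_state_summary(rec)
        assert s["dTol"] == pytest.approx(0.0, abs=1e-6 * cfg.flow.inlet_toluene)

    def test_cumulative_degraded_bounds(self, exp_b_config):
        """Perfect removal for 192 h bounds the integral at Q·c_in·T."""
        cfg = exp_b_config
        rec = mc.simulate_column(cfg.replace(duration_h=48.0))
        got = mc.cumulative_toluene_degraded(rec)
        upper = cfg.flow.flow_rate * 1e-3 * cfg.flow.inlet_toluene * 48.0
        assert 0.0 < got < upper
        with pytest.raises(ValidationError):
            mc.cumulative_toluene_degraded(rec, 96.0)


class TestLogisticVariant:
    def test_matches_full_model_at_steady_state(self, exp_b_config, exp_b_record_96h):
        """The mobile-cell-free logistic formulation reproduces the full
        model's steady toluene profile within 5%."""
        rec_log = mc.logistic_variant_simulate(exp_b_config.replace(duration_h=96.0))
        assert rec_log.X_mob is None
        diff = np.abs(rec_log.c_tol[-1] - exp_b_record_96h.c_tol[-1])
        assert np.max(diff) < 0.05 * exp_b_config.flow.inlet_toluene
        assert np.all(rec_log.X_att <= exp_b_config.params.X_att_max * (1 + 1e-9))

    def test_unbounded_capacity_recovers_pure_growth(self, exp_b_config):
        """X_att_max → ∞ removes the throttle: attached growth is pure
        dual-Monod exponential while substrate lasts."""
        cfg = exp_b_config.replace(
            params=exp_b_config.params.replace(X_att_max=1e30), duration_h=12.0)
        rec = mc.logistic_variant_simulate(cfg)
        i0 = np.searchsorted(rec.times_h, 6.0)
        mu_eff = np.log(rec.X_att[-1, 0] / rec.X_att[i0, 0]) / (
            (rec.times[-1] - rec.times[i0]))
        p = cfg.params
        mu_expected = p.mu_max * (65.0 / (65.0 + p.K_tol)) * (240.0 / (240.0 + p.K_ox))
        assert mu_eff == pytest.approx(mu_expected, rel=0.05)


class TestFitColumn:
    def test_noise_free_self_consistency(self, exp_b_config):
        """Noise-free synthetic breakthrough returns the generating
        (µ_max, f_ox) to < 1%."""
        cfg = exp_b_config.replace(duration_h=48.0)
        design = mc.StudyDesign(sample_times=(6, 12, 24, 36, 48), sacrifice_times=(48.0,))
        obs = mc.gen_column_dataset(
            cfg, design,
            mc.NoiseModel(conc_sd_abs=0, cell_cv=0, detection_floor_cells=0, replicates=1),
            seed=0)
        truth = cfg.params
        guess = truth.replace(mu_max=truth.mu_max * 1.3, f_ox=truth.f_ox * 0.85)
        fit = mc.fit_column(obs, ["mu_max", "f_ox"], guess, cfg, n_starts=1,
                            seed=0, xtol=1e-8)
        assert fit.estimates["mu_max"] == pytest.approx(truth.mu_max, rel=0.01)
        assert fit.estimates["f_ox"] == pytest.approx(truth.f_ox, rel=0.01)

    def test_invalid_free_parameter_rejected(self, exp_b_config):
        with pytest.raises(ValidationError):
            mc.fit_column(None, ["yield_Y"], exp_b_config.params, exp_b_config)

    def test_objective_at_truth_below_perturbed(self, exp_b_config):
        cfg = exp_b_config.replace(duration_h=48.0)
        design = mc.StudyDesign(sample_times=(6, 12, 24, 36, 48))
        obs = mc.gen_column_dataset(cfg, design, mc.NoiseModel(), seed=3)
        at_truth = column_objective(obs, cfg.params, cfg)
        perturbed = column_objective(obs, cfg.params.replace(mu_max=9.0, f_ox=2.0), cfg)
        assert at_truth < perturbed


def test_grid_resolution_from_solver_settings(exp_b_config):
    model = _ColumnModel(exp_b_config)
    assert model.N == 32                     # 1.6 cm at 0.5 mm cells
    assert model.dx == pytest.approx(0.5e-3)
    assert model.x_centers[0] == pytest.approx(0.25e-3)
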