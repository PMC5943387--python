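import numpy as np
import pandas as pd
import pytest

import monodcol as mc
from monodcol.geometry import ValidationError

TRUTH = mc.BiokineticParams(mu_max=0.35, K_tol=21.7, yield_Y=1.38e8)
INIT = mc.BatchState(c_tol=150.0, X=1e9)
DESIGN = mc.StudyDesign(sample_times=(0, 48, 96, 144, 192, 240, 288))


class TestBatchGenerator:
    def test_zero_noise_reproduces_model_truth(self):
        noise = mc.NoiseModel(conc_sd_abs=0, cell_cv=0, detection_floor_cells=0,
                              replicates=2)
        obs = mc.gen_batch_dataset(TRUTH, INIT, DESIGN, noise, seed=5)
        traj = mc.simulate_batch_monod(TRUTH, INIT, np.array(DESIGN.sample_times[1:]) / 24)
        tol = obs.subset("toluene_uM")
        by_rep = {r: g.sort_values("time_h")["value"].to_numpy()
                  for r, g in tol.groupby("replicate")}
        assert np.allclose(by_rep[1], by_rep[2])
        assert np.allclose(by_rep[1][1:], traj.c_tol)
        assert by_rep[1][0] == INIT.c_tol

    def test_same_seed_is_byte_identical(self, tmp_path):
        a = mc.gen_batch_dataset(TRUTH, INIT, DESIGN, mc.NoiseModel(), seed=7)
        b = mc.gen_batch_dataset(TRUTH, INIT, DESIGN, mc.NoiseModel(), seed=7)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.write_csv(pa), b.write_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()
        c = mc.gen_batch_dataset(TRUTH, INIT, DESIGN, mc.NoiseModel(), seed=8)
        assert not a.df["value"].equals(c.df["value"])

    def test_noise_is_unbiased_away_from_the_floor(self):
        """Across 100 seeds the pooled mean of observed toluene matches
        the model truth to well under half a standard error (checked where
        truth ≳ 4 SD so the zero truncation is inactive; per-time means
        scatter ±2 SE as any unbiased sampler's must)."""
        noise = mc.NoiseModel(replicates=3)
        times = np.array(DESIGN.sample_times[1:]) / 24
        traj = mc.simulate_batch_monod(TRUTH, INIT, times)
        truth_vals = np.concatenate([[INIT.c_tol], traj.c_tol])
        keep = truth_vals > 4 * noise.conc_sd_abs
        sums = np.zeros(keep.sum())
        n_seeds = 100
        for seed in range(n_seeds):
            obs = mc.gen_batch_dataset(TRUTH, INIT, DESIGN, noise, seed=seed)
            tol = obs.subset("toluene_uM").groupby("time_h")["value"].mean()
            sums += tol.sort_index().to_numpy()[keep]
        deviation = sums / n_seeds - truth_vals[keep]
        n_pts = keep.sum()
        se_pooled = noise.conc_sd_abs / np.sqrt(n_seeds * noise.replicates * n_pts)
        assert abs(deviation.mean()) < 0.5 * se_pooled

    def test_count_noise_is_mean_corrected(self):
        """The lognormal count factor has unit mean: across many draws the
        linear-scale average converges on the truth."""
        noise = mc.NoiseModel(cell_cv=0.2, detection_floor_cells=0)
        rng = np.random.default_rng(0)
        draws = noise.noisy_cells(np.full(20000, 1e6), rng)
        assert draws.mean() == pytest.approx(1e6, rel=0.01)
        assert draws.std() == pytest.approx(0.2e6, rel=0.05)

    def test_times_outside_horizon_rejected(self):
        with pytest.raises(ValidationError):
            mc.StudyDesign(sample_times=(0, -5.0))


@pytest.fixture(scope="module")
def short_cfg():
    return mc.bundled_config("exp_B").replace(duration_h=48.0)


class TestColumnGenerator:

    def test_zero_noise_equals_simulator_output(self, short_cfg):
        design = mc.StudyDesign(sample_times=(6, 12, 24, 48))
        noise = mc.NoiseModel(conc_sd_abs=0, cell_cv=0, detection_floor_cells=0,
                              replicates=1)
        obs = mc.gen_column_dataset(short_cfg, design, noise, seed=0)
        rec = mc.simulate_column(short_cfg, output_times_h=np.array([6., 12., 24., 48.]))
        got = obs.subset("toluene_uM", "outlet").sort_values("time_h")["value"].to_numpy()
        assert np.allclose(got, rec.outlet_toluene[1:])

    def test_sacrifice_schema_counts(self, short_cfg):
        design = mc.StudyDesign(sample_times=(12, 24), sacrifice_times=(6, 12, 24, 48))
        obs = mc.gen_column_dataset(short_cfg, design, mc.NoiseModel(replicates=2), seed=1)
        att = obs.subset("attached_cells_per_ml_sed")
        # 4 sacrifice times × 3 sections per replicate
        assert len(att) == 4 * 3 * 2
        assert set(att["location"]) == {"bottom", "middle", "top"}

    def test_design_beyond_horizon_rejected(self, short_cfg):
        with pytest.raises(ValidationError):
            mc.gen_column_dataset(short_cfg, mc.StudyDesign(sample_times=(24, 96)),
                                  mc.NoiseModel(), seed=0)


class TestCommunityVariant:
    def test_full_activity_reduces_to_plain_generator(self):
        cfg = mc.bundled_config("exp_B").replace(duration_h=24.0)
        design = mc.StudyDesign(sample_times=(6, 12, 24), sacrifice_times=(24.0,))
        a = mc.gen_community_variant(cfg, 1.0, seed=3, design=design,
                                     noise=mc.NoiseModel())
        b = mc.gen_column_dataset(cfg, design, mc.NoiseModel(), seed=3)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_background_offset_visible_in_attached_counts(self):
        cfg = mc.bundled_config("exp_G").replace(duration_h=24.0, inoculum_cells=1e8)
        design = mc.StudyDesign(sample_times=(6.0,), sacrifice_times=(0.0, 6.0))
        noise = mc.NoiseModel(conc_sd_abs=0, cell_cv=0, detection_floor_cells=0,
                              replicates=1)
        frac = 0.01
        obs = mc.gen_community_variant(cfg, frac, seed=0, design=design, noise=noise)
        att0 = obs.subset("attached_cells_per_ml_sed")
        att0 = att0[att0["time_h"] == 0.0]["value"].to_numpy()
        background = cfg.inoculum_cells * (1 - frac) / mc.bulk_volume(cfg.geometry)
        degraders = cfg.inoculum_cells * frac / mc.bulk_volume(cfg.geometry)
        assert np.allclose(att0, background + degraders, rtol=1e-9)
        assert np.all(att0 > degraders * 10)

    def test_invalid_fraction_rejected(self):
        cfg = mc.bundled_config("exp_G")
        for frac in (0.0, 1.5, -0.1):
            with pytest.raises(ValidationError):
                mc.gen_community_variant(cfg, frac, seed=0)

    def test_small_active_fraction_delays_but_converges(self):
        """With 1% active degraders the approach to full removal is
        delayed, but the late-time outlet toluene matches the fully
        active run within 5% of the inlet concentration."""
        cfg = mc.bundled_config("exp_G").replace(duration_h=480.0, inoculum_cells=1e7,
                                                 output_dt_h=12.0)
        design = mc.StudyDesign(sample_times=tuple(np.arange(12.0, 481.0, 12.0)))
        noise = mc.NoiseModel(conc_sd_abs=0, cell_cv=0, detection_floor_cells=0,
                              replicates=1)
        full = mc.gen_community_variant(cfg, 1.0, seed=0, design=design, noise=noise)
        partial = mc.gen_community_variant(cfg, 0.01, seed=0, design=design, noise=noise)
        c_in = cfg.flow.inlet_toluene

        def outlet(obs):
            sub = obs.subset("toluene_uM", "outlet").sort_values("time_h")
            return sub["time_h"].to_numpy(), sub["value"].to_numpy()

        t_f, out_f = outlet(full)
        t_p, out_p = outlet(partial)
        # time to 95% removal is later for the 1% community
        t95_f = t_f[np.argmax(out_f < 0.05 * c_in)]
        t95_p = t_p[np.argmax(out_p < 0.05 * c_in)]
        assert t95_p > t95_f
        # but the late-time removal converges
        assert abs(out_p[-1] - out_f[-1]) < 0.05 * c_in
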