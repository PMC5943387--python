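import pytest

import monodcol as mc


@pytest.fixture(scope="session")
def bench_geometry() -> mc.ColumnGeometry:
    """The mini-column bench geometry: 1.6 cm bed, 1.34 cm bore, n = 0.3."""
    return mc.ColumnGeometry.from_cm(1.6, 1.34, 0.3)


@pytest.fixture(scope="session")
def exp_b_config() -> mc.ExperimentConfig:
    return mc.bundled_config("exp_B")


@pytest.fixture(scope="session")
def exp_b_record_96h(exp_b_config) -> mc.ColumnRecord:
    """One 96 h forward run of the standard-flow experiment, shared by the
    tests that only read it."""
    return mc.simulate_column(exp_b_config.replace(duration_h=96.0))


@pytest.fixture(scope="session")
def ebn1_params() -> mc.BiokineticParams:
    """Denitrifier batch kinetics (slow grower, high K)."""
    return mc.BiokineticParams(mu_max=0.35, K_tol=21.7, yield_Y=1.38e8)


def two_bottle_dataset(truth: mc.BiokineticParams, seed: int) -> mc.ObservationSet:
    """Joint two-bottle batch design: a high-substrate bottle that pins
    µ_max and Y plus a near-K bottle that pins K_tol."""
    bottles = [
        ("b150", 150.0, 1e9, (0, 48, 96, 144, 192, 216, 240, 252, 264, 276, 288, 312)),
        ("b30", 30.0, 1e9, (0, 24, 48, 72, 96, 120, 144, 168, 192, 216, 240, 264)),
    ]
    parts = []
    for i, (eid, c0, x0, times) in enumerate(bottles):
        parts.append(mc.gen_batch_dataset(
            truth, mc.BatchState(c_tol=c0, X=x0),
            mc.StudyDesign(sample_times=times), mc.NoiseModel(),
            seed=seed * 10 + i, experiment_id=eid,
        ))
    return mc.ObservationSet.concat(parts)


def two_bottle_inits() -> dict[str, mc.BatchState]:
    return {"b150": mc.BatchState(c_tol=150.0, X=1e9),
            "b30": mc.BatchState(c_tol=30.0, X=1e9)}
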