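"""Seeded synthetic observation sets emulating the study's sampling design.

The generator runs the forward models and overlays a stated noise model:
additive Gaussian noise on concentrations (truncated at zero) and
multiplicative lognormal noise on every cell count (counts stay positive
over four orders of magnitude; the lognormal is mean-corrected so counts
are unbiased on the linear scale).  Replicate rows share the same model
truth — batch replicates emulate repeated bottles, column sacrifice
replicates emulate parallel columns sacrificed at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .batch import BatchState, simulate_batch_metabolite, simulate_batch_monod
from .column import ColumnRecord, section_averages, simulate_column
from .geometry import BiokineticParams, HOURS_PER_DAY, ValidationError
from .io import ExperimentConfig, ObservationSet, OBS_COLUMNS

__all__ = [
    "NoiseModel",
    "StudyDesign",
    "gen_batch_dataset",
    "gen_column_dataset",
    "gen_community_variant",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    conc_sd_abs : additive Gaussian SD on concentrations [µM]
    cell_cv     : CV of the multiplicative lognormal noise on counts
    detection_floor_cells : reporting floor for counts [cells mL⁻¹]
    replicates  : replicate measurements per time point
    """

    conc_sd_abs: float = 3.0
    cell_cv: float = 0.2
    detection_floor_cells: float = 1e3
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("conc_sd_abs", "cell_cv", "detection_floor_cells"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    def noisy_conc(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.maximum(truth + rng.normal(0.0, self.conc_sd_abs, size=np.shape(truth)), 0.0)

    def noisy_cells(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cell_cv == 0:
            return np.maximum(np.asarray(truth, dtype=float), self.detection_floor_cells)
        sigma = np.sqrt(np.log1p(self.cell_cv**2))
        factor = rng.lognormal(-0.5 * sigma**2, sigma, size=np.shape(truth))
        return np.maximum(np.asarray(truth) * factor, self.detection_floor_cells)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule of one experiment (hours)."""

    sample_times: tuple[float, ...]
    sacrifice_times: tuple[float, ...] = ()
    locations: tuple[str, ...] = ("outlet", "bottom", "middle", "top")

    def __post_init__(self) -> None:
        if len(self.sample_times) == 0:
            raise ValidationError("sample_times must not be empty")
        for t in tuple(self.sample_times) + tuple(self.sacrifice_times):
            if t < 0:
                raise ValidationError("sampling times must be >= 0")


def _rows(exp_id, rep, times, loc, quantity, values):
    return pd.DataFrame({
        "experiment_id": exp_id, "replicate": rep, "time_h": times,
        "location": loc, "quantity": quantity, "value": values,
    })


def gen_batch_dataset(
    params: BiokineticParams,
    init: BatchState,
    design: StudyDesign,
    noise: NoiseModel,
    seed: int,
    variant: str = "monod",
    experiment_id: str = "batch",
) -> ObservationSet:
    """Simulate a batch bottle experiment and emit noisy replicate rows.

    The same model trajectory underlies every replicate; a fixed seed
    reproduces the dataset bit for bit.
    """
    simulate = {"monod": simulate_batch_monod, "metabolite": simulate_batch_metabolite}
    if variant not in simulate:
        raise ValidationError(f"unknown variant {variant!r}")
    times_h = np.asarray(sorted(design.sample_times), dtype=float)
    times_day = times_h / HOURS_PER_DAY
    sim_days = times_day if times_day[0] > 0 else times_day[1:]
    traj = simulate[variant](params, init, sim_days)
    if times_day[0] == 0.0:
        c_tol = np.concatenate([[init.c_tol], traj.c_tol])
        c_met = np.concatenate([[init.c_met], traj.c_met])
        cells_ml = np.concatenate([[init.X], traj.X]) / 1e3
    else:
        c_tol, c_met, cells_ml = traj.c_tol, traj.c_met, traj.X / 1e3

    rng = np.random.default_rng(seed)
    parts = []
    for rep in range(1, noise.replicates + 1):
        parts.append(_rows(experiment_id, rep, times_h, "", "toluene_uM",
                           noise.noisy_conc(c_tol, rng)))
        parts.append(_rows(experiment_id, rep, times_h, "", "cells_per_ml",
                           noise.noisy_cells(cells_ml, rng)))
        if variant == "metabolite":
            parts.append(_rows(experiment_id, rep, times_h, "", "metabolite_uM",
                               noise.noisy_conc(c_met, rng)))
    df = pd.concat(parts, ignore_index=True)[OBS_COLUMNS]
    return ObservationSet(df, provenance=f"synthetic batch ({variant}), seed={seed}")


def _column_truth(record: ColumnRecord, design: StudyDesign):
    """Noise-free observable series from a simulated column record."""
    sample_h = np.asarray(sorted(design.sample_times), dtype=float)
    idx = np.searchsorted(record.times_h, sample_h)
    if np.any(np.abs(record.times_h[idx] - sample_h) > 1e-9):
        raise ValidationError("sample times outside the simulated output grid")
    truth = {
        ("toluene_uM", "outlet"): record.outlet_toluene[idx],
        ("cells_per_ml", "outlet"): record.outlet_cells[idx],
    }
    ox = record.section_series("c_ox")
    for loc in ("bottom", "middle", "top"):
        truth[("oxygen_uM", loc)] = ox[loc][idx]
    sac: dict[str, np.ndarray] = {}
    if design.sacrifice_times:
        sac_h = np.asarray(sorted(design.sacrifice_times), dtype=float)
        jdx = np.searchsorted(record.times_h, sac_h)
        if np.any(np.abs(record.times_h[jdx] - sac_h) > 1e-9):
            raise ValidationError("sacrifice times outside the simulated output grid")
        att = np.array([section_averages(row) for row in record.X_att[jdx]])
        sac = {"times_h": sac_h, "sections": att}  # (n_sac, 3)
    return sample_h, truth, sac


def gen_column_dataset(
    config: ExperimentConfig,
    design: StudyDesign,
    noise: NoiseModel,
    seed: int,
    attached_offset: float = 0.0,
) -> ObservationSet:
    """Simulate a flow-through column and sample it like the bench protocol:
    outlet toluene and suspended cells plus three-section oxygen at the
    sample times, and section-averaged attached cells from whole columns
    sacrificed at the sacrifice times."""
    horizon = max(tuple(design.sample_times) + tuple(design.sacrifice_times or (0,)))
    if horizon > config.duration_h + 1e-9:
        raise ValidationError("sampling design exceeds the simulation horizon")
    all_times = np.unique(np.concatenate([
        np.asarray(design.sample_times, float),
        np.asarray(design.sacrifice_times or [], dtype=float),
    ]))
    record = simulate_column(config, output_times_h=all_times)
    sample_h, truth, sac = _column_truth(record, design)

    rng = np.random.default_rng(seed)
    exp_id = config.experiment_id
    parts = []
    for rep in range(1, noise.replicates + 1):
        for (quantity, loc), values in truth.items():
            if loc not in design.locations and loc != "outlet":
                continue
            noisy = (noise.noisy_cells(values, rng) if quantity == "cells_per_ml"
                     else noise.noisy_conc(values, rng))
            parts.append(_rows(exp_id, rep, sample_h, loc, quantity, noisy))
        if sac:
            for j, t in enumerate(sac["times_h"]):
                reported = sac["sections"][j] + attached_offset
                noisy = noise.noisy_cells(reported, rng)
                for s, loc in enumerate(("bottom", "middle", "top")):
                    parts.append(_rows(exp_id, rep, [t], loc,
                                       "attached_cells_per_ml_sed", [noisy[s]]))
    df = pd.concat(parts, ignore_index=True)[OBS_COLUMNS]
    return ObservationSet(df, provenance=f"synthetic column {exp_id}, seed={seed}")


def gen_community_variant(
    config: ExperimentConfig,
    active_fraction: float,
    seed: int,
    design: StudyDesign | None = None,
    noise: NoiseModel | None = None,
) -> ObservationSet:
    """Natural-community scenario: only ``active_fraction`` of the initially
    attached cells degrade toluene; the inactive background stays as a
    constant offset in the reported attached counts.

    With active_fraction = 1 this is exactly :func:`gen_column_dataset`.
    """
    if not 0.0 < active_fraction <= 1.0:
        raise ValidationError(f"active_fraction must lie in (0, 1], got {active_fraction}")
    if design is None:
        d = config.duration_h
        design = StudyDesign(
            sample_times=tuple(np.arange(0.0, d + 1e-9, min(6.0, d / 4))),
            sacrifice_times=(d / 4, d / 2, d),
        )
    if noise is None:
        noise = NoiseModel()
    from .geometry import bulk_volume

    background = (config.inoculum_cells * (1.0 - active_fraction)
                  / bulk_volume(config.geometry))
    scaled = config.replace(inoculum_cells=config.inoculum_cells * active_fraction)
    return gen_column_dataset(scaled, design, noise, seed, attached_offset=background)
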