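"""Closed-system (batch) Monod growth models and their calibration.

Two model variants are provided:

* the standard Monod model — cells grow directly on toluene,

      dX/dt = µ_max · c/(c+K_tol) · X,     dc/dt = −(1/Y) dX/dt,

  which carries the exact first integral X(t) = X(0) + Y·(c(0) − c(t));

* a two-step variant in which toluene is first transformed to a generic
  metabolite intermediate without growth, and the cells then grow on the
  metabolite,

      r_tol = r_tol_max · c_tol/(c_tol+K_tol) · X
      r_met = r_met_max · c_met/(c_met+K_met) · X
      dc_tol/dt = −r_tol,  dc_met/dt = r_tol − r_met,  dX/dt = Y · r_met,

  whose first integral is c_tol + c_met + X/Y = const.  In the limit of a
  fast second step (r_met_max → ∞, K_met → 0) the (c_tol, X) trajectories
  converge to the standard model with µ_max = Y · r_tol_max.

Cell concentration X is carried in cells L⁻¹; concentrations in µM; time
in days.  Both systems are integrated with an adaptive explicit
Runge–Kutta scheme (scipy's RK45).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .fitting import FitResult, fit_least_squares
from .geometry import BiokineticParams, SolverSettings, ValidationError
from .io import ObservationSet

__all__ = [
    "BatchState",
    "BatchTrajectory",
    "simulate_batch_monod",
    "simulate_batch_metabolite",
    "fit_batch",
    "MONOD_PARAMS",
    "METABOLITE_PARAMS",
]

#: Parameter names each variant actually uses (the admissible free sets).
MONOD_PARAMS = ("mu_max", "K_tol", "yield_Y")
METABOLITE_PARAMS = ("r_tol_max", "r_met_max", "K_tol", "K_met", "yield_Y")

# Default observation SDs used to weight residuals when the observation
# set carries no replicates to estimate them from: 3 µM on concentrations,
# 20% CV on counts (CV/ln10 in log10 space).
_DEFAULT_CONC_SD = 3.0
_DEFAULT_LOG10_SD = 0.2 / np.log(10.0)


@dataclass(frozen=True)
class BatchState:
    """State of a closed, well-mixed reactor."""

    c_tol: float          # toluene [µM]
    X: float              # suspended cells [cells L⁻¹]
    c_met: float = 0.0    # metabolite [µM]

    def __post_init__(self) -> None:
        for name in ("c_tol", "c_met", "X"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BatchTrajectory:
    """Time series of a batch simulation, aligned on ``times`` [day]."""

    times: np.ndarray
    c_tol: np.ndarray
    c_met: np.ndarray
    X: np.ndarray

    def state_at(self, i: int) -> BatchState:
        return BatchState(float(self.c_tol[i]), float(self.X[i]), float(self.c_met[i]))


def _monod(c: np.ndarray | float, K: float) -> np.ndarray | float:
    """Saturation factor c/(c+K) with safe limits at c=0 and K=0."""
    c = np.maximum(c, 0.0)
    denom = c + K
    return np.where(denom > 0, c / np.where(denom > 0, denom, 1.0), 0.0)


def _check_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValidationError("times must be a 1-D strictly increasing array with t >= 0")
    return t


def _integrate(rhs, y0: np.ndarray, times: np.ndarray, settings: SolverSettings) -> np.ndarray:
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), y0, method="RK45", t_eval=times,
        rtol=settings.ode_rel_tol,
        atol=[settings.ode_abs_tol, settings.ode_abs_tol, settings.ode_abs_tol * 1e6],
    )
    if not sol.success:
        raise RuntimeError(f"batch integrator failed: {sol.message}")
    return np.maximum(sol.y, 0.0)


def simulate_batch_monod(
    params: BiokineticParams,
    init: BatchState,
    times: Sequence[float],
    settings: SolverSettings = SolverSettings(),
) -> BatchTrajectory:
    """Integrate the standard Monod model at the requested times [day]."""
    if init.c_met != 0.0:
        raise ValidationError("standard Monod model has no metabolite pool; init.c_met must be 0")
    if not params.yield_Y > 0 or not params.mu_max >= 0:
        raise ValidationError("mu_max and yield_Y must be set")
    t = _check_times(times)

    mu, K, Y = params.mu_max, params.K_tol, params.yield_Y

    def rhs(_t, y):
        c, cm, X = y
        growth = mu * _monod(c, K) * X
        return (-growth / Y, 0.0, growth)

    y = _integrate(rhs, np.array([init.c_tol, init.c_met, init.X]), t, settings)
    return BatchTrajectory(t, y[0], y[1], y[2])


def simulate_batch_metabolite(
    params: BiokineticParams,
    init: BatchState,
    times: Sequence[float],
    settings: SolverSettings = SolverSettings(),
) -> BatchTrajectory:
    """Integrate the two-step metabolite-intermediate model."""
    if not params.yield_Y > 0:
        raise ValidationError("yield_Y must be set")
    t = _check_times(times)

    rt, rm = params.r_tol_max, params.r_met_max
    Kt, Km, Y = params.K_tol, params.K_met, params.yield_Y

    def rhs(_t, y):
        c, cm, X = y
        r_tol = rt * _monod(c, Kt) * X
        r_met = rm * _monod(cm, Km) * X
        return (-r_tol, r_tol - r_met, Y * r_met)

    y = _integrate(rhs, np.array([init.c_tol, init.c_met, init.X]), t, settings)
    return BatchTrajectory(t, y[0], y[1], y[2])


_SIMULATORS = {"monod": simulate_batch_monod, "metabolite": simulate_batch_metabolite}


def _replicate_sd(df, quantity: str, log10: bool) -> float | None:
    """Pooled per-time replicate SD of one quantity, or None if singletons."""
    sub = df[df["quantity"] == quantity]
    if sub.empty:
        return None
    values = sub["value"].to_numpy(dtype=float)
    if log10:
        sub = sub.assign(value=np.log10(np.maximum(values, 1.0)))
    sds = sub.groupby("time_h")["value"].std(ddof=1).dropna()
    if sds.empty:
        return None
    pooled = float(np.sqrt(np.mean(sds.to_numpy() ** 2)))
    return pooled if pooled > 0 else None


def fit_batch(
    obs: ObservationSet,
    variant: str,
    free: Iterable[str],
    init_guess: BiokineticParams,
    init: BatchState | dict[str, BatchState] | None = None,
    *,
    n_starts: int = 8,
    seed: int = 0,
    settings: SolverSettings = SolverSettings(),
    xtol: float = 1e-10,
) -> FitResult:
    """Calibrate a batch model variant to a tidy observation table.

    The table may contain several bottles (distinct ``experiment_id``
    values, e.g. different starting concentrations) which are fitted
    jointly with shared kinetic parameters — the way bottle series at
    several substrate levels are normally analysed, since high-substrate
    bottles constrain µ_max and Y while near-K bottles constrain K_tol.

    Toluene (and metabolite) residuals are taken on the linear scale, cell
    counts on the log₁₀ scale, each series divided by its observation-noise
    SD (estimated from replicate scatter when replicates are present).
    Optimization runs in log-parameter space from ``n_starts``
    Latin-hypercube starting points.

    ``init`` may be a single starting state, a {experiment_id: state}
    mapping, or None to take each bottle's t=0 observations as its start.
    """
    if variant not in _SIMULATORS:
        raise ValidationError(f"unknown variant {variant!r}")
    admissible = MONOD_PARAMS if variant == "monod" else METABOLITE_PARAMS
    free = list(free)
    bad = set(free) - set(admissible)
    if bad:
        raise ValidationError(f"free parameters {sorted(bad)} not used by variant {variant!r}")

    df = obs.df
    quantities = set(df["quantity"])
    if not {"toluene_uM", "cells_per_ml"} <= quantities:
        raise ValidationError("observations must include toluene_uM and cells_per_ml")

    sd_conc = _replicate_sd(df, "toluene_uM", log10=False) or _DEFAULT_CONC_SD
    sd_met = _replicate_sd(df, "metabolite_uM", log10=False) or _DEFAULT_CONC_SD
    sd_cells = _replicate_sd(df, "cells_per_ml", log10=True) or _DEFAULT_LOG10_SD
    simulate = _SIMULATORS[variant]

    # Per-bottle layout: initial state, unique times, row → time index.
    bottles = []
    offset = 0
    order = np.zeros(len(df), dtype=int)
    for exp_id, sub in df.groupby("experiment_id", sort=True):
        if isinstance(init, dict):
            b_init = init[exp_id]
        elif isinstance(init, BatchState):
            b_init = init
        else:
            t0 = sub["time_h"].min()
            first = sub[sub["time_h"] == t0]
            c0 = float(first.loc[first["quantity"] == "toluene_uM", "value"].mean())
            x0 = float(first.loc[first["quantity"] == "cells_per_ml", "value"].mean()) * 1e3
            b_init = BatchState(c_tol=c0, X=x0)
        times_day = np.unique(sub["time_h"].to_numpy(dtype=float)) / 24.0
        if len(times_day) < 2:
            raise ValidationError(f"bottle {exp_id!r} needs observations at two or more times")
        rows_t = sub["time_h"].to_numpy(dtype=float) / 24.0
        bottles.append({
            "init": b_init,
            "times": times_day,
            "t_index": np.searchsorted(times_day, rows_t),
            "q": sub["quantity"].to_numpy(),
            "v": sub["value"].to_numpy(dtype=float),
        })
        order[offset : offset + len(sub)] = sub.index.to_numpy()
        offset += len(sub)

    all_q = np.concatenate([b["q"] for b in bottles])

    def residual_fn(values: dict[str, float]) -> np.ndarray:
        params = init_guess.replace(**{k: values[k] for k in free})
        parts = []
        for b in bottles:
            b_init, times_day = b["init"], b["times"]
            if times_day[0] == 0.0:
                traj = simulate(params, b_init, times_day[1:], settings)
                c_tol = np.concatenate([[b_init.c_tol], traj.c_tol])
                c_met = np.concatenate([[b_init.c_met], traj.c_met])
                X = np.concatenate([[b_init.X], traj.X])
            else:
                traj = simulate(params, b_init, times_day, settings)
                c_tol, c_met, X = traj.c_tol, traj.c_met, traj.X
            res = np.empty(len(b["v"]))
            for q, model, sd, log in (
                ("toluene_uM", c_tol, sd_conc, False),
                ("metabolite_uM", c_met, sd_met, False),
                ("cells_per_ml", X / 1e3, sd_cells, True),
            ):
                mask = b["q"] == q
                if not np.any(mask):
                    continue
                m = model[b["t_index"][mask]]
                if log:
                    res[mask] = (np.log10(np.maximum(m, 1.0))
                                 - np.log10(np.maximum(b["v"][mask], 1.0))) / sd
                else:
                    res[mask] = (m - b["v"][mask]) / sd
            parts.append(res)
        return np.concatenate(parts)

    guess = {name: max(getattr(init_guess, name), 1e-300) for name in admissible}

    def split(r: np.ndarray) -> dict[str, np.ndarray]:
        return {q: r[all_q == q] for q in quantities}

    return fit_least_squares(
        residual_fn, free, guess, n_starts=n_starts, seed=seed,
        xtol=xtol, split_residuals=split,
    )
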