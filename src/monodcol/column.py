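"""1-D reactive-transport model of flow-through sediment columns.

Four coupled fields are solved on a cell-centred finite-volume grid:
aqueous toluene and oxygen (µM), mobile cells (cells mL⁻¹ pore water) and
attached cells (cells mL⁻¹ bulk sediment).  Growth of attached cells
follows dual Monod kinetics in the electron donor and acceptor; once the
attached population approaches its carrying capacity X_att_max, new-grown
cells are released to the mobile phase by a growth-proportional daughter
rate, while attachment of mobile cells is throttled by the same
capacity factor:

    r_att      = µ_max · c_tol/(c_tol+K_tol) · c_ox/(c_ox+K_ox) · X_att
    r_daughter = r_att · X_att / X_att_max
    r_attach   = k_att · X_mob · (1 − X_att / X_att_max)

    ∂c_tol/∂t = −v ∂c_tol/∂x + D ∂²c_tol/∂x² − (1/(nY)) r_att   [− mobile]
    ∂c_ox/∂t  = −v ∂c_ox/∂x  + D ∂²c_ox/∂x²  − (f_ox/(nY)) r_att
    ∂X_att/∂t = r_att + n·r_attach − r_daughter
    ∂X_mob/∂t = −v ∂X_mob/∂x + D ∂²X_mob/∂x² − r_attach + (1/n) r_daughter

Because X_att is counted per bulk-sediment volume while the aqueous
concentrations are per pore-water volume, the consumption terms carry the
1/n porosity factor — the mass-conservative form (the factor-n bookkeeping
is the same one the cell-exchange terms use).

Numerics: upwind advection, Danckwerts (flux) inlet / advective outlet
boundaries, implicit Euler in time with adaptive step control (halve on a
rejected step, grow 1.5× after easy convergence, capped at dt_max) and a
Newton-Raphson solve of the coupled nonlinear system per step with an
analytic Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fitting import FitResult, fit_least_squares
from .geometry import (
    BiokineticParams,
    ColumnGeometry,
    FlowCondition,
    SolverSettings,
    ValidationError,
    ML_PER_L,
    HOURS_PER_DAY,
    SECONDS_PER_DAY,
)
from .io import ExperimentConfig, ObservationSet

__all__ = [
    "ColumnState",
    "ColumnRecord",
    "SolverError",
    "growth_rates",
    "daughter_release_rate",
    "attachment_rate",
    "step_implicit_euler",
    "simulate_column",
    "logistic_variant_simulate",
    "steady_state_summary",
    "cumulative_toluene_degraded",
    "section_averages",
    "fit_column",
    "column_objective",
]


class SolverError(RuntimeError):
    """Raised when the implicit time stepper cannot advance the solution."""


@dataclass
class ColumnState:
    """Spatial fields of the column at one instant (inlet at index 0)."""

    x_centers: np.ndarray   # m
    c_tol: np.ndarray       # µM
    c_ox: np.ndarray        # µM
    X_mob: np.ndarray       # cells mL⁻¹ (pore water)
    X_att: np.ndarray       # cells mL_sed⁻¹ (bulk sediment)

    def __post_init__(self) -> None:
        n = len(self.x_centers)
        for name in ("c_tol", "c_ox", "X_mob", "X_att"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
            if np.any(arr < 0):
                raise ValidationError(f"{name} must be non-negative")
            setattr(self, name, arr)


@dataclass
class ColumnRecord:
    """Output of a column simulation sampled at the recording times."""

    times: np.ndarray        # day
    x_centers: np.ndarray    # m
    c_tol: np.ndarray        # (n_times, n_cells)
    c_ox: np.ndarray
    X_att: np.ndarray
    X_mob: np.ndarray | None
    config: ExperimentConfig
    balance: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def times_h(self) -> np.ndarray:
        return self.times * HOURS_PER_DAY

    @property
    def outlet_toluene(self) -> np.ndarray:
        return self.c_tol[:, -1]

    @property
    def outlet_oxygen(self) -> np.ndarray:
        return self.c_ox[:, -1]

    @property
    def outlet_cells(self) -> np.ndarray:
        if self.X_mob is None:
            raise ValidationError("this record has no mobile-cell field")
        return self.X_mob[:, -1]

    def state_at(self, i: int) -> ColumnState:
        x_mob = self.X_mob[i] if self.X_mob is not None else np.zeros_like(self.c_tol[i])
        return ColumnState(self.x_centers, self.c_tol[i], self.c_ox[i], x_mob, self.X_att[i])

    def section_series(self, field_name: str) -> dict[str, np.ndarray]:
        """Bottom/middle/top third averages of a field over time."""
        arr = getattr(self, field_name)
        return {
            loc: np.array([section_averages(row)[j] for row in arr])
            for j, loc in enumerate(("bottom", "middle", "top"))
        }


def section_averages(values: np.ndarray) -> np.ndarray:
    """Averages over the three equal-length thirds of the column (the
    bottom/middle/top sediment fractions, inlet side first)."""
    parts = np.array_split(np.asarray(values, dtype=float), 3)
    return np.array([p.mean() for p in parts])


# ---------------------------------------------------------------------------
# Kinetic rate laws (arrays over grid cells)


def _monod(c: np.ndarray, K: float) -> np.ndarray:
    c = np.maximum(c, 0.0)
    denom = c + K
    return np.where(denom > 0, c / np.where(denom > 0, denom, 1.0), 0.0)


def _dmonod(c: np.ndarray, K: float) -> np.ndarray:
    """d/dc of c/(c+K) evaluated at max(c, 0)."""
    if K == 0.0:
        return np.zeros_like(c)
    c = np.maximum(c, 0.0)
    return K / (c + K) ** 2


def _acceptor_factor(c_ox: np.ndarray, params: BiokineticParams) -> np.ndarray:
    """Monod factor of the electron acceptor; K_ox = 0 disables the factor
    (single-Monod mode, used when no acceptor kinetics were constrained)."""
    if params.K_ox == 0.0:
        if params.f_ox != 0.0:
            raise ValidationError("K_ox = 0 (acceptor factor disabled) requires f_ox = 0")
        return np.ones_like(np.asarray(c_ox, dtype=float))
    return _monod(c_ox, params.K_ox)


def growth_rates(
    state: ColumnState, params: BiokineticParams, mobile_growth: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Dual-Monod growth rates of attached and mobile cells per grid cell.

    Returns (r_att [cells mL_sed⁻¹ day⁻¹], r_mob [cells mL⁻¹ day⁻¹]);
    mobile growth is off by default — it is insignificant at the short
    water residence times these columns run at.
    """
    m = params.mu_max * _monod(state.c_tol, params.K_tol) * _acceptor_factor(state.c_ox, params)
    r_att = m * state.X_att
    r_mob = m * state.X_mob if mobile_growth else np.zeros_like(r_att)
    return r_att, r_mob


def daughter_release_rate(state: ColumnState, params: BiokineticParams) -> np.ndarray:
    """Release of new-grown attached cells to the mobile phase
    [cells mL_sed⁻¹ day⁻¹]: all growth is exported once X_att hits the
    carrying capacity."""
    if not params.X_att_max > 0:
        raise ValidationError("X_att_max must be > 0")
    r_att, _ = growth_rates(state, params)
    return r_att * state.X_att / params.X_att_max


def attachment_rate(state: ColumnState, params: BiokineticParams) -> np.ndarray:
    """Capacity-limited first-order attachment of mobile cells
    [cells mL⁻¹ day⁻¹]."""
    if not params.X_att_max > 0:
        raise ValidationError("X_att_max must be > 0")
    return params.k_att * state.X_mob * (1.0 - state.X_att / params.X_att_max)


# ---------------------------------------------------------------------------
# Finite-volume model


class _ColumnModel:
    """Discretized operator shared by the stepper, the simulator and the
    calibration routines.  Unknown ordering: [c_tol | c_ox | X_mob | X_att]
    (the logistic variant drops the X_mob block)."""

    def __init__(self, config: ExperimentConfig, variant: str = "full"):
        if variant not in ("full", "logistic"):
            raise ValidationError(f"unknown variant {variant!r}")
        self.config = config
        self.variant = variant
        geom, flow, params = config.geometry, config.flow, config.params
        if not params.X_att_max > 0:
            raise ValidationError("transport model requires X_att_max > 0")
        self.params = params
        self.n = geom.porosity
        self.N = max(int(round(geom.active_length / config.solver.dx)), 2)
        self.dx = geom.active_length / self.N
        self.x_centers = (np.arange(self.N) + 0.5) * self.dx

        from .geometry import pore_velocity, bulk_volume

        self.v = pore_velocity(geom, flow.flow_rate)         # m day⁻¹
        self.D = geom.dispersion_m2_day                      # m² day⁻¹
        self.q_l_day = flow.flow_rate * 1e-3 * HOURS_PER_DAY  # L day⁻¹
        self.bulk_ml = bulk_volume(geom)
        self.cell_bulk_ml = self.bulk_ml / self.N            # mL_sed per FV cell
        self.cell_water_ml = self.cell_bulk_ml * self.n      # mL water per FV cell

        # µM change per unit attached-growth rate [cells/mL_sed/day]:
        # (1/Y) µmol/mL_sed → /n per mL water → ×1e3 per litre.
        self.alpha = ML_PER_L / (self.n * params.yield_Y) if params.yield_Y > 0 else 0.0
        self.beta = ML_PER_L / params.yield_Y if params.yield_Y > 0 else 0.0

        # Transport operator: dc/dt = T c + b·c_in (upwind advection,
        # Danckwerts inlet, zero diffusive gradient at both ends).
        N, dx, v, D = self.N, self.dx, self.v, self.D
        T = np.zeros((N, N))
        adv, disp = v / dx, D / dx**2
        for i in range(N):
            T[i, i] -= adv
            if i > 0:
                T[i, i - 1] += adv + disp
                T[i, i] -= disp
            if i < N - 1:
                T[i, i + 1] += disp
                T[i, i] -= disp
        self.T = T
        self.b = np.zeros(N)
        self.b[0] = adv

        self.n_fields = 3 if variant == "logistic" else 4
        self.size = self.n_fields * N

    # -- state vector packing ------------------------------------------------

    def pack(self, state: ColumnState) -> np.ndarray:
        if self.variant == "logistic":
            return np.concatenate([state.c_tol, state.c_ox, state.X_att])
        return np.concatenate([state.c_tol, state.c_ox, state.X_mob, state.X_att])

    def unpack(self, u: np.ndarray) -> ColumnState:
        N = self.N
        c_tol, c_ox = u[:N], u[N : 2 * N]
        if self.variant == "logistic":
            return ColumnState(self.x_centers, np.maximum(c_tol, 0), np.maximum(c_ox, 0),
                               np.zeros(N), np.maximum(u[2 * N :], 0))
        return ColumnState(self.x_centers, np.maximum(c_tol, 0), np.maximum(c_ox, 0),
                           np.maximum(u[2 * N : 3 * N], 0), np.maximum(u[3 * N :], 0))

    def initial_state(self) -> ColumnState:
        N = self.N
        x_att0 = np.full(N, self.config.inoculum_cells / self.bulk_ml)
        return ColumnState(self.x_centers, np.zeros(N), np.zeros(N), np.zeros(N), x_att0)

    # -- right-hand side and Jacobian ---------------------------------------

    def _kinetics(self, c_tol, c_ox, X_mob, X_att):
        """Rates and their local derivatives on the raw (unclipped) fields."""
        p = self.params
        m_t, m_o = _monod(c_tol, p.K_tol), _acceptor_factor(c_ox, p)
        dm_t, dm_o = _dmonod(c_tol, p.K_tol), (
            _dmonod(c_ox, p.K_ox) if p.K_ox > 0 else np.zeros_like(c_ox)
        )
        mu = p.mu_max
        Xa = np.maximum(X_att, 0.0)
        r_att = mu * m_t * m_o * Xa
        k = {
            "r_att": r_att,
            "dr_att_dct": mu * dm_t * m_o * Xa,
            "dr_att_dco": mu * m_t * dm_o * Xa,
            "dr_att_dXa": mu * m_t * m_o,
        }
        if self.variant == "full":
            Xm = np.maximum(X_mob, 0.0)
            frac = Xa / p.X_att_max
            k["r_daughter"] = r_att * frac
            k["drd_dct"] = k["dr_att_dct"] * frac
            k["drd_dco"] = k["dr_att_dco"] * frac
            k["drd_dXa"] = k["dr_att_dXa"] * frac + r_att / p.X_att_max
            k["r_attach"] = p.k_att * Xm * (1.0 - frac)
            k["dra_dXm"] = p.k_att * (1.0 - frac)
            k["dra_dXa"] = -p.k_att * Xm / p.X_att_max
            if self.config.mobile_growth:
                k["r_mob"] = mu * m_t * m_o * Xm
                k["drm_dct"] = mu * dm_t * m_o * Xm
                k["drm_dco"] = mu * m_t * dm_o * Xm
                k["drm_dXm"] = mu * m_t * m_o
        return k

    def rhs(self, u: np.ndarray) -> np.ndarray:
        N, cfg, p = self.N, self.config, self.params
        c_tol, c_ox = u[:N], u[N : 2 * N]
        if self.variant == "logistic":
            X_mob, X_att = np.zeros(N), u[2 * N :]
        else:
            X_mob, X_att = u[2 * N : 3 * N], u[3 * N :]
        k = self._kinetics(c_tol, c_ox, X_mob, X_att)

        cons = self.alpha * k["r_att"]
        if cfg.mobile_growth and "r_mob" in k:
            cons = cons + self.beta * k["r_mob"]

        d_ct = self.T @ c_tol + self.b * cfg.flow.inlet_toluene - cons
        d_co = self.T @ c_ox + self.b * cfg.flow.inlet_oxygen - p.f_ox * cons

        if self.variant == "logistic":
            d_Xa = k["r_att"] * (1.0 - X_att / p.X_att_max)
            if cfg.freeze_biomass:
                d_Xa = np.zeros(N)
            return np.concatenate([d_ct, d_co, d_Xa])

        d_Xm = (self.T @ X_mob + self.b * cfg.flow.inlet_mobile_cells
                - k["r_attach"] + k["r_daughter"] / self.n)
        d_Xa = k["r_att"] + self.n * k["r_attach"] - k["r_daughter"]
        if cfg.mobile_growth and "r_mob" in k:
            d_Xm = d_Xm + k["r_mob"]
        if cfg.freeze_biomass:
            d_Xm = self.T @ X_mob + self.b * cfg.flow.inlet_mobile_cells
            d_Xa = np.zeros(N)
        return np.concatenate([d_ct, d_co, d_Xm, d_Xa])

    def jacobian(self, u: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs`."""
        N, cfg, p = self.N, self.config, self.params
        c_tol, c_ox = u[:N], u[N : 2 * N]
        if self.variant == "logistic":
            X_mob, X_att = np.zeros(N), u[2 * N :]
        else:
            X_mob, X_att = u[2 * N : 3 * N], u[3 * N :]
        k = self._kinetics(c_tol, c_ox, X_mob, X_att)

        J = np.zeros((self.size, self.size))
        idx = np.arange(N)
        tol, ox = idx, N + idx
        if self.variant == "logistic":
            att = 2 * N + idx
        else:
            mob, att = 2 * N + idx, 3 * N + idx

        J[:N, :N] += self.T
        J[N : 2 * N, N : 2 * N] += self.T

        dcons_ct, dcons_co, dcons_Xa = (
            self.alpha * k["dr_att_dct"], self.alpha * k["dr_att_dco"],
            self.alpha * k["dr_att_dXa"],
        )
        dcons_Xm = np.zeros(N)
        if cfg.mobile_growth and "r_mob" in k:
            dcons_ct = dcons_ct + self.beta * k["drm_dct"]
            dcons_co = dcons_co + self.beta * k["drm_dco"]
            dcons_Xm = self.beta * k["drm_dXm"]

        J[tol, tol] -= dcons_ct
        J[tol, ox] -= dcons_co
        J[tol, att] -= dcons_Xa
        J[ox, tol] -= p.f_ox * dcons_ct
        J[ox, ox] -= p.f_ox * dcons_co
        J[ox, att] -= p.f_ox * dcons_Xa
        if self.variant == "full":
            J[tol, mob] -= dcons_Xm
            J[ox, mob] -= p.f_ox * dcons_Xm

        if self.variant == "logistic":
            if not cfg.freeze_biomass:
                thr = 1.0 - X_att / p.X_att_max
                J[att, tol] += k["dr_att_dct"] * thr
                J[att, ox] += k["dr_att_dco"] * thr
                J[att, att] += k["dr_att_dXa"] * thr - k["r_att"] / p.X_att_max
            return J

        J[2 * N : 3 * N, 2 * N : 3 * N] += self.T
        if not cfg.freeze_biomass:
            inv_n = 1.0 / self.n
            J[mob, mob] += -k["dra_dXm"]
            J[mob, att] += -k["dra_dXa"] + inv_n * k["drd_dXa"]
            J[mob, tol] += inv_n * k["drd_dct"]
            J[mob, ox] += inv_n * k["drd_dco"]
            if cfg.mobile_growth and "r_mob" in k:
                J[mob, mob] += k["drm_dXm"]
                J[mob, tol] += k["drm_dct"]
                J[mob, ox] += k["drm_dco"]
            J[att, att] += k["dr_att_dXa"] + self.n * k["dra_dXa"] - k["drd_dXa"]
            J[att, tol] += k["dr_att_dct"] - k["drd_dct"]
            J[att, ox] += k["dr_att_dco"] - k["drd_dco"]
            J[att, mob] += self.n * k["dra_dXm"]
        return J

    # -- implicit Euler ------------------------------------------------------

    def newton_step(self, u_old: np.ndarray, dt: float) -> tuple[np.ndarray, int]:
        """One implicit Euler step of size dt [day].  Returns the new state
        vector and the Newton iteration count; raises SolverError on
        non-convergence."""
        settings = self.config.solver
        scales = self._field_scales()
        u = u_old.copy()
        for it in range(1, settings.newton_max_iters + 1):
            F = u - u_old - dt * self.rhs(u)
            J = np.eye(self.size) - dt * self.jacobian(u)
            try:
                delta = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError as exc:
                raise SolverError(f"singular Newton system: {exc}") from exc
            u = u + delta
            rel = np.max(np.abs(delta) / (np.abs(u) + scales))
            if rel < settings.newton_tol:
                if np.min(u / scales) < -1e-6:
                    raise SolverError("negative state after converged step")
                return np.maximum(u, 0.0), it
        raise SolverError(f"Newton did not converge in {settings.newton_max_iters} iterations")

    def _field_scales(self) -> np.ndarray:
        # Absolute floors per field for the relative-update convergence norm.
        N = self.N
        conc = np.full(N, 1e-3)                      # µM
        cells = np.full(N, 1.0)                      # cells mL⁻¹
        if self.variant == "logistic":
            return np.concatenate([conc, conc, cells])
        return np.concatenate([conc, conc, cells, cells])


def step_implicit_euler(
    state: ColumnState,
    dt: float,
    params: BiokineticParams,
    geom: ColumnGeometry,
    flow: FlowCondition,
    settings: SolverSettings = SolverSettings(),
    **config_kwargs,
) -> ColumnState:
    """Advance the coupled system by one implicit Euler step of dt [day].

    The step is solved fully coupled by Newton-Raphson; a non-convergent
    step raises SolverError (callers halve dt and retry).
    """
    if dt > settings.dt_max_days * (1 + 1e-12):
        raise ValidationError("dt exceeds settings.dt_max")
    # honour the caller's grid: derive dx from the state's cell count
    settings = SolverSettings(
        dx=geom.active_length / len(state.x_centers), dt_max=settings.dt_max,
        newton_tol=settings.newton_tol, newton_max_iters=settings.newton_max_iters,
        ode_rel_tol=settings.ode_rel_tol, ode_abs_tol=settings.ode_abs_tol,
        seed=settings.seed,
    )
    config = ExperimentConfig(geometry=geom, flow=flow, params=params,
                              solver=settings, **config_kwargs)
    model = _ColumnModel(config)
    u_new, _ = model.newton_step(model.pack(state), dt)
    return model.unpack(u_new)


_MIN_DT_DAYS = 1e-6 / SECONDS_PER_DAY  # 1 µs floor → solver error below this


def _march(model: _ColumnModel, output_times_day: np.ndarray) -> ColumnRecord:
    cfg = model.config
    state = model.initial_state()
    u = model.pack(state)
    N = model.N

    n_out = len(output_times_day)
    shape = (n_out, N)
    rec = {name: np.zeros(shape) for name in ("c_tol", "c_ox", "X_att")}
    x_mob_rec = np.zeros(shape) if model.variant == "full" else None

    # Cumulative mass bookkeeping (µmol / cells), updated per accepted step
    # from end-of-step fluxes — consistent with the implicit Euler balance.
    cum = {k: 0.0 for k in ("tol_in", "tol_out", "tol_consumed",
                            "ox_in", "ox_out", "ox_consumed",
                            "cells_in", "cells_out", "cells_grown")}
    bal = {k: np.zeros(n_out) for k in cum}

    def record_at(j: int, u_vec: np.ndarray) -> None:
        s = model.unpack(u_vec)
        rec["c_tol"][j], rec["c_ox"][j], rec["X_att"][j] = s.c_tol, s.c_ox, s.X_att
        if x_mob_rec is not None:
            x_mob_rec[j] = s.X_mob
        for k in cum:
            bal[k][j] = cum[k]

    t = 0.0
    j_out = 0
    if output_times_day[0] == 0.0:
        record_at(0, u)
        j_out = 1

    dt = min(cfg.solver.dt_max_days, output_times_day[-1] / 100.0)
    while j_out < n_out:
        t_target = output_times_day[j_out]
        dt_step = min(dt, cfg.solver.dt_max_days, t_target - t)
        try:
            u_new, iters = model.newton_step(u, dt_step)
        except SolverError:
            dt = dt_step / 2.0
            if dt < _MIN_DT_DAYS:
                raise SolverError(f"time step underflow at t = {t * 24:.3f} h")
            continue

        # end-of-step flux accounting (exact for implicit Euler)
        s = model.unpack(u_new)
        r_att, r_mob = growth_rates(s, model.params, cfg.mobile_growth)
        cons_umol = float(np.sum(model.alpha * r_att + model.beta * r_mob)
                          * model.cell_water_ml / ML_PER_L) * dt_step
        cum["tol_in"] += model.q_l_day * cfg.flow.inlet_toluene * dt_step
        cum["tol_out"] += model.q_l_day * s.c_tol[-1] * dt_step
        cum["tol_consumed"] += cons_umol
        cum["ox_in"] += model.q_l_day * cfg.flow.inlet_oxygen * dt_step
        cum["ox_out"] += model.q_l_day * s.c_ox[-1] * dt_step
        cum["ox_consumed"] += model.params.f_ox * cons_umol
        growth = float(np.sum(r_att) * model.cell_bulk_ml
                       + np.sum(r_mob) * model.cell_water_ml) * dt_step
        cum["cells_grown"] += growth
        cum["cells_in"] += model.q_l_day * ML_PER_L * cfg.flow.inlet_mobile_cells * dt_step
        if model.variant == "full":
            cum["cells_out"] += model.q_l_day * ML_PER_L * s.X_mob[-1] * dt_step

        u = u_new
        t += dt_step
        if iters <= 5:
            dt = min(dt_step * 1.5, cfg.solver.dt_max_days)
        else:
            dt = dt_step
        if abs(t - t_target) < 1e-12 or t >= t_target:
            record_at(j_out, u)
            j_out += 1

    return ColumnRecord(
        times=output_times_day, x_centers=model.x_centers,
        c_tol=rec["c_tol"], c_ox=rec["c_ox"], X_att=rec["X_att"],
        X_mob=x_mob_rec, config=cfg, balance=bal,
    )


def _output_times(config: ExperimentConfig, output_times_h: Sequence[float] | None) -> np.ndarray:
    if output_times_h is None:
        n = int(round(config.duration_h / config.output_dt_h))
        times_h = np.linspace(0.0, config.duration_h, n + 1)
    else:
        times_h = np.asarray(output_times_h, dtype=float)
        if times_h[0] != 0.0:
            times_h = np.concatenate([[0.0], times_h])
    if np.any(np.diff(times_h) <= 0):
        raise ValidationError("output times must be strictly increasing")
    return times_h / HOURS_PER_DAY


def simulate_column(
    config: ExperimentConfig, output_times_h: Sequence[float] | None = None
) -> ColumnRecord:
    """Run the full four-field reactive-transport simulation.

    Records all fields at the requested output times (default: every
    ``config.output_dt_h`` hours up to ``config.duration_h``).
    """
    model = _ColumnModel(config, variant="full")
    return _march(model, _output_times(config, output_times_h))


def logistic_variant_simulate(
    config: ExperimentConfig, output_times_h: Sequence[float] | None = None
) -> ColumnRecord:
    """Alternative model without explicit mobile cells: the growth term is
    throttled by the logistic factor (1 − X_att/X_att_max) while substrate
    consumption keeps the unthrottled rate.  Returns a record with
    ``X_mob is None``."""
    model = _ColumnModel(config, variant="logistic")
    return _march(model, _output_times(config, output_times_h))


# ---------------------------------------------------------------------------
# Derived summaries


def steady_state_summary(record: ColumnRecord) -> dict:
    """Steady in/out differences and the empirical ΔO₂/ΔTol ratio.

    Quasi-steady state requires the outlet toluene to change by less than
    1% (relative to max(outlet, 1% of inlet)) over the last 10% of the
    simulated time; otherwise the result is flagged ``steady=False``.
    """
    cfg = record.config
    t = record.times
    window = t >= t[-1] - 0.1 * (t[-1] - t[0])
    out_tol = record.outlet_toluene[window]
    scale = max(float(out_tol.mean()), 0.01 * cfg.flow.inlet_toluene)
    steady = bool((out_tol.max() - out_tol.min()) / scale < 0.01)

    d_tol = cfg.flow.inlet_toluene - float(record.outlet_toluene[-1])
    d_ox = cfg.flow.inlet_oxygen - float(record.outlet_oxygen[-1])
    summary = {
        "steady": steady,
        "dTol": d_tol,
        "dOx": d_ox,
        "outlet_X_mob": (float(record.outlet_cells[-1]) if record.X_mob is not None
                         else float("nan")),
        "f_ox_empirical": d_ox / d_tol if d_tol > 0 else float("nan"),
        "removal_pct": 100.0 * d_tol / cfg.flow.inlet_toluene,
    }
    return summary


def cumulative_toluene_degraded(record: ColumnRecord, t_end_h: float | None = None) -> float:
    """Cumulative toluene mass transformed [µmol]: trapezoidal integral of
    Q·(c_in − c_out) over the recorded breakthrough up to t_end_h."""
    times_h = record.times_h
    if t_end_h is None:
        t_end_h = float(times_h[-1])
    if t_end_h > times_h[-1] + 1e-9:
        raise ValidationError("record does not cover t_end")
    mask = times_h <= t_end_h + 1e-9
    q_l_h = record.config.flow.flow_rate * 1e-3
    removed = record.config.flow.inlet_toluene - record.outlet_toluene[mask]
    return float(np.trapezoid(q_l_h * removed, times_h[mask]))


# ---------------------------------------------------------------------------
# Calibration


_COLUMN_FREE = ("mu_max", "f_ox", "k_att")

_DEFAULT_CONC_SD = 3.0
_DEFAULT_LOG10_SD = 0.2 / math.log(10.0)


def _make_column_residual(
    obs: ObservationSet,
    config: ExperimentConfig,
    detection_floor_cells: float,
):
    """Build the weighted residual function shared by fitting and
    objective profiling.  Cell counts below the flow-cytometry detection
    floor are treated as censored: model and observation are both clamped
    to the floor, so a prediction anywhere below an at-floor observation
    contributes no misfit."""
    df = obs.df
    obs_times_h = np.unique(df["time_h"].to_numpy(dtype=float))
    rows_q = df["quantity"].to_numpy()
    rows_loc = df["location"].fillna("").to_numpy()
    rows_t = df["time_h"].to_numpy(dtype=float)
    rows_v = df["value"].to_numpy(dtype=float)

    from .batch import _replicate_sd  # same pooled-SD estimator

    sd_conc = _replicate_sd(df, "toluene_uM", log10=False) or _DEFAULT_CONC_SD
    sd_ox = _replicate_sd(df, "oxygen_uM", log10=False) or _DEFAULT_CONC_SD
    sd_cells = _replicate_sd(df, "cells_per_ml", log10=True) or _DEFAULT_LOG10_SD
    sd_att = _replicate_sd(df, "attached_cells_per_ml_sed", log10=True) or _DEFAULT_LOG10_SD
    sd_map = {"toluene_uM": (sd_conc, False), "oxygen_uM": (sd_ox, False),
              "cells_per_ml": (sd_cells, True), "attached_cells_per_ml_sed": (sd_att, True)}

    t_index = np.searchsorted(obs_times_h, rows_t)
    floor = max(detection_floor_cells, 1.0)

    def predictions(record: ColumnRecord) -> dict[tuple[str, str], np.ndarray]:
        rec_idx = np.searchsorted(record.times_h, obs_times_h)
        pred: dict[tuple[str, str], np.ndarray] = {
            ("toluene_uM", "outlet"): record.outlet_toluene[rec_idx],
            ("toluene_uM", "inlet"): np.full(len(obs_times_h), config.flow.inlet_toluene),
            ("oxygen_uM", "outlet"): record.outlet_oxygen[rec_idx],
            ("cells_per_ml", "outlet"): record.outlet_cells[rec_idx],
        }
        ox_sections = record.section_series("c_ox")
        att_sections = record.section_series("X_att")
        for loc in ("bottom", "middle", "top"):
            pred[("oxygen_uM", loc)] = ox_sections[loc][rec_idx]
            pred[("attached_cells_per_ml_sed", loc)] = att_sections[loc][rec_idx]
        return pred

    def residuals(params: BiokineticParams) -> np.ndarray:
        record = simulate_column(config.replace(params=params), output_times_h=obs_times_h)
        pred = predictions(record)
        res = np.empty(len(rows_v))
        res.fill(np.nan)
        for (q, loc), model in pred.items():
            mask = (rows_q == q) & (rows_loc == loc)
            if not np.any(mask):
                continue
            sd, log = sd_map[q]
            m = model[t_index[mask]]
            if log:
                res[mask] = (np.log10(np.maximum(m, floor))
                             - np.log10(np.maximum(rows_v[mask], floor))) / sd
            else:
                res[mask] = (m - rows_v[mask]) / sd
        if np.any(np.isnan(res)):
            raise ValidationError("observations contain series the model does not predict")
        return res

    return residuals, rows_q


def column_objective(
    obs: ObservationSet,
    params: BiokineticParams,
    config: ExperimentConfig,
    detection_floor_cells: float = 1e3,
) -> float:
    """Half the weighted sum of squared residuals of a forward simulation
    at fixed parameters — the quantity :func:`fit_column` minimizes."""
    residuals, _ = _make_column_residual(obs, config, detection_floor_cells)
    r = residuals(params)
    return 0.5 * float(np.sum(r**2))


def fit_column(
    obs: ObservationSet,
    free: Iterable[str],
    fixed: BiokineticParams,
    config: ExperimentConfig,
    *,
    n_starts: int = 4,
    seed: int = 0,
    xtol: float = 1e-8,
    max_nfev: int | None = None,
    detection_floor_cells: float = 1e3,
) -> FitResult:
    """Calibrate column parameters against breakthrough observations.

    ``free`` is a subset of {mu_max, f_ox, k_att} (the parameters the
    breakthrough data can constrain); everything else is taken from
    ``fixed``.  Cells enter the objective in log₁₀ space, concentrations
    linearly, each series scaled by its noise SD; the forward model is
    :func:`simulate_column`.
    """
    free = list(free)
    bad = set(free) - set(_COLUMN_FREE)
    if bad:
        raise ValidationError(f"free parameters {sorted(bad)} not calibratable here")

    residuals, rows_q = _make_column_residual(obs, config, detection_floor_cells)

    def residual_fn(values: dict[str, float]) -> np.ndarray:
        return residuals(fixed.replace(**{k: values[k] for k in free}))

    guess = {name: getattr(fixed, name) for name in BiokineticParams.__dataclass_fields__}
    for name in free:
        guess[name] = max(guess[name], 1e-12)

    def split(r: np.ndarray) -> dict[str, np.ndarray]:
        return {q: r[rows_q == q] for q in np.unique(rows_q)}

    return fit_least_squares(
        residual_fn, free, guess, n_starts=n_starts, seed=seed,
        xtol=xtol, max_nfev=max_nfev, diff_step=1e-4, split_residuals=split,
    )
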