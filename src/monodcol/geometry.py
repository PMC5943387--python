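"""Column geometry, flow arithmetic, and the shared parameter containers.

Internal unit convention (used by every solver in the package):

* length          metres
* time            days
* aqueous conc.   µM  (µmol per litre of pore water)
* mobile cells    cells per mL of pore water
* attached cells  cells per mL of bulk sediment

I/O-facing helpers accept the bench units the quantities are usually
reported in (cm, mL h⁻¹, minutes) and convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ValidationError",
    "ColumnGeometry",
    "FlowCondition",
    "BiokineticParams",
    "SolverSettings",
    "bulk_volume",
    "pore_volume",
    "residence_time",
    "pore_velocity",
    "flow_for_velocity",
    "SECONDS_PER_DAY",
    "HOURS_PER_DAY",
    "MINUTES_PER_DAY",
    "ML_PER_L",
]

SECONDS_PER_DAY = 86400.0
HOURS_PER_DAY = 24.0
MINUTES_PER_DAY = 1440.0
ML_PER_L = 1000.0

#: Longitudinal dispersion coefficient, stored in SI and converted once.
DISPERSION_M2_S = 1.95e-8
DISPERSION_M2_DAY = DISPERSION_M2_S * SECONDS_PER_DAY  # 1.685e-3 m² day⁻¹


class ValidationError(ValueError):
    """Raised when a domain object or config violates its invariants."""


@dataclass(frozen=True)
class ColumnGeometry:
    """Geometry of a saturated 1-D sediment column.

    Parameters
    ----------
    active_length : float
        Flow-through length of the sediment bed [m].
    inner_diameter : float
        Inner diameter of the column [m].
    porosity : float
        Volumetric pore fraction n, 0 < n < 1.
    dispersion_coeff : float
        Longitudinal dispersion coefficient D [m² s⁻¹].
    """

    active_length: float
    inner_diameter: float
    porosity: float
    dispersion_coeff: float = DISPERSION_M2_S

    def __post_init__(self) -> None:
        if not self.active_length > 0:
            raise ValidationError(f"active_length must be > 0, got {self.active_length}")
        if not self.inner_diameter > 0:
            raise ValidationError(f"inner_diameter must be > 0, got {self.inner_diameter}")
        if not 0.0 < self.porosity < 1.0:
            raise ValidationError(f"porosity must lie in (0, 1), got {self.porosity}")
        if self.dispersion_coeff < 0:
            raise ValidationError("dispersion_coeff must be >= 0")

    @classmethod
    def from_cm(
        cls,
        length_cm: float,
        diameter_cm: float,
        porosity: float,
        dispersion_m2_s: float = DISPERSION_M2_S,
    ) -> "ColumnGeometry":
        return cls(length_cm * 1e-2, diameter_cm * 1e-2, porosity, dispersion_m2_s)

    @property
    def cross_section_area(self) -> float:
        """Inner cross-section area [m²]."""
        return math.pi * (self.inner_diameter / 2.0) ** 2

    @property
    def dispersion_m2_day(self) -> float:
        return self.dispersion_coeff * SECONDS_PER_DAY


#: Bench geometry of the mini sediment columns used throughout the examples:
#: 1.6 cm active length, 1.34 cm inner diameter, porosity 0.3.
DEFAULT_GEOMETRY = ColumnGeometry.from_cm(1.6, 1.34, 0.3)


@dataclass(frozen=True)
class FlowCondition:
    """Inflow boundary condition of a column experiment.

    flow_rate [mL h⁻¹]; inlet concentrations in µM; inlet mobile cells
    in cells mL⁻¹ (usually 0 — the feed is cell-free).
    """

    flow_rate: float
    inlet_toluene: float
    inlet_oxygen: float
    inlet_mobile_cells: float = 0.0

    def __post_init__(self) -> None:
        if not self.flow_rate > 0:
            raise ValidationError(f"flow_rate must be > 0, got {self.flow_rate}")
        for name in ("inlet_toluene", "inlet_oxygen", "inlet_mobile_cells"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BiokineticParams:
    """Biokinetic rate and stoichiometry parameters.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate [day⁻¹].
    K_tol, K_ox, K_met : float
        Half-saturation concentrations of toluene, oxygen (electron
        acceptor) and the generic metabolite intermediate [µM].
    yield_Y : float
        Growth yield [cells µmol_tol⁻¹].
    f_ox : float
        Stoichiometric ratio of acceptor consumed per toluene degraded
        [µmol µmol⁻¹]; 9 would be full mineralization of toluene.
    k_att : float
        First-order attachment rate coefficient [day⁻¹].
    X_att_max : float
        Carrying capacity for attached cells [cells mL_sed⁻¹].
    r_tol_max, r_met_max : float
        Maximum specific transformation rates of the two-step batch model
        [µmol cell⁻¹ day⁻¹].
    """

    mu_max: float = 0.0
    K_tol: float = 0.0
    K_ox: float = 0.0
    yield_Y: float = 0.0
    f_ox: float = 0.0
    k_att: float = 0.0
    X_att_max: float = 0.0
    r_tol_max: float = 0.0
    r_met_max: float = 0.0
    K_met: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")

    def replace(self, **kwargs: float) -> "BiokineticParams":
        values = {name: getattr(self, name) for name in self.__dataclass_fields__}
        values.update(kwargs)
        return BiokineticParams(**values)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the batch integrator and the column solver."""

    dx: float = 0.5e-3            # spatial step [m]
    dt_max: float = 600.0         # maximum time step [s]
    newton_tol: float = 1e-8      # relative update-norm convergence
    newton_max_iters: int = 20
    ode_rel_tol: float = 1e-8
    ode_abs_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dx > 0:
            raise ValidationError("dx must be > 0")
        if not self.dt_max > 0:
            raise ValidationError("dt_max must be > 0")
        for name in ("newton_tol", "ode_rel_tol", "ode_abs_tol"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def dt_max_days(self) -> float:
        return self.dt_max / SECONDS_PER_DAY


# ---------------------------------------------------------------------------
# Flow arithmetic


def bulk_volume(geom: ColumnGeometry) -> float:
    """Bulk (sediment) volume of the column [mL]: π (d/2)² L."""
    return geom.cross_section_area * geom.active_length * 1e6


def pore_volume(geom: ColumnGeometry) -> float:
    """Water-filled pore volume [mL]: bulk volume × porosity."""
    return bulk_volume(geom) * geom.porosity


def residence_time(geom: ColumnGeometry, flow_rate_ml_h: float) -> float:
    """Mean water residence time [min] at volumetric flow Q [mL h⁻¹]."""
    if not flow_rate_ml_h > 0:
        raise ValidationError(f"flow rate must be > 0, got {flow_rate_ml_h}")
    return pore_volume(geom) / flow_rate_ml_h * 60.0


def pore_velocity(geom: ColumnGeometry, flow_rate_ml_h: float) -> float:
    """Linear pore-water velocity [m day⁻¹]: Q / (n · A)."""
    if not flow_rate_ml_h > 0:
        raise ValidationError(f"flow rate must be > 0, got {flow_rate_ml_h}")
    q_m3_day = flow_rate_ml_h * 1e-6 * HOURS_PER_DAY
    return q_m3_day / (geom.porosity * geom.cross_section_area)


def flow_for_velocity(geom: ColumnGeometry, velocity_m_day: float) -> float:
    """Inverse of :func:`pore_velocity`: flow rate [mL h⁻¹] for a target
    pore velocity [m day⁻¹]."""
    if not velocity_m_day > 0:
        raise ValidationError(f"velocity must be > 0, got {velocity_m_day}")
    q_m3_day = velocity_m_day * geom.porosity * geom.cross_section_area
    return q_m3_day * 1e6 / HOURS_PER_DAY
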