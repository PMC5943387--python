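"""Stoichiometric and biomass-accounting arithmetic.

Two independent routes to the carbon assimilation efficiency are covered:
from the oxygen/toluene consumption ratio f_ox, and from cell counts via
biovolume and cell carbon.  Both are simple closed-form conversions; the
point of the module is to keep the unit bookkeeping in one audited place.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .geometry import ValidationError

__all__ = [
    "CellMorphology",
    "YieldSummary",
    "f_ox_empirical",
    "mineralization_o2_demand",
    "denitrification_no3_demand",
    "assimilation_efficiency_from_fox",
    "biovolume_ellipsoid",
    "cell_carbon",
    "yield_from_counts",
    "efficiency_from_yield",
    "F_OX_FULL_TOLUENE",
    "DEFAULT_CARBON_PER_BIOVOLUME",
]

#: O₂ demand of complete toluene (C7H8) mineralization [mol/mol].
F_OX_FULL_TOLUENE = 9.0

#: fg C per µm³ of biovolume.  Back-derived from the 0.5 µm³ ↔ 130 fg C
#: pairing (carbon assumed to be 50% of cell dry mass); overridable.
DEFAULT_CARBON_PER_BIOVOLUME = 260.0

#: Molar mass of carbon [µg µmol⁻¹] and carbon atoms per toluene.
_CARBON_UG_PER_UMOL = 12.011
_TOLUENE_CARBONS = 7

_FORMULA_RE = re.compile(r"^C(\d*)H(\d*)$")


@dataclass(frozen=True)
class CellMorphology:
    """Average cell dimensions and carbon density used for count→carbon
    conversion.  Lengths in µm, carbon density in fg C µm⁻³."""

    length: float = 1.6
    width: float = 0.8
    carbon_per_biovolume: float = DEFAULT_CARBON_PER_BIOVOLUME

    def __post_init__(self) -> None:
        if not self.width > 0 or self.length < self.width:
            raise ValidationError("need length >= width > 0")
        if not self.carbon_per_biovolume > 0:
            raise ValidationError("carbon_per_biovolume must be > 0")


@dataclass(frozen=True)
class YieldSummary:
    """Growth yield and stoichiometry of one experiment."""

    yield_cells: float            # cells µmol_tol⁻¹
    f_ox: float                   # µmol O₂ µmol_tol⁻¹
    assimilation_efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.assimilation_efficiency <= 1.0:
            raise ValidationError("assimilation_efficiency must lie in [0, 1]")


def _parse_cxhy(formula: str) -> tuple[int, int]:
    m = _FORMULA_RE.match(formula.strip())
    if m is None:
        raise ValidationError(f"cannot parse hydrocarbon formula {formula!r} (expected CxHy)")
    x = int(m.group(1)) if m.group(1) else 1
    y = int(m.group(2)) if m.group(2) else 1
    if x < 1 or y < 0:
        raise ValidationError(f"non-physical formula {formula!r}")
    return x, y


def f_ox_empirical(delta_ox: float, delta_tol: float) -> float:
    """Empirical stoichiometric ratio ΔO₂/ΔTol [µmol µmol⁻¹]."""
    if not delta_tol > 0:
        raise ValidationError(f"delta_tol must be > 0, got {delta_tol}")
    return delta_ox / delta_tol


def mineralization_o2_demand(formula: str) -> float:
    """O₂ per hydrocarbon for complete mineralization [mol/mol].

    Balances CxHy + (x + y/4) O₂ → x CO₂ + (y/2) H₂O; toluene gives 9.
    """
    x, y = _parse_cxhy(formula)
    return x + y / 4.0


def denitrification_no3_demand(formula: str) -> float:
    """NO₃⁻ per hydrocarbon for complete oxidation with NO₃⁻ → N₂ [mol/mol].

    Electron balance: CxHy donates 4x + y electrons, each nitrate accepts 5;
    toluene gives 36/5 = 7.2 (70 µM toluene ⇒ 504 µM nitrate).
    """
    x, y = _parse_cxhy(formula)
    return (4 * x + y) / 5.0


def assimilation_efficiency_from_fox(f_ox: float, f_full: float = F_OX_FULL_TOLUENE) -> float:
    """Carbon assimilation efficiency 1 − f_ox/f_full.

    Under growth only the respired carbon consumes oxygen, so the shortfall
    of f_ox below the full-mineralization demand measures the assimilated
    fraction.
    """
    if f_ox < 0 or f_ox > f_full:
        raise ValidationError(f"f_ox must lie in [0, {f_full}], got {f_ox}")
    return 1.0 - f_ox / f_full


def biovolume_ellipsoid(length: float, width: float) -> float:
    """Biovolume of a prolate-spheroid cell [µm³]: (π/6)·L·W²."""
    import math

    if not width > 0 or length < width:
        raise ValidationError("need length >= width > 0")
    return math.pi / 6.0 * length * width**2


def cell_carbon(biovolume: float, morph: CellMorphology | None = None) -> float:
    """Carbon content of one cell [fg C] from its biovolume [µm³]."""
    if not biovolume > 0:
        raise ValidationError("biovolume must be > 0")
    density = (morph.carbon_per_biovolume if morph is not None
               else DEFAULT_CARBON_PER_BIOVOLUME)
    return biovolume * density


def yield_from_counts(new_cells: float, tol_degraded: float) -> float:
    """Growth yield [cells µmol⁻¹] from newly formed cells per toluene degraded."""
    if not tol_degraded > 0:
        raise ValidationError(f"tol_degraded must be > 0, got {tol_degraded}")
    if new_cells < 0:
        raise ValidationError("new_cells must be >= 0")
    return new_cells / tol_degraded


def efficiency_from_yield(yield_cells: float, carbon_per_cell: float = 130.0) -> float:
    """Carbon assimilation efficiency from a cell-count yield.

    Converts Y [cells µmol_tol⁻¹] × carbon_per_cell [fg] into µmol cell
    carbon per µmol toluene carbon (7 × 12.011 µg per µmol toluene).
    """
    if yield_cells < 0:
        raise ValidationError("yield must be >= 0")
    # fg → µg: 1e-9; µg C / (µg C per µmol C) = µmol C
    umol_cell_carbon = yield_cells * carbon_per_cell * 1e-9 / _CARBON_UG_PER_UMOL
    return umol_cell_carbon / _TOLUENE_CARBONS
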