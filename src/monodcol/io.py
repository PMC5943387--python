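"""Configuration handling, tidy observation tables, and bundled fixtures.

Experiment configs are YAML (or JSON) mappings with the blocks
``geometry``, ``flow``, ``params`` and optionally ``solver``; bench units
(cm, mL h⁻¹, mm, s) are converted to the internal convention on load.
Observation tables are tidy CSV with the columns
``experiment_id, replicate, time_h, location, quantity, value``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .geometry import (
    BiokineticParams,
    ColumnGeometry,
    FlowCondition,
    SolverSettings,
    ValidationError,
)

__all__ = [
    "ObservationSet",
    "ExperimentConfig",
    "load_config",
    "bundled_config",
    "read_observations",
    "paper_tables",
    "QUANTITY_UNITS",
    "OBS_COLUMNS",
]

OBS_COLUMNS = ["experiment_id", "replicate", "time_h", "location", "quantity", "value"]

QUANTITY_UNITS = {
    "toluene_uM": "µM",
    "oxygen_uM": "µM",
    "metabolite_uM": "µM",
    "cells_per_ml": "cells mL⁻¹",
    "attached_cells_per_ml_sed": "cells mL_sed⁻¹",
}

VALID_LOCATIONS = {"", "inlet", "outlet", "bottom", "middle", "top"}


@dataclass
class ObservationSet:
    """A tidy table of measured quantities with replicate structure."""

    df: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"observation table missing columns {missing}")
        self.df = self.df[OBS_COLUMNS].reset_index(drop=True)
        if not self.units:
            self.units = {q: QUANTITY_UNITS[q] for q in self.df["quantity"].unique()
                          if q in QUANTITY_UNITS}
        self.validate()

    def validate(self) -> None:
        unknown = set(self.df["quantity"]) - set(self.units)
        if unknown:
            raise ValidationError(f"units map does not cover quantities {sorted(unknown)}")
        bad_loc = set(self.df["location"].fillna("")) - VALID_LOCATIONS
        if bad_loc:
            raise ValidationError(f"unknown locations {sorted(bad_loc)}")
        if (self.df["value"] < 0).any():
            raise ValidationError("negative values for concentrations/counts")

    def subset(self, quantity: str, location: str | None = None) -> pd.DataFrame:
        sub = self.df[self.df["quantity"] == quantity]
        if location is not None:
            sub = sub[sub["location"] == location]
        return sub

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def concat(cls, parts: list["ObservationSet"], provenance: str = "") -> "ObservationSet":
        df = pd.concat([p.df for p in parts], ignore_index=True)
        units: dict[str, str] = {}
        for p in parts:
            units.update(p.units)
        return cls(df, units, provenance)


def read_observations(path: str | Path, provenance: str = "") -> ObservationSet:
    df = pd.read_csv(path)
    if "location" not in df.columns:
        df["location"] = ""
    df["location"] = df["location"].fillna("")
    return ObservationSet(df, provenance=provenance or str(path))


# ---------------------------------------------------------------------------
# Experiment configuration


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one column experiment run."""

    geometry: ColumnGeometry
    flow: FlowCondition
    params: BiokineticParams
    solver: SolverSettings = SolverSettings()
    duration_h: float = 192.0
    inoculum_cells: float = 1e5     # cells placed uniformly attached at t=0
    output_dt_h: float = 1.0
    mobile_growth: bool = False
    freeze_biomass: bool = False
    experiment_id: str = "experiment"

    def __post_init__(self) -> None:
        if not self.duration_h > 0:
            raise ValidationError("duration_h must be > 0")
        if self.inoculum_cells < 0:
            raise ValidationError("inoculum_cells must be >= 0")
        if not self.output_dt_h > 0:
            raise ValidationError("output_dt_h must be > 0")

    def replace(self, **kwargs) -> "ExperimentConfig":
        values = {name: getattr(self, name) for name in self.__dataclass_fields__}
        values.update(kwargs)
        return ExperimentConfig(**values)


_PARAM_KEYS = set(BiokineticParams.__dataclass_fields__)


def _require(block: dict, key: str, context: str):
    if key not in block:
        raise ValidationError(f"missing required key {context}.{key}")
    return block[key]


def _build_config(raw: dict, source: str = "") -> ExperimentConfig:
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping ({source})")
    for block in ("geometry", "flow", "params"):
        if block not in raw:
            raise ValidationError(f"missing required block '{block}'")

    g = raw["geometry"]
    try:
        geometry = ColumnGeometry.from_cm(
            _require(g, "length_cm", "geometry"),
            _require(g, "diameter_cm", "geometry"),
            _require(g, "porosity", "geometry"),
            g.get("dispersion_m2_s", 1.95e-8),
        )
    except ValidationError as exc:
        raise ValidationError(f"geometry: {exc}") from exc

    f = raw["flow"]
    try:
        flow = FlowCondition(
            _require(f, "rate_ml_h", "flow"),
            _require(f, "inlet_toluene_uM", "flow"),
            f.get("inlet_oxygen_uM", 250.0),
            f.get("inlet_cells_per_ml", 0.0),
        )
    except ValidationError as exc:
        raise ValidationError(f"flow: {exc}") from exc

    p = raw["params"]
    unknown = set(p) - _PARAM_KEYS
    if unknown:
        raise ValidationError(f"params: unknown keys {sorted(unknown)}")
    try:
        params = BiokineticParams(**{k: float(v) for k, v in p.items()})
    except ValidationError as exc:
        raise ValidationError(f"params: {exc}") from exc

    s = raw.get("solver", {})
    try:
        solver = SolverSettings(
            dx=s.get("dx_mm", 0.5) * 1e-3,
            dt_max=s.get("dt_max_s", 600.0),
            seed=int(s.get("seed", 0)),
        )
    except ValidationError as exc:
        raise ValidationError(f"solver: {exc}") from exc

    return ExperimentConfig(
        geometry=geometry,
        flow=flow,
        params=params,
        solver=solver,
        duration_h=float(raw.get("duration_h", 192.0)),
        inoculum_cells=float(raw.get("inoculum_cells", 1e5)),
        output_dt_h=float(raw.get("output_dt_h", 1.0)),
        mobile_growth=bool(raw.get("mobile_growth", False)),
        freeze_biomass=bool(raw.get("freeze_biomass", False)),
        experiment_id=str(raw.get("experiment_id", source or "experiment")),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment config from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _build_config(raw, source=path.stem)


def bundled_config(name: str) -> ExperimentConfig:
    """Load one of the packaged experiment configs (``exp_A`` … ``exp_G``)."""
    ref = resources.files("monodcol.data") / f"{name}.yaml"
    if not ref.is_file():
        raise ValidationError(f"no bundled config named {name!r}")
    return _build_config(yaml.safe_load(ref.read_text()), source=name)


def paper_tables() -> dict:
    """Packaged transcription of the published empirical summaries, model
    parameters and batch fit values, each entry tagged with its source."""
    ref = resources.files("monodcol.data") / "paper_tables.yaml"
    return yaml.safe_load(ref.read_text())
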