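"""Analyte panel domain model, configuration loading and unit conversion.

The panel describes the six-compound assay: MRM transitions (one quantifier
and at least zero qualifiers per analyte), average molar masses, retention
times and dual calibration ranges (mass concentration and molar). Mass
concentration in blood (ng/mL) and in lyophilized faeces (ng/g) share one
numeric scale; they are tags on the matrix, not different units — no density
correction is applied.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import PanelError

__all__ = [
    "MrmTransition",
    "Analyte",
    "InternalStandard",
    "AnalytePanel",
    "convert_concentration",
    "round_half_up",
    "format_endpoint",
    "load_panel",
    "default_panel",
    "DEFAULT_PANEL_NAME",
]

DEFAULT_PANEL_NAME = "rodenticides6"

_MOLAR_ALIASES = {"µM", "uM", "um", "μM", "umol/L", "µmol/L"}
_MASS_ALIASES = {"ng/mL", "ng/ml", "ng/g"}


def _normalise_unit(unit: str) -> str:
    if unit in _MOLAR_ALIASES:
        return "µM"
    if unit in _MASS_ALIASES:
        return "ng"  # ng/mL and ng/g are the same numeric scale
    raise ValueError(f"unknown concentration unit: {unit!r}")


def convert_concentration(
    value: float,
    from_unit: str,
    to_unit: str,
    molar_mass: float,
) -> float:
    """Convert between µM and mass concentration (ng/mL or ng/g).

    1 µM of a compound with molar mass M g/mol is numerically M ng/mL,
    so the conversion is a single multiplication/division; ng/mL and ng/g
    are treated as identical (matrix tag only). Round-trips are exact to
    machine precision.

    Raises
    ------
    PanelError
        If ``molar_mass`` is not strictly positive.
    ValueError
        If ``value`` is negative or a unit is unknown.
    """
    if molar_mass <= 0:
        raise PanelError(f"molar mass must be positive, got {molar_mass}")
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    src = _normalise_unit(from_unit)
    dst = _normalise_unit(to_unit)
    if src == dst:
        return value
    if src == "µM":
        return value * molar_mass
    return value / molar_mass


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_endpoint(value: float) -> float:
    """Print convention for calibration-range endpoints.

    Half-up to an integer at or above 100, to one decimal below.
    """
    if value >= 100:
        return round_half_up(value, 0)
    return round_half_up(value, 1)


class MrmTransition(BaseModel):
    """A single precursor -> product MRM transition."""

    precursor_mz: float = Field(gt=0)
    product_mz: float = Field(gt=0)
    role: Literal["quantifier", "qualifier"]
    cone_voltage: float = Field(ge=0)
    collision_energy: float = Field(ge=0)

    @model_validator(mode="after")
    def _check_masses(self) -> "MrmTransition":
        if not self.precursor_mz > self.product_mz:
            raise ValueError(
                f"precursor m/z ({self.precursor_mz}) must exceed product m/z "
                f"({self.product_mz})"
            )
        return self


class Analyte(BaseModel):
    """One panel compound with transitions and dual calibration range."""

    name: str
    molecular_formula: str = ""
    molar_mass: float = Field(gt=0, description="average molecular weight, g/mol")
    retention_time_min: float = Field(gt=0)
    transitions: list[MrmTransition] = Field(min_length=1)
    calibration_range_ng: tuple[float, float]
    calibration_range_um: tuple[float, float]

    @field_validator("calibration_range_ng", "calibration_range_um")
    @classmethod
    def _check_range(cls, rng: tuple[float, float]) -> tuple[float, float]:
        low, high = rng
        if not (0 < low < high):
            raise ValueError(f"range must satisfy 0 < low < high, got {rng}")
        return rng

    @model_validator(mode="after")
    def _check_consistency(self) -> "Analyte":
        n_quant = sum(1 for t in self.transitions if t.role == "quantifier")
        if n_quant != 1:
            raise ValueError(
                f"analyte {self.name!r} must have exactly one quantifier "
                f"transition, found {n_quant}"
            )
        # dual ranges must agree through the molar mass, after the print rounding
        for mass_ep, molar_ep in zip(self.calibration_range_ng, self.calibration_range_um):
            converted = format_endpoint(
                convert_concentration(molar_ep, "µM", "ng/mL", self.molar_mass)
            )
            if abs(mass_ep - converted) > 0.01 * converted:
                raise ValueError(
                    f"analyte {self.name!r}: mass endpoint {mass_ep} disagrees "
                    f"with µM endpoint {molar_ep} (-> {converted}) by more than 1%"
                )
        return self

    @property
    def quantifier(self) -> MrmTransition:
        return next(t for t in self.transitions if t.role == "quantifier")

    @property
    def qualifiers(self) -> list[MrmTransition]:
        return [t for t in self.transitions if t.role == "qualifier"]

    @property
    def loq(self) -> float:
        """LOQ policy: the lowest calibrator, in ng/mL (blood) or ng/g (faeces)."""
        return self.calibration_range_ng[0]


class InternalStandard(BaseModel):
    """Isotope-labelled internal standard added at a fixed working concentration."""

    name: str
    working_concentration_mg_per_l: float = Field(gt=0)
    retention_time_min: float = Field(gt=0)
    transitions: list[MrmTransition] = Field(min_length=1)


class AnalytePanel(BaseModel):
    name: str = "panel"
    analytes: list[Analyte] = Field(min_length=1)
    internal_standard: InternalStandard

    @model_validator(mode="after")
    def _check_unique(self) -> "AnalytePanel":
        names = [a.name for a in self.analytes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate analyte names: {sorted(dupes)}")
        if self.internal_standard.name in names:
            raise ValueError(
                f"internal standard {self.internal_standard.name!r} collides "
                "with an analyte name"
            )
        return self

    def __getitem__(self, name: str) -> Analyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def analyte_names(self) -> list[str]:
        return [a.name for a in self.analytes]


def load_panel(source: str | Path | dict[str, Any]) -> AnalytePanel:
    """Load and validate a panel from a YAML/JSON file path or a parsed dict.

    Raises :class:`PanelError` with the offending analyte named for any
    invariant violation (duplicate analytes, quantifier count, inconsistent
    dual ranges).
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if not path.exists():
            raise PanelError(f"panel file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PanelError(f"panel file {path} does not contain a mapping")
    try:
        return AnalytePanel.model_validate(raw)
    except ValidationError as exc:
        raise PanelError(f"invalid panel configuration: {exc}") from exc


def default_panel() -> AnalytePanel:
    """The bundled six-compound rodenticide panel."""
    ref = resources.files("toxiquant") / "panels" / f"{DEFAULT_PANEL_NAME}.yaml"
    with resources.as_file(ref) as path:
        return load_panel(path)
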