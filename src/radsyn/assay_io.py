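"""Shared data model, CSV schema readers/writers, and run configuration.

Every downstream stage (viability, clonogenic, growth, cohort) consumes the
validated record types defined here.  CSV is the single exchange format: one
header row, UTF-8, decimal point.  Group labels form a closed vocabulary
(``normal``, ``control``, ``radiation``, ``drug``, ``combination``) matched
case-insensitively; unknown labels are rejected rather than silently kept,
because downstream arithmetic (delay versus control, normalization to the
normal group) must be able to identify its anchor groups.

Days in caliper tables count from treatment start (day 0 = irradiation day).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "ViabilityWell",
    "ClonogenicRecord",
    "CaliperMeasurement",
    "AnimalRecord",
    "RunConfig",
    "SchemaError",
    "TableValidationError",
    "read_table",
    "write_report_table",
    "canonical_group",
]

#: Closed vocabulary of experimental arms.
GROUPS = ("normal", "control", "radiation", "drug", "combination")

#: Default coefficients (c1, c2, c3, c4) of the alamarBlue viability equation
#: 100 * (c1*A1 - c2*A2) / (c3*N2 - c4*N1), as supplied by the reagent
#: manufacturer for 570/600 nm absorbance pairs.
VIABILITY_COEFFICIENTS = (117216.0, 80586.0, 155677.0, 14652.0)

BIOCHEM_ANALYTES = ("alp", "alb", "alt", "ast", "bun", "cre")


class SchemaError(ValueError):
    """A table's header does not match the declared schema."""


class TableValidationError(ValueError):
    """One or more rows violate a type invariant; message lists line numbers."""


def canonical_group(label: str) -> str:
    """Normalize a group label; raise ``ValueError`` for unknown labels."""
    norm = str(label).strip().lower()
    if norm not in GROUPS:
        raise ValueError(
            f"unknown group label {label!r}; expected one of {GROUPS}"
        )
    return norm


def _finite(v: float, name: str) -> float:
    if not math.isfinite(v):
        raise ValueError(f"{name} must be finite, got {v!r}")
    return v


class ViabilityWell(BaseModel):
    """One well of an alamarBlue viability plate.

    ``a570``/``a600`` are raw absorbances at 570 and 600 nm.  Negative-control
    wells contain medium plus reagent but no cells and anchor the denominator
    of the viability equation.
    """

    model_config = ConfigDict(frozen=True)

    well_id: str
    dose: float = Field(ge=0, description="drug concentration, µM")
    a570: float
    a600: float
    is_negative_control: bool = False

    @field_validator("a570", "a600")
    @classmethod
    def _check_finite(cls, v: float) -> float:
        return _finite(v, "absorbance")


class ClonogenicRecord(BaseModel):
    """One dish of a clonogenic (colony formation) assay."""

    model_config = ConfigDict(frozen=True)

    radiation_gy: float = Field(ge=0)
    drug_um: float = Field(ge=0)
    cells_plated: int = Field(gt=0)
    colonies: int = Field(ge=0)
    replicate: int = 0

    @model_validator(mode="after")
    def _colonies_le_plated(self) -> "ClonogenicRecord":
        if self.colonies > self.cells_plated:
            raise ValueError(
                f"colonies ({self.colonies}) exceed cells plated "
                f"({self.cells_plated})"
            )
        return self


class CaliperMeasurement(BaseModel):
    """One caliper measurement of one animal on one day.

    Either all three dimensions (mm) or a pre-computed volume (mm³) must be
    present.
    """

    model_config = ConfigDict(frozen=True)

    animal_id: str
    group: str
    day: float = Field(ge=0)
    length_mm: float | None = Field(default=None, gt=0)
    width_mm: float | None = Field(default=None, gt=0)
    height_mm: float | None = Field(default=None, gt=0)
    volume_mm3: float | None = Field(default=None, ge=0)

    @field_validator("group")
    @classmethod
    def _check_group(cls, v: str) -> str:
        return canonical_group(v)

    @model_validator(mode="after")
    def _dims_or_volume(self) -> "CaliperMeasurement":
        dims = (self.length_mm, self.width_mm, self.height_mm)
        has_all_dims = all(d is not None for d in dims)
        if not has_all_dims and self.volume_mm3 is None:
            raise ValueError(
                "either all of length/width/height or volume_mm3 required"
            )
        return self


class AnimalRecord(BaseModel):
    """Terminal body/spleen weights and serum biochemistry for one animal."""

    model_config = ConfigDict(frozen=True)

    animal_id: str
    group: str
    body_weight_g: float = Field(gt=0)
    spleen_weight_g: float = Field(ge=0)
    biochem: Mapping[str, float] = Field(default_factory=dict)

    @field_validator("group")
    @classmethod
    def _check_group(cls, v: str) -> str:
        return canonical_group(v)

    @model_validator(mode="after")
    def _spleen_lt_body(self) -> "AnimalRecord":
        if self.spleen_weight_g >= self.body_weight_g:
            raise ValueError("spleen weight must be less than body weight")
        return self


class RunConfig(BaseModel):
    """Analysis-wide configuration.

    ``precision_mode`` selects between full floating-point arithmetic
    (``full``, the default) and ``printed`` mode, which rounds intermediate
    rates the way published summary tables conventionally do (ratios taken on
    two-decimal rates, combination index on whole-percent rates).
    """

    growth_threshold_mm3: float = Field(default=400.0, gt=0)
    volume_constant: float = Field(default=0.523, gt=0)
    evaluation_day: float = Field(default=26.0, ge=0)
    precision_mode: Literal["printed", "full"] = "full"
    viability_coefficients: tuple[float, float, float, float] = (
        VIABILITY_COEFFICIENTS
    )
    significance_thresholds: tuple[float, ...] = (0.05, 0.01, 0.001)
    seed: int = 0

    @field_validator("significance_thresholds")
    @classmethod
    def _strictly_decreasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(b >= a for a, b in zip(v, v[1:])):
            raise ValueError("significance thresholds must strictly decrease")
        return v


# ---------------------------------------------------------------------------
# CSV schemas

_SCHEMAS: dict[str, tuple[type[BaseModel], tuple[str, ...]]] = {
    "viability": (
        ViabilityWell,
        ("well_id", "dose_um", "a570", "a600", "is_negative_control"),
    ),
    "clonogenic": (
        ClonogenicRecord,
        ("radiation_gy", "drug_um", "cells_plated", "colonies", "replicate"),
    ),
    "caliper": (
        CaliperMeasurement,
        ("animal_id", "group", "day", "length_mm", "width_mm", "height_mm"),
    ),
    "animal": (
        AnimalRecord,
        ("animal_id", "group", "body_weight_g", "spleen_weight_g")
        + BIOCHEM_ANALYTES,
    ),
}

_CSV_TO_FIELD = {"dose_um": "dose"}


def _row_to_record(schema: str, row: Mapping[str, object]) -> BaseModel:
    model, _ = _SCHEMAS[schema]
    if schema == "viability":
        return ViabilityWell(
            well_id=str(row["well_id"]),
            dose=row["dose_um"],
            a570=row["a570"],
            a600=row["a600"],
            is_negative_control=_parse_bool(row["is_negative_control"]),
        )
    if schema == "clonogenic":
        return ClonogenicRecord(**{k: row[k] for k in _SCHEMAS[schema][1]})
    if schema == "caliper":
        kwargs = {
            "animal_id": str(row["animal_id"]),
            "group": row["group"],
            "day": row["day"],
        }
        for col in ("length_mm", "width_mm", "height_mm", "volume_mm3"):
            val = row.get(col)
            if val is not None and not (
                isinstance(val, float) and math.isnan(val)
            ):
                kwargs[col] = val
        return CaliperMeasurement(**kwargs)
    if schema == "animal":
        biochem = {
            a: float(row[a])
            for a in BIOCHEM_ANALYTES
            if a in row and row[a] is not None
            and not (isinstance(row[a], float) and math.isnan(row[a]))
        }
        return AnimalRecord(
            animal_id=str(row["animal_id"]),
            group=row["group"],
            body_weight_g=row["body_weight_g"],
            spleen_weight_g=row["spleen_weight_g"],
            biochem=biochem,
        )
    raise ValueError(f"unknown schema {schema!r}")


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def read_table(path: str | Path, schema: str) -> list[BaseModel]:
    """Read and validate a CSV table against one of the four assay schemas.

    Parameters
    ----------
    path
        CSV file with one header row.
    schema
        One of ``viability``, ``clonogenic``, ``caliper``, ``animal``.

    Returns
    -------
    list of validated records, in file order.

    Raises
    ------
    SchemaError
        If a required column is missing.
    TableValidationError
        If any row fails validation; the message names the offending CSV
        line numbers (header = line 1).
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    _, required = _SCHEMAS[schema]
    df = pd.read_csv(path)
    # volume_mm3 substitutes for the three dimensions in caliper tables
    if schema == "caliper" and "volume_mm3" in df.columns:
        required = ("animal_id", "group", "day")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing} "
            f"for schema {schema!r}"
        )

    records: list[BaseModel] = []
    errors: list[str] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        line = idx + 2  # header is line 1
        try:
            records.append(_row_to_record(schema, row))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise TableValidationError(
            f"{path.name}: {len(errors)} invalid row(s):\n"
            + "\n".join(errors)
        )

    _check_collection_invariants(schema, records, path)
    return records


def _check_collection_invariants(
    schema: str, records: Sequence[BaseModel], path: Path
) -> None:
    if schema == "viability" and records:
        if not any(w.is_negative_control for w in records):
            raise TableValidationError(
                f"{path.name}: plate has no negative-control well"
            )
    if schema == "caliper":
        seen: set[tuple[str, float]] = set()
        for rec in records:
            key = (rec.animal_id, rec.day)
            if key in seen:
                raise TableValidationError(
                    f"{path.name}: duplicate measurement for animal "
                    f"{rec.animal_id!r} on day {rec.day}"
                )
            seen.add(key)


def write_report_table(rows: Iterable[object], path: str | Path) -> None:
    """Write a collection of records or mappings to CSV at full precision.

    Reading the file back reproduces every stored value exactly (floats are
    serialized with ``repr`` round-trip precision).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to write an empty table")
    dicts = [
        r.model_dump() if isinstance(r, BaseModel) else dict(r) for r in rows
    ]
    df = pd.DataFrame(dicts)
    path = Path(path)
    df.to_csv(path, index=False, float_format=None)
    logger.info("wrote %d rows to %s", len(df), path)
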