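"""Reading, validation and writing of the four canonical tabular inputs.

All tables are tab-separated UTF-8 text with a mandatory header row and "."
as the decimal separator, matching the conventions of inForm-style per-cell
exports without binding to any vendor format.  The four canonical tables are

``cells.tsv``
    one row per segmented cell: ``patient_id``, ``field_id``, ``x_um``,
    ``y_um`` (micrometres, origin top-left of the field, y increasing
    downward), ``compartment`` (``epithelium`` / ``stroma`` / ``other``),
    binary marker calls ``cd3 cd8 foxp3 ki67 ck`` (0/1) and
    ``grb_intensity`` (granzyme-B cytoplasmic mean intensity on [0, 1]).

``fields.tsv``
    one row per imaged field: ``patient_id``, ``field_id``, the three
    compartment areas in mm^2 and the redundant ``epithelium_fraction``
    (checked for consistency on read).

``expression.tsv``
    gene x patient matrix; first column ``gene`` holds HGNC symbols, the
    remaining column names are patient IDs.

``clinical.tsv``
    one row per patient with survival endpoints (years, strictly positive),
    event flags and the clinical covariates used by the survival stage.

Validation is total: a malformed row raises a located error, never a
silent drop.  Fields are spatially disjoint; coordinates are only
comparable within one ``(patient_id, field_id)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TableValidationError",
    "CellRecord",
    "FieldSummary",
    "ClinicalRecord",
    "COMPARTMENTS",
    "MARKERS",
    "read_cell_table",
    "write_cell_table",
    "read_field_summary",
    "write_field_summary",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
]


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class TableValidationError(ValueError):
    """A row violates an invariant; carries the 0-based row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


COMPARTMENTS = ("epithelium", "stroma", "other")
MARKERS = ("cd3", "cd8", "foxp3", "ki67", "ck")

CELL_COLUMNS = [
    "patient_id", "field_id", "x_um", "y_um", "compartment",
    "cd3", "cd8", "foxp3", "ki67", "ck", "grb_intensity",
]
FIELD_COLUMNS = [
    "patient_id", "field_id",
    "area_epithelium_mm2", "area_stroma_mm2", "area_other_mm2",
    "epithelium_fraction",
]
AJCC_STAGES = ("I", "II", "III", "IV")
SIDES = ("right", "left")
SEXES = ("M", "F")
MSI_STATUSES = ("MSI-H", "MSS")
CMS_CLASSES = ("CMS1", "CMS2", "CMS3", "CMS4", "Mixed")
ICR_CLASSES = ("Low", "Medium", "High")
CLINICAL_COLUMNS = [
    "patient_id", "os_time", "os_event", "pfs_time", "pfs_event",
    "age", "sex", "side", "adjuvant", "ajcc", "msi", "cms", "icr",
]


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell with coordinates, compartment and marker state."""

    patient_id: str
    field_id: str
    x_um: float
    y_um: float
    compartment: str
    cd3: bool
    cd8: bool
    foxp3: bool
    ki67: bool
    ck: bool
    grb_intensity: float


@dataclass(frozen=True)
class FieldSummary:
    """Per-field compartment areas (mm^2); density denominators."""

    patient_id: str
    field_id: str
    area_epithelium_mm2: float
    area_stroma_mm2: float
    area_other_mm2: float
    epithelium_fraction: float


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    os_time: float
    os_event: bool
    pfs_time: float
    pfs_event: bool
    age: float
    sex: str
    side: str
    adjuvant: bool
    ajcc: str
    msi: str
    cms: str
    icr: str


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def _to_bool(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    vals = df[col]
    if vals.dtype == bool:
        return vals
    numeric = pd.to_numeric(vals, errors="coerce")
    bad = ~numeric.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableValidationError(
            f"{what}: column {col!r} must be 0/1, got {vals.iloc[row]!r}", row=row
        )
    return numeric.astype(bool)


def validate_cells(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize dtypes and enforce the per-cell invariants.

    Returns a new frame with canonical column order and dtypes; raises
    :class:`SchemaError` / :class:`TableValidationError` on any violation.
    """
    _require_columns(df, CELL_COLUMNS, "cell table")
    out = df[CELL_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["field_id"] = out["field_id"].astype(str)
    for col in ("x_um", "y_um", "grb_intensity"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
        bad = ~np.isfinite(out[col].to_numpy())
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TableValidationError(f"non-finite {col}", row=row)
    for col in ("x_um", "y_um"):
        neg = out[col].to_numpy() < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise TableValidationError(f"negative coordinate {col}", row=row)
    grb = out["grb_intensity"].to_numpy()
    oob = (grb < 0) | (grb > 1)
    if oob.any():
        row = int(np.flatnonzero(oob)[0])
        raise TableValidationError(
            f"grb_intensity {grb[row]} outside [0, 1]", row=row
        )
    out["compartment"] = out["compartment"].astype(str)
    bad = ~out["compartment"].isin(COMPARTMENTS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableValidationError(
            f"unknown compartment {out['compartment'].iloc[row]!r} "
            f"(expected one of {COMPARTMENTS})", row=row
        )
    for col in MARKERS:
        out[col] = _to_bool(out, col, "cell table")
    return out.reset_index(drop=True)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path, sep="\t", dtype={"patient_id": str, "field_id": str}, float_precision="round_trip"))


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    out = validate_cells(df).copy()
    for col in MARKERS:
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def validate_fields(df: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    _require_columns(df, FIELD_COLUMNS, "field table")
    out = df[FIELD_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["field_id"] = out["field_id"].astype(str)
    area_cols = ["area_epithelium_mm2", "area_stroma_mm2", "area_other_mm2"]
    for col in area_cols + ["epithelium_fraction"]:
        out[col] = pd.to_numeric(out[col], errors="coerce")
        bad = ~np.isfinite(out[col].to_numpy())
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TableValidationError(f"non-finite {col}", row=row)
        neg = out[col].to_numpy() < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise TableValidationError(f"negative {col}", row=row)
    total = out[area_cols].sum(axis=1).to_numpy()
    zero_total = total <= 0
    if zero_total.any():
        row = int(np.flatnonzero(zero_total)[0])
        raise TableValidationError("total field area is zero", row=row)
    expected = out["area_epithelium_mm2"].to_numpy() / total
    off = np.abs(expected - out["epithelium_fraction"].to_numpy()) > atol
    if off.any():
        row = int(np.flatnonzero(off)[0])
        raise TableValidationError(
            f"epithelium_fraction {out['epithelium_fraction'].iloc[row]} "
            f"disagrees with areas (expected {expected[row]})", row=row
        )
    dup = out.duplicated(subset=["patient_id", "field_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TableValidationError("duplicate (patient_id, field_id)", row=row)
    return out.reset_index(drop=True)


def read_field_summary(path: str | Path) -> pd.DataFrame:
    return validate_fields(pd.read_csv(path, sep="\t", dtype={"patient_id": str, "field_id": str}, float_precision="round_trip"))


def write_field_summary(df: pd.DataFrame, path: str | Path) -> None:
    validate_fields(df).to_csv(path, sep="\t", index=False)


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Expression matrix as a gene x patient frame (index = gene symbols)."""
    if df.index.name != "gene":
        if "gene" not in df.columns:
            raise SchemaError("expression table: first column must be 'gene'")
        df = df.set_index("gene")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise TableValidationError(f"duplicate gene symbol(s): {', '.join(map(str, dup))}")
    out = df.astype(float)
    if not np.isfinite(out.to_numpy()).all():
        raise TableValidationError("expression matrix contains non-finite values")
    out.index = out.index.astype(str)
    out.index.name = "gene"
    out.columns = out.columns.astype(str)
    return out


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    return validate_expression(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    validate_expression(df).to_csv(path, sep="\t", index=True)


def _check_enum(out: pd.DataFrame, col: str, allowed: tuple[str, ...]) -> None:
    bad = ~out[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableValidationError(
            f"{col} {out[col].iloc[row]!r} not in {allowed}", row=row
        )


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, CLINICAL_COLUMNS, "clinical table")
    out = df[CLINICAL_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    dup = out.duplicated(subset=["patient_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TableValidationError("duplicate patient_id", row=row)
    for col in ("os_time", "pfs_time", "age"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
        bad = ~np.isfinite(out[col].to_numpy())
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TableValidationError(f"non-finite {col}", row=row)
    for col in ("os_time", "pfs_time"):
        nonpos = out[col].to_numpy() <= 0
        if nonpos.any():
            row = int(np.flatnonzero(nonpos)[0])
            raise TableValidationError(f"{col} must be strictly positive", row=row)
    for col in ("os_event", "pfs_event", "adjuvant"):
        out[col] = _to_bool(out, col, "clinical table")
    for col in ("sex", "side", "ajcc", "msi", "cms", "icr"):
        out[col] = out[col].astype(str)
    _check_enum(out, "sex", SEXES)
    _check_enum(out, "side", SIDES)
    _check_enum(out, "ajcc", AJCC_STAGES)
    _check_enum(out, "msi", MSI_STATUSES)
    _check_enum(out, "cms", CMS_CLASSES)
    _check_enum(out, "icr", ICR_CLASSES)
    return out.reset_index(drop=True)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path, sep="\t", dtype={"patient_id": str}, float_precision="round_trip"))


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    out = validate_clinical(df).copy()
    for col in ("os_event", "pfs_event", "adjuvant"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def cells_to_records(df: pd.DataFrame) -> list[CellRecord]:
    df = validate_cells(df)
    return [CellRecord(**row) for row in df.to_dict("records")]


def records_to_cells(records: list[CellRecord]) -> pd.DataFrame:
    return validate_cells(pd.DataFrame([r.__dict__ for r in records]))
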