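"""Per-patient, compartment-resolved cell densities and marker fractions.

Densities are reported in cells/mm^2 per (patient, category, compartment)
for the epithelium and stroma compartments; "other" tissue (necrosis,
empty space) enters neither numerators nor denominators.  Patient-level
aggregation over a patient's fields is the pooled ratio

    density = (sum of counts over fields) / (sum of compartment areas),

i.e. area-weighted, not the mean of per-field densities.  Marker fractions
(percent Ki67+ or GrB+ within a parent category and compartment) use the
same pooled counts.  Undefined combinations (zero compartment area, zero
parent count) are emitted as NaN with a reason code, never silently as 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotyping import CATEGORIES

__all__ = [
    "compute_density",
    "compute_fraction",
    "build_metric_table",
    "DENSITY_COMPARTMENTS",
    "FRACTION_PARENTS",
    "FRACTION_MARKERS",
]

DENSITY_COMPARTMENTS = ("epithelium", "stroma")
#: parent categories for which marker-positive fractions are reported
FRACTION_PARENTS = ("T", "Th", "Treg", "CD8T")
#: marker -> category whose membership defines marker positivity within a parent
FRACTION_MARKERS = {"Ki67": "ki67", "GrB": "grb"}

_AREA_COL = {
    "epithelium": "area_epithelium_mm2",
    "stroma": "area_stroma_mm2",
    "other": "area_other_mm2",
}


def _patient_area(fields: pd.DataFrame, patient: str, compartment: str) -> float:
    sub = fields[fields["patient_id"] == patient]
    return float(sub[_AREA_COL[compartment]].sum())


def compute_density(
    gated: pd.DataFrame,
    fields: pd.DataFrame,
    category: str,
    compartment: str,
    patient: str,
) -> float:
    """Pooled density (cells/mm^2) of one category for one patient.

    Returns NaN when the patient's total compartment area is zero.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if compartment not in DENSITY_COMPARTMENTS:
        raise ValueError(f"density is defined for {DENSITY_COMPARTMENTS}, got {compartment!r}")
    area = _patient_area(fields, patient, compartment)
    if area <= 0:
        return float("nan")
    mask = (
        (gated["patient_id"] == patient)
        & (gated["compartment"] == compartment)
        & gated[f"is_{category}"]
    )
    return float(mask.sum()) / area


def compute_fraction(
    gated: pd.DataFrame,
    parent: str,
    marker: str,
    compartment: str,
    patient: str,
) -> float:
    """Percentage of ``parent``-category cells positive for ``marker``
    (``Ki67`` or ``GrB``) in one compartment; NaN when no parent cells."""
    if marker not in FRACTION_MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    sub = gated[
        (gated["patient_id"] == patient)
        & (gated["compartment"] == compartment)
        & gated[f"is_{parent}"]
    ]
    n_parent = len(sub)
    if n_parent == 0:
        return float("nan")
    if marker == "Ki67":
        n_pos = int(sub["ki67"].sum())
    else:
        # GrB positivity was resolved at gating time via the aCD8T gate for
        # CD8T parents; for other parents fall back to the gated intensity call
        n_pos = int(sub["is_aCD8T"].sum()) if parent == "CD8T" else int(
            (sub["grb_intensity"] >= 0.25).sum()
        )
    return 100.0 * n_pos / n_parent


def build_metric_table(
    gated: pd.DataFrame,
    fields: pd.DataFrame,
    grb_cutoff: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-patient density and fraction grids.

    Returns ``(density_table, fraction_table)``:

    * density_table: ``patient_id, category, compartment, count, area_mm2,
      density, reason`` — one row per patient x category x {epithelium,
      stroma}; ``reason`` is "" or ``zero_area``.
    * fraction_table: ``patient_id, parent, marker, compartment, n_parent,
      n_positive, percent, reason`` — ``reason`` is "" or ``no_parent_cells``.
    """
    patients = sorted(fields["patient_id"].unique())
    grb_pos = gated["grb_intensity"].to_numpy(float) >= grb_cutoff

    areas = fields.groupby("patient_id")[list(_AREA_COL.values())].sum()

    dens_rows = []
    frac_rows = []
    for patient in patients:
        sub = gated[gated["patient_id"] == patient]
        sub_grb = grb_pos[gated["patient_id"].to_numpy() == patient]
        for compartment in DENSITY_COMPARTMENTS:
            area = float(areas.loc[patient, _AREA_COL[compartment]]) if patient in areas.index else 0.0
            in_comp = sub["compartment"].to_numpy() == compartment
            for category in CATEGORIES:
                count = int((in_comp & sub[f"is_{category}"].to_numpy()).sum())
                if area > 0:
                    dens_rows.append((patient, category, compartment, count, area, count / area, ""))
                else:
                    dens_rows.append((patient, category, compartment, count, area, np.nan, "zero_area"))
            for parent in FRACTION_PARENTS:
                in_parent = in_comp & sub[f"is_{parent}"].to_numpy()
                n_parent = int(in_parent.sum())
                for marker in FRACTION_MARKERS:
                    if marker == "Ki67":
                        n_pos = int((in_parent & sub["ki67"].to_numpy()).sum())
                    else:
                        n_pos = int((in_parent & sub_grb).sum())
                    if n_parent > 0:
                        frac_rows.append(
                            (patient, parent, marker, compartment, n_parent, n_pos,
                             100.0 * n_pos / n_parent, "")
                        )
                    else:
                        frac_rows.append(
                            (patient, parent, marker, compartment, 0, 0, np.nan,
                             "no_parent_cells")
                        )

    density = pd.DataFrame(
        dens_rows,
        columns=["patient_id", "category", "compartment", "count", "area_mm2", "density", "reason"],
    )
    fraction = pd.DataFrame(
        frac_rows,
        columns=["patient_id", "parent", "marker", "compartment", "n_parent", "n_positive", "percent", "reason"],
    )
    return density, fraction


def density_wide(density: pd.DataFrame) -> pd.DataFrame:
    """Pivot the density table to patient x metric, columns named
    ``density_<category>_<compartment>``."""
    wide = density.pivot_table(
        index="patient_id", columns=["category", "compartment"], values="density",
        dropna=False,
    )
    wide.columns = [f"density_{cat}_{comp}" for cat, comp in wide.columns]
    return wide.sort_index(axis=1)
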