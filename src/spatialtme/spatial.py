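"""Nearest-neighbor distance statistics between phenotype categories.

All distances are Euclidean, in micrometres, computed strictly within one
imaged field (fields are separate 20x images; cross-field distances are
undefined).  For each ordered pair (source A, target B) the per-cell
statistic is the distance from an A-cell to the nearest B-cell in the same
field; a cell belonging to both categories is excluded as its own target
(self-exclusion by cell id).  Per-patient summaries are medians of the
per-cell distances pooled across the patient's fields (not medians of
per-field medians).

Distances from T-cell categories to tumor (CK+) cells are restricted to
source cells that are *not* intraepithelial — only T cells with compartment
!= epithelium contribute — while targets are all tumor cells in the field
regardless of compartment.  This avoids the trivially short distances of
T cells already inside the epithelium.

The cohort-level "overall nearest radius" is the median over patients of
the per-patient median CD3+ -> tumor nearest distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .phenotyping import T_CATEGORIES

__all__ = [
    "pairwise_distances",
    "nn_distance",
    "nn_to_tumor",
    "per_cell_nn_distances",
    "summarize_patient_distances",
    "build_distance_table",
    "overall_nearest_radius",
    "metric_correlation_matrix",
    "DEFAULT_DISTANCE_PAIRS",
    "distance_wide",
]

#: ordered (source, target) pairs reported by default: every T-cell category
#: to tumor cells, and the regulatory/effector subset pairs used for
#: stratification
DEFAULT_DISTANCE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    [(cat, "Tumor") for cat in T_CATEGORIES]
    + [
        ("Treg", "Th"), ("Th", "Treg"),
        ("Treg", "CD8T"), ("CD8T", "Treg"),
        ("Th", "CD8T"), ("CD8T", "Th"),
        ("Treg", "aCD8T"),
    ]
)


def pairwise_distances(points, field_ids=None) -> np.ndarray:
    """Full Euclidean distance matrix between points of one field.

    ``field_ids``, when given, is checked for uniqueness: distances across
    fields are undefined and raise a ValueError.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array with n >= 1")
    if field_ids is not None and len(np.unique(np.asarray(field_ids))) > 1:
        raise ValueError("points span multiple fields; cross-field distances are undefined")
    return cdist(pts, pts)


def nn_distance(source_xy, target_xy, source_ids=None, target_ids=None) -> np.ndarray:
    """Distance from each source point to its nearest target point.

    When ids are supplied, a source never matches the target with the same
    id (self-exclusion for overlapping categories).  Sources with no
    eligible target get NaN — never 0 or infinity.
    """
    src = np.atleast_2d(np.asarray(source_xy, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_xy, dtype=float))
    if src.size == 0:
        return np.empty(0)
    if tgt.size == 0:
        return np.full(src.shape[0], np.nan)

    tree = cKDTree(tgt)
    if source_ids is None or target_ids is None:
        d, _ = tree.query(src, k=1)
        return np.asarray(d, dtype=float)

    source_ids = np.asarray(source_ids)
    target_ids = np.asarray(target_ids)
    k = min(2, tgt.shape[0])
    d, idx = tree.query(src, k=k)
    d = np.atleast_2d(np.asarray(d, dtype=float).reshape(src.shape[0], k))
    idx = np.atleast_2d(np.asarray(idx).reshape(src.shape[0], k))
    out = np.empty(src.shape[0])
    for i in range(src.shape[0]):
        is_self = target_ids[idx[i]] == source_ids[i]
        valid = d[i][~is_self]
        out[i] = valid[0] if valid.size else np.nan
    return out


def per_cell_nn_distances(gated: pd.DataFrame, source: str, target: str) -> pd.DataFrame:
    """Per-cell nearest distances for one (source, target) category pair.

    Returns ``patient_id, field_id, cell_id, distance_um`` with one row per
    contributing source cell.  Fields without targets contribute nothing.
    For tumor targets, only non-intraepithelial source cells contribute.
    """
    restrict_source = target == "Tumor"
    rows = []
    for (pat, fid), sub in gated.groupby(["patient_id", "field_id"], sort=True):
        src = sub[sub[f"is_{source}"]]
        if restrict_source:
            src = src[src["compartment"] != "epithelium"]
        tgt = sub[sub[f"is_{target}"]]
        if len(src) == 0 or len(tgt) == 0:
            continue
        d = nn_distance(
            src[["x_um", "y_um"]].to_numpy(),
            tgt[["x_um", "y_um"]].to_numpy(),
            src["cell_id"].to_numpy(),
            tgt["cell_id"].to_numpy(),
        )
        keep = np.isfinite(d)
        if keep.any():
            rows.append(pd.DataFrame({
                "patient_id": pat,
                "field_id": fid,
                "cell_id": src["cell_id"].to_numpy()[keep],
                "distance_um": d[keep],
            }))
    if not rows:
        return pd.DataFrame(columns=["patient_id", "field_id", "cell_id", "distance_um"])
    return pd.concat(rows, ignore_index=True)


def nn_to_tumor(gated: pd.DataFrame, source: str) -> pd.DataFrame:
    """Per-cell distances from non-intraepithelial ``source`` cells to the
    nearest tumor cell of the same field."""
    return per_cell_nn_distances(gated, source, "Tumor")


def summarize_patient_distances(per_cell: pd.DataFrame) -> pd.DataFrame:
    """Median of pooled per-cell distances per patient.

    Returns ``patient_id, n_source_cells, median_um`` (mid-mean median
    convention for even counts, numpy default).
    """
    if len(per_cell) == 0:
        return pd.DataFrame(columns=["patient_id", "n_source_cells", "median_um"])
    g = per_cell.groupby("patient_id")["distance_um"]
    out = g.agg(n_source_cells="size", median_um="median").reset_index()
    out["n_source_cells"] = out["n_source_cells"].astype(int)
    return out


def build_distance_table(
    gated: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_DISTANCE_PAIRS,
) -> pd.DataFrame:
    """Per-patient median nearest-neighbor distances for each category pair.

    Columns: ``patient_id, source, target, n_source_cells, median_um``.
    Patients with no contributing cells for a pair are absent for that pair
    (missing, never zero).
    """
    frames = []
    for source, target in pairs:
        summary = summarize_patient_distances(per_cell_nn_distances(gated, source, target))
        summary.insert(1, "source", source)
        summary.insert(2, "target", target)
        frames.append(summary)
    if not frames:
        return pd.DataFrame(columns=["patient_id", "source", "target", "n_source_cells", "median_um"])
    return pd.concat(frames, ignore_index=True)


def overall_nearest_radius(
    distance_table: pd.DataFrame, source: str = "T", target: str = "Tumor"
) -> float:
    """Cohort-level nearest radius (µm): median over patients of the
    per-patient median ``source`` -> ``target`` nearest distance."""
    sub = distance_table[
        (distance_table["source"] == source) & (distance_table["target"] == target)
    ]
    if len(sub) == 0:
        return float("nan")
    return float(sub["median_um"].median())


def distance_wide(distance_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot to patient x metric, columns ``dist_<source>_<target>``."""
    if len(distance_table) == 0:
        return pd.DataFrame()
    wide = distance_table.pivot_table(
        index="patient_id", columns=["source", "target"], values="median_um",
        dropna=False,
    )
    wide.columns = [f"dist_{s}_{t}" for s, t in wide.columns]
    return wide.sort_index(axis=1)


def metric_correlation_matrix(metric_wide: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Inter-metric correlation matrix over patients (pairwise-complete).

    ``method`` is ``"pearson"`` or ``"spearman"``; the result is symmetric
    with unit diagonal (for metrics with nonzero variance).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return metric_wide.corr(method=method)
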