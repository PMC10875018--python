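"""Marker-combination gating into the ten T-cell / tumor phenotype categories.

Categories are *memberships*, not a partition: a CD3+CD8+Ki67+ cell belongs
simultaneously to T, CD8T and pCD8T (and pT).  The lattice is::

    T   = CD3+                        pT    = CD3+ Ki67+
    Th  = CD3+ CD8- FoxP3-            pTh   = Th  & Ki67+
    Treg= CD3+ FoxP3+                 pTreg = Treg & Ki67+
    CD8T= CD3+ CD8+                   pCD8T = CD8T & Ki67+
    aCD8T = CD8T & GrB+               Tumor = CK+ (& CD3- by default)

GrB (granzyme B) positivity is the one marker derived from a raw intensity
here, using a cytoplasmic mean-intensity cutoff on the [0, 1] scale
(default 0.25, boundary inclusive: intensity >= cutoff is positive).

A CD3+CD8+FoxP3+ cell qualifies for both Treg and CD8T — no mutual
exclusion is imposed beyond the marker definitions.  By default CD3+CK+
co-positive cells (rare segmentation artifacts) are excluded from both the
T-cell lattice and the Tumor class; both exclusions are flag-controlled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CellRecord, validate_cells

__all__ = [
    "CATEGORIES",
    "T_CATEGORIES",
    "DEFAULT_GRB_CUTOFF",
    "call_grb_positive",
    "assign_memberships",
    "gate_cohort",
    "category_counts",
]

#: the closed set of phenotype categories, supersets first
CATEGORIES = ("T", "pT", "Th", "pTh", "Treg", "pTreg", "CD8T", "pCD8T", "aCD8T", "Tumor")
T_CATEGORIES = CATEGORIES[:-1]

#: parent category in the subset lattice (used by property tests and
#: monotonicity checks; aCD8T/pCD8T are both children of CD8T)
PARENT = {
    "pT": "T", "Th": "T", "Treg": "T", "CD8T": "T",
    "pTh": "Th", "pTreg": "Treg", "pCD8T": "CD8T", "aCD8T": "CD8T",
}

DEFAULT_GRB_CUTOFF = 0.25


def call_grb_positive(grb_intensity, cutoff: float = DEFAULT_GRB_CUTOFF):
    """GrB positivity from cytoplasmic mean intensity (closed lower bound).

    Accepts a scalar or array; intensities must lie in [0, 1].
    """
    arr = np.asarray(grb_intensity, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("grb_intensity must lie in [0, 1]")
    pos = arr >= cutoff
    return bool(pos) if np.isscalar(grb_intensity) else pos


def _membership_masks(
    df: pd.DataFrame,
    grb_cutoff: float,
    tumor_excludes_cd3: bool,
    t_excludes_ck: bool,
) -> dict[str, np.ndarray]:
    cd3 = df["cd3"].to_numpy(bool)
    cd8 = df["cd8"].to_numpy(bool)
    foxp3 = df["foxp3"].to_numpy(bool)
    ki67 = df["ki67"].to_numpy(bool)
    ck = df["ck"].to_numpy(bool)
    grb = call_grb_positive(df["grb_intensity"].to_numpy(), grb_cutoff)

    t = cd3 & ~ck if t_excludes_ck else cd3
    th = t & ~cd8 & ~foxp3
    treg = t & foxp3
    cd8t = t & cd8
    return {
        "T": t,
        "pT": t & ki67,
        "Th": th,
        "pTh": th & ki67,
        "Treg": treg,
        "pTreg": treg & ki67,
        "CD8T": cd8t,
        "pCD8T": cd8t & ki67,
        "aCD8T": cd8t & grb,
        "Tumor": ck & ~cd3 if tumor_excludes_cd3 else ck,
    }


def assign_memberships(
    cell: CellRecord,
    grb_cutoff: float = DEFAULT_GRB_CUTOFF,
    tumor_excludes_cd3: bool = True,
    t_excludes_ck: bool = True,
) -> frozenset[str]:
    """Phenotype memberships of a single cell as a frozenset of names."""
    df = pd.DataFrame([cell.__dict__])
    masks = _membership_masks(df, grb_cutoff, tumor_excludes_cd3, t_excludes_ck)
    return frozenset(name for name, m in masks.items() if m[0])


def gate_cohort(
    cells: pd.DataFrame,
    grb_cutoff: float = DEFAULT_GRB_CUTOFF,
    tumor_excludes_cd3: bool = True,
    t_excludes_ck: bool = True,
) -> pd.DataFrame:
    """Annotate a cell table with one boolean column ``is_<category>`` per
    phenotype category, plus a unique ``cell_id``.

    Idempotent: re-gating a gated table recomputes the same columns.
    Membership is a pure function of the marker booleans, ``grb_intensity``
    and the configuration flags.
    """
    out = validate_cells(cells)
    masks = _membership_masks(out, grb_cutoff, tumor_excludes_cd3, t_excludes_ck)
    for name in CATEGORIES:
        out[f"is_{name}"] = masks[name]
    out["cell_id"] = np.arange(len(out))
    return out


def n_cd3_ck_copositive(cells: pd.DataFrame) -> int:
    """Count of CD3+CK+ co-positive cells excluded by the default gates."""
    df = validate_cells(cells)
    return int((df["cd3"].to_numpy(bool) & df["ck"].to_numpy(bool)).sum())


def category_counts(gated: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Per-category cell counts, optionally grouped (e.g. by patient/field)."""
    cols = [f"is_{c}" for c in CATEGORIES]
    if by:
        counts = gated.groupby(by, sort=True)[cols].sum().astype(int)
    else:
        counts = gated[cols].sum().astype(int).to_frame().T
    counts.columns = list(CATEGORIES)
    return counts
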