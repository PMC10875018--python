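"""Seeded synthetic mIF cohort generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes,
per imaged field and per patient:

* **Geometry** — each patient contributes ``fields_per_patient`` fields
  (default 4) of ``field_width_um x field_height_um``.  The tumor
  epithelium is a union of random discs, rejection-sampled until its area
  fraction reaches at least ``epithelium_fraction_min`` (default 0.30,
  mirroring the field-selection rule for tumor regions); small random
  discs carved out of the stroma form the "other" compartment (necrosis /
  empty space).
* **Tumor cells** — a homogeneous Poisson process on the epithelium mask
  (CK+ cells).
* **T cells** — each base class (Th, Treg, CD8T) is a Thomas cluster
  process: shared cluster parents (coordinated infiltration) with
  Gaussian offspring, thinned per compartment to planted intensities in
  cells/mm^2, all scaled by ``exp(density_loading * latent)`` where
  ``latent`` is the patient's latent immune-activity factor.  Treg
  cluster centres can be displaced a planted ``treg_offset_um`` from the
  shared parents, moving Treg cells away from the effector clusters.
* **Markers** — Ki67 is Bernoulli per class and compartment; granzyme-B
  intensity comes from a two-component mixture fully separated at the
  0.25 cutoff (active CD8 T cells from the high component).
* **Expression** — each panel gene is ``target_r * z + sqrt(1-r^2) * noise``
  (z = standardized latent), so corr(latent, gene) is planted exactly.
* **Survival** — exponential proportional hazards with planted log-HRs on
  *realized spatial covariates*: the above-median indicator of each
  patient's stromal Treg density (OS) and of the median Treg -> Th
  nearest-neighbor distance (PFS), plus an AJCC III/IV effect, with
  independent exponential censoring and an administrative follow-up cap.
  Because the hazard acts on the very metrics the analysis pipeline
  measures, median-split survival analysis can recover the planted hazard
  ratios directly.

Identical ``(params, seed)`` reproduce the cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box
from shapely.ops import unary_union

from . import io as io_tables
from .association import builtin_panels

__all__ = ["SimulationParams", "Cohort", "generate_field", "generate_cohort"]

UM2_PER_MM2 = 1e6


def _default_t_cell_intensity() -> dict:
    # cells/mm^2 at latent = 0; Th dominates, Treg ~ CD8T, all denser in stroma
    return {
        "Th": {"epithelium": 90.0, "stroma": 595.0},
        "Treg": {"epithelium": 30.0, "stroma": 150.0},
        "CD8T": {"epithelium": 35.0, "stroma": 160.0},
    }


def _default_ki67_prob() -> dict:
    # proliferating fraction, higher intraepithelially
    return {
        "Th": {"epithelium": 0.337, "stroma": 0.15},
        "Treg": {"epithelium": 0.25, "stroma": 0.12},
        "CD8T": {"epithelium": 0.148, "stroma": 0.08},
    }


def _default_grb_active_prob() -> dict:
    # GrB+ fraction within CD8 T cells
    return {"epithelium": 0.30, "stroma": 0.12}


def _default_gene_corr() -> dict:
    # planted corr(latent, gene) per panel
    return {"icr20": 0.7, "kegg_chemokine": 0.5, "kegg_cell_cell_interaction": 0.5}


@dataclass
class SimulationParams:
    """All planted cohort parameters (defaults are the study conditions)."""

    n_patients: int = 90
    fields_per_patient: int = 4
    field_width_um: float = 670.0
    field_height_um: float = 500.0
    epithelium_fraction_min: float = 0.30
    n_epithelium_discs: int = 5
    epithelium_disc_radius_um: tuple[float, float] = (90.0, 200.0)
    n_other_discs: int = 2
    other_disc_radius_um: tuple[float, float] = (20.0, 60.0)
    mask_retry_budget: int = 200
    tumor_intensity: float = 2000.0
    t_cell_intensity: dict = field(default_factory=_default_t_cell_intensity)
    other_intensity_scale: float = 0.2
    ki67_prob: dict = field(default_factory=_default_ki67_prob)
    grb_active_prob: dict = field(default_factory=_default_grb_active_prob)
    cluster_parent_intensity: float = 12.0  # parents per mm^2
    cluster_sigma_um: float = 30.0
    share_cluster_parents: bool = True
    treg_offset_um: float = 0.0
    latent_sd: float = 1.0
    density_loading: float = 0.35
    gene_corr: dict = field(default_factory=_default_gene_corr)
    expression_mean: float = 5.0
    baseline_hazard_os: float = 0.08   # events / year
    baseline_hazard_pfs: float = 0.10
    #: log-HR on above-median stromal Treg density (OS endpoint)
    beta_os_density_high: float = float(np.log(0.5))
    #: log-HR on above-median Treg -> Th nearest distance (PFS endpoint)
    beta_pfs_distance_high: float = float(np.log(0.281))
    beta_ajcc: float = float(np.log(2.0))    # log-HR, AJCC III/IV vs I/II
    censor_rate: float = 0.12  # / year
    followup_cap_years: float = 12.0


T_BASE_CLASSES = ("Th", "Treg", "CD8T")
_CLASS_MARKERS = {
    "Th": dict(cd3=True, cd8=False, foxp3=False, ck=False),
    "Treg": dict(cd3=True, cd8=False, foxp3=True, ck=False),
    "CD8T": dict(cd3=True, cd8=True, foxp3=False, ck=False),
    "Tumor": dict(cd3=False, cd8=False, foxp3=False, ck=True),
}


def _grb_negative(rng: np.random.Generator, n: int) -> np.ndarray:
    return 0.249 * rng.beta(2.0, 8.0, size=n)


def _grb_positive(rng: np.random.Generator, n: int) -> np.ndarray:
    return 0.25 + 0.75 * rng.beta(2.0, 6.0, size=n)


def _sample_on_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points on a shapely polygon by bbox rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 16)
        cand = np.column_stack([
            rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)
        ])
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[inside]])
    return pts[:n]


def _field_masks(params: SimulationParams, rng: np.random.Generator):
    """Rejection-sample the epithelium/other geometry of one field."""
    w, h = params.field_width_um, params.field_height_um
    frame = box(0.0, 0.0, w, h)
    r_lo, r_hi = params.epithelium_disc_radius_um
    for _ in range(params.mask_retry_budget):
        discs = [
            Point(rng.uniform(0, w), rng.uniform(0, h)).buffer(
                rng.uniform(r_lo, r_hi), quad_segs=64
            )
            for _ in range(params.n_epithelium_discs)
        ]
        epithelium = unary_union(discs).intersection(frame)
        if epithelium.area / frame.area >= params.epithelium_fraction_min:
            break
    else:
        raise RuntimeError(
            f"epithelium mask rejection exceeded {params.mask_retry_budget} retries"
        )
    o_lo, o_hi = params.other_disc_radius_um
    other_discs = [
        Point(rng.uniform(0, w), rng.uniform(0, h)).buffer(
            rng.uniform(o_lo, o_hi), quad_segs=64
        )
        for _ in range(params.n_other_discs)
    ]
    other = unary_union(other_discs).intersection(frame).difference(epithelium)
    return frame, epithelium, other


def _compartment_of(xy: np.ndarray, epithelium, other) -> np.ndarray:
    comp = np.full(len(xy), "stroma", dtype=object)
    if len(xy):
        in_epi = shapely.contains_xy(epithelium, xy[:, 0], xy[:, 1])
        comp[in_epi] = "epithelium"
        in_other = shapely.contains_xy(other, xy[:, 0], xy[:, 1]) & ~in_epi
        comp[in_other] = "other"
    return comp


def _thomas_points(
    params: SimulationParams,
    parents: np.ndarray,
    offsets: np.ndarray | None,
    lam_max_per_um2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring of a Thomas process given parent locations (per µm^2)."""
    w, h = params.field_width_um, params.field_height_um
    if len(parents) == 0 or lam_max_per_um2 <= 0:
        return np.empty((0, 2))
    kappa_per_um2 = params.cluster_parent_intensity / UM2_PER_MM2
    mu = lam_max_per_um2 / kappa_per_um2
    centers = parents if offsets is None else parents + offsets
    counts = rng.poisson(mu, size=len(centers))
    pts = np.repeat(centers, counts, axis=0) + rng.normal(
        0.0, params.cluster_sigma_um, size=(int(counts.sum()), 2)
    )
    inside = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
    return pts[inside]


def generate_field(
    params: SimulationParams,
    latent: float,
    rng: np.random.Generator,
    patient_id: str = "P001",
    field_id: str = "F1",
) -> tuple[pd.DataFrame, dict]:
    """One imaged field: a validated cell table plus its field-summary row."""
    frame, epithelium, other = _field_masks(params, rng)
    area_epi_mm2 = epithelium.area / UM2_PER_MM2
    area_other_mm2 = other.area / UM2_PER_MM2
    area_total_mm2 = frame.area / UM2_PER_MM2
    area_stroma_mm2 = area_total_mm2 - area_epi_mm2 - area_other_mm2

    rows: list[pd.DataFrame] = []

    n_tumor = rng.poisson(params.tumor_intensity * area_epi_mm2)
    tumor_xy = _sample_on_polygon(epithelium, n_tumor, rng)

    # shared cluster parents on an expanded window so edge clusters still
    # contribute offspring inside the field (4-sigma margin)
    w, h = params.field_width_um, params.field_height_um
    margin = 4.0 * params.cluster_sigma_um
    kappa_per_um2 = params.cluster_parent_intensity / UM2_PER_MM2
    expanded_area = (w + 2 * margin) * (h + 2 * margin)
    n_parents = rng.poisson(kappa_per_um2 * expanded_area)
    shared_parents = np.column_stack([
        rng.uniform(-margin, w + margin, n_parents),
        rng.uniform(-margin, h + margin, n_parents),
    ])
    # planted Treg displacement: one random unit direction per parent
    theta = rng.uniform(0, 2 * np.pi, n_parents)
    treg_offsets = params.treg_offset_um * np.column_stack([np.cos(theta), np.sin(theta)])

    scale = float(np.exp(params.density_loading * latent))
    for cls in T_BASE_CLASSES:
        if not params.share_cluster_parents:
            n_p = rng.poisson(kappa_per_um2 * expanded_area)
            parents = np.column_stack([
                rng.uniform(-margin, w + margin, n_p),
                rng.uniform(-margin, h + margin, n_p),
            ])
            offsets = None
        else:
            parents = shared_parents
            offsets = treg_offsets if cls == "Treg" else None
        lam = {
            "epithelium": params.t_cell_intensity[cls]["epithelium"] * scale,
            "stroma": params.t_cell_intensity[cls]["stroma"] * scale,
        }
        lam["other"] = params.other_intensity_scale * lam["stroma"]
        lam_max = max(lam.values())
        pts = _thomas_points(params, parents, offsets, lam_max / UM2_PER_MM2, rng)
        comp = _compartment_of(pts, epithelium, other)
        keep_prob = np.array([lam[c] / lam_max for c in comp]) if len(pts) else np.empty(0)
        keep = rng.uniform(size=len(pts)) < keep_prob
        pts, comp = pts[keep], comp[keep]
        n = len(pts)
        ki = np.array([
            rng.uniform() < params.ki67_prob[cls].get(c, params.ki67_prob[cls]["stroma"])
            for c in comp
        ], dtype=bool) if n else np.zeros(0, bool)
        if cls == "CD8T" and n:
            p_act = np.array([
                params.grb_active_prob.get(c, params.grb_active_prob["stroma"])
                for c in comp
            ])
            active = rng.uniform(size=n) < p_act
            grb = np.where(active, _grb_positive(rng, n), _grb_negative(rng, n))
        else:
            grb = _grb_negative(rng, n)
        m = _CLASS_MARKERS[cls]
        rows.append(pd.DataFrame({
            "patient_id": patient_id, "field_id": field_id,
            "x_um": pts[:, 0], "y_um": pts[:, 1], "compartment": comp,
            "cd3": m["cd3"], "cd8": m["cd8"], "foxp3": m["foxp3"],
            "ki67": ki, "ck": m["ck"], "grb_intensity": grb,
        }))

    m = _CLASS_MARKERS["Tumor"]
    rows.append(pd.DataFrame({
        "patient_id": patient_id, "field_id": field_id,
        "x_um": tumor_xy[:, 0], "y_um": tumor_xy[:, 1],
        "compartment": "epithelium",
        "cd3": m["cd3"], "cd8": m["cd8"], "foxp3": m["foxp3"],
        "ki67": rng.uniform(size=n_tumor) < 0.2, "ck": m["ck"],
        "grb_intensity": _grb_negative(rng, n_tumor),
    }))

    cells = pd.concat(rows, ignore_index=True)
    cells = io_tables.validate_cells(cells)
    summary = {
        "patient_id": patient_id,
        "field_id": field_id,
        "area_epithelium_mm2": area_epi_mm2,
        "area_stroma_mm2": area_stroma_mm2,
        "area_other_mm2": area_other_mm2,
        "epithelium_fraction": area_epi_mm2 / area_total_mm2,
    }
    return cells, summary


@dataclass
class Cohort:
    """A generated cohort plus its planted ground truth."""

    cells: pd.DataFrame
    fields: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth_patients: pd.DataFrame   # per-patient latent factor and hazard group
    truth_genes: pd.DataFrame      # per-gene planted corr(latent, gene)
    truth_scalars: dict            # planted betas, offset, intensities
    params: SimulationParams
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cells": outdir / "cells.tsv",
            "fields": outdir / "fields.tsv",
            "expression": outdir / "expression.tsv",
            "clinical": outdir / "clinical.tsv",
            "ground_truth_patients": outdir / "ground_truth_patients.tsv",
            "ground_truth_genes": outdir / "ground_truth_genes.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        io_tables.write_cell_table(self.cells, paths["cells"])
        io_tables.write_field_summary(self.fields, paths["fields"])
        io_tables.write_expression_matrix(self.expression, paths["expression"])
        io_tables.write_clinical_table(self.clinical, paths["clinical"])
        self.truth_patients.to_csv(paths["ground_truth_patients"], sep="\t", index=False)
        self.truth_genes.to_csv(paths["ground_truth_genes"], sep="\t", index=False)
        paths["ground_truth"].write_text(
            json.dumps(self.truth_scalars, indent=2, sort_keys=True) + "\n"
        )
        return paths


def _spatial_covariates(
    cells: pd.DataFrame, fields: pd.DataFrame, patients: list[str]
) -> pd.DataFrame:
    """Realized per-patient spatial covariates the hazard is planted on:
    stromal Treg density and median Treg -> Th nearest distance, with their
    above-median (high = 1) indicators; missing metrics count as low."""
    from .phenotyping import gate_cohort
    from .quantification import compute_density
    from .spatial import build_distance_table

    gated = gate_cohort(cells)
    dens = pd.Series(
        {p: compute_density(gated, fields, "Treg", "stroma", p) for p in patients}
    )
    dist_table = build_distance_table(gated, pairs=(("Treg", "Th"),))
    dist = dist_table.set_index("patient_id")["median_um"].reindex(patients)
    out = pd.DataFrame({
        "patient_id": patients,
        "density_treg_stroma": dens.to_numpy(),
        "dist_treg_th_um": dist.to_numpy(),
    })
    for col, ind in (("density_treg_stroma", "density_treg_stroma_high"),
                     ("dist_treg_th_um", "dist_treg_th_high")):
        v = out[col]
        out[ind] = ((v > v.median()) & v.notna()).astype(int)
    return out


def _simulate_clinical(
    params: SimulationParams,
    patients: list[str],
    latent: np.ndarray,
    spatial_cov: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(patients)
    latent_high = (latent > np.median(latent)).astype(int)
    dens_high = spatial_cov["density_treg_stroma_high"].to_numpy()
    dist_high = spatial_cov["dist_treg_th_high"].to_numpy()
    age = np.clip(np.round(rng.normal(68, 10, n)), 30, 95)
    sex = rng.choice(["M", "F"], size=n)
    side = rng.choice(["right", "left"], size=n)
    adjuvant = rng.uniform(size=n) < 0.35
    ajcc = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.15, 0.35, 0.35, 0.15])
    ajcc34 = np.isin(ajcc, ["III", "IV"]).astype(int)
    msi = np.where(rng.uniform(size=n) < 0.10 + 0.10 * latent_high, "MSI-H", "MSS")
    cms = rng.choice(["CMS1", "CMS2", "CMS3", "CMS4", "Mixed"], size=n,
                     p=[0.15, 0.35, 0.15, 0.25, 0.10])
    # ICR class from latent tertiles: the latent factor IS immune activity
    terciles = np.quantile(latent, [1 / 3, 2 / 3])
    icr = np.where(latent <= terciles[0], "Low",
                   np.where(latent <= terciles[1], "Medium", "High"))

    def _endpoint(h0: float, beta: float, covariate: np.ndarray):
        rate = h0 * np.exp(beta * covariate + params.beta_ajcc * ajcc34)
        t = rng.exponential(1.0 / rate)
        c = np.minimum(rng.exponential(1.0 / params.censor_rate, n),
                       params.followup_cap_years)
        time = np.maximum(np.minimum(t, c), 1e-6)
        event = t <= c
        return time, event

    os_time, os_event = _endpoint(
        params.baseline_hazard_os, params.beta_os_density_high, dens_high)
    pfs_time, pfs_event = _endpoint(
        params.baseline_hazard_pfs, params.beta_pfs_distance_high, dist_high)

    clinical = pd.DataFrame({
        "patient_id": patients,
        "os_time": os_time, "os_event": os_event,
        "pfs_time": pfs_time, "pfs_event": pfs_event,
        "age": age, "sex": sex, "side": side, "adjuvant": adjuvant,
        "ajcc": ajcc, "msi": msi, "cms": cms, "icr": icr,
    })
    truth = pd.DataFrame({
        "patient_id": patients,
        "latent": latent,
        "latent_high": latent_high,
        "ajcc_III_IV": ajcc34,
    }).merge(spatial_cov, on="patient_id")
    return clinical, truth


def _simulate_expression(
    params: SimulationParams,
    patients: list[str],
    latent: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    z = latent / params.latent_sd
    gene_rows, truth_rows = [], []
    seen: set[str] = set()
    for panel_name, panel in builtin_panels().items():
        r = float(params.gene_corr.get(panel_name, 0.0))
        for gene in panel.symbols:
            if gene in seen:
                continue
            seen.add(gene)
            noise = rng.normal(size=len(patients))
            values = params.expression_mean + r * z + np.sqrt(1 - r**2) * noise
            gene_rows.append(pd.Series(values, index=patients, name=gene))
            truth_rows.append((gene, panel_name, r))
    expression = pd.DataFrame(gene_rows)
    expression.index.name = "gene"
    truth = pd.DataFrame(truth_rows, columns=["gene", "panel", "target_r"])
    return expression, truth


def generate_cohort(params: SimulationParams | None = None, seed: int = 0) -> Cohort:
    """Generate a full cohort: cells, field summaries, expression matrix,
    clinical table, and planted ground truth.  Deterministic in (params, seed)."""
    params = params or SimulationParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = params.n_patients
    width = max(3, len(str(n)))
    patients = [f"P{i + 1:0{width}d}" for i in range(n)]
    latent = rng.normal(0.0, params.latent_sd, n)

    all_cells, all_fields = [], []
    for pid, lat in zip(patients, latent):
        for f in range(params.fields_per_patient):
            cells, summary = generate_field(
                params, lat, rng, patient_id=pid, field_id=f"F{f + 1}"
            )
            all_cells.append(cells)
            all_fields.append(summary)
    cells = pd.concat(all_cells, ignore_index=True)
    fields = io_tables.validate_fields(pd.DataFrame(all_fields))

    expression, truth_genes = _simulate_expression(params, patients, latent, rng)
    spatial_cov = _spatial_covariates(cells, fields, patients)
    clinical, truth_patients = _simulate_clinical(
        params, patients, latent, spatial_cov, rng)

    truth_scalars = {
        "beta_os_density_high": params.beta_os_density_high,
        "beta_pfs_distance_high": params.beta_pfs_distance_high,
        "beta_ajcc": params.beta_ajcc,
        "hr_pfs_dist_high_vs_low": float(np.exp(params.beta_pfs_distance_high)),
        "hr_os_density_high_vs_low": float(np.exp(params.beta_os_density_high)),
        "treg_offset_um": params.treg_offset_um,
        "density_loading": params.density_loading,
        "t_cell_intensity": params.t_cell_intensity,
        "tumor_intensity": params.tumor_intensity,
        "gene_corr": params.gene_corr,
    }
    return Cohort(
        cells=cells, fields=fields, expression=io_tables.validate_expression(expression),
        clinical=io_tables.validate_clinical(clinical),
        truth_patients=truth_patients, truth_genes=truth_genes,
        truth_scalars=truth_scalars, params=params, seed=seed,
    )


def params_from_dict(d: dict) -> SimulationParams:
    """Build SimulationParams from a (YAML-loaded) dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
    return SimulationParams(**d)
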