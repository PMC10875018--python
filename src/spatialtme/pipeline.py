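"""End-to-end pipeline: gate -> quantify -> spatial -> associate -> survive.

Driven by a validated configuration (YAML-loadable dict; unknown keys are
rejected).  Stages run in order, any failure aborts with a located error,
and every output file is listed in a ``manifest.json`` with its SHA-256
content hash.  The effective configuration is echoed into the output
directory, so identical (inputs, config) reruns produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as io_tables
from .association import builtin_panels, correlate_panel, load_panel
from .phenotyping import DEFAULT_GRB_CUTOFF, gate_cohort
from .quantification import build_metric_table, density_wide
from .spatial import (
    DEFAULT_DISTANCE_PAIRS,
    build_distance_table,
    distance_wide,
    metric_correlation_matrix,
    overall_nearest_radius,
)
from .survival import run_survival_analysis

log = logging.getLogger("spatialtme")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


_DEFAULT_SURVIVAL_METRICS = [
    "density_Treg_stroma",
    "density_CD8T_epithelium",
    "dist_Treg_Th",
    "dist_Treg_CD8T",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see module docstring)."""

    cells: str
    fields: str
    expression: str | None = None
    clinical: str | None = None
    grb_cutoff: float = DEFAULT_GRB_CUTOFF
    tumor_excludes_cd3: bool = True
    t_excludes_ck: bool = True
    metric_correlation_method: str = "spearman"
    gene_correlation_method: str = "pearson"
    flip_distance_sign: bool = True
    panels: list[str] = field(default_factory=lambda: list(builtin_panels()))
    distance_pairs: list[list[str]] | None = None
    survival_endpoints: list[str] = field(default_factory=lambda: ["os", "pfs"])
    survival_metrics: list[str] = field(
        default_factory=lambda: list(_DEFAULT_SURVIVAL_METRICS)
    )
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in self.__dict__.items()
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig | dict, outdir: str | Path) -> dict:
    """Execute all stages and write result tables plus a hash manifest.

    Returns a dict with the manifest and the in-memory stage results.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # validate up front: a requested stage with a missing input is a
    # config error before any computation
    for name in ("cells", "fields"):
        if not Path(getattr(config, name)).exists():
            raise PipelineError("config", f"input {name!r} not found: {getattr(config, name)}")
    want_survival = bool(config.survival_metrics and config.survival_endpoints)
    if want_survival and (config.clinical is None or not Path(config.clinical).exists()):
        raise PipelineError("config", "survival requested but clinical table missing")
    want_assoc = bool(config.panels)
    if want_assoc and (config.expression is None or not Path(config.expression).exists()):
        raise PipelineError("config", "panel correlation requested but expression matrix missing")

    outputs: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = outdir / name
        _write_tsv(df, path, index=index)
        outputs.append(path)

    t0 = time.perf_counter()

    def _stage(stage, fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, str(err)) from err
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - start)
        return result

    cells = _stage("read", io_tables.read_cell_table, config.cells)
    fields = _stage("read", io_tables.read_field_summary, config.fields)

    gated = _stage(
        "gate", gate_cohort, cells,
        grb_cutoff=config.grb_cutoff,
        tumor_excludes_cd3=config.tumor_excludes_cd3,
        t_excludes_ck=config.t_excludes_ck,
    )

    density, fraction = _stage(
        "quantify", build_metric_table, gated, fields, grb_cutoff=config.grb_cutoff
    )
    emit("metrics_density.tsv", density)
    emit("metrics_fraction.tsv", fraction)

    pairs = (
        tuple(tuple(p) for p in config.distance_pairs)
        if config.distance_pairs is not None
        else DEFAULT_DISTANCE_PAIRS
    )
    distance = _stage("spatial", build_distance_table, gated, pairs)
    emit("metrics_distance.tsv", distance)

    dens_wide = density_wide(density)
    dist_wide = distance_wide(distance)
    metric_wide = dens_wide.join(dist_wide, how="outer")
    emit("metrics_wide.tsv", metric_wide, index=True)

    radius = overall_nearest_radius(distance)
    corr_dens = metric_correlation_matrix(dens_wide, config.metric_correlation_method)
    corr_dist = metric_correlation_matrix(dist_wide, config.metric_correlation_method)
    emit(f"metric_correlation_density_{config.metric_correlation_method}.tsv",
         corr_dens, index=True)
    emit(f"metric_correlation_distance_{config.metric_correlation_method}.tsv",
         corr_dist, index=True)

    panel_results = {}
    if want_assoc:
        expression = _stage("read", io_tables.read_expression_matrix, config.expression)
        for panel_name in config.panels:
            panel = load_panel(panel_name)
            for kind, wide in (("density", dens_wide), ("distance", dist_wide)):
                table = _stage(
                    "associate", correlate_panel, wide, expression, panel,
                    metric_kind=kind, method=config.gene_correlation_method,
                    flip_distance_sign=config.flip_distance_sign,
                )
                emit(f"correlation_{panel.name}_{kind}.tsv", table)
                panel_results[(panel.name, kind)] = table

    survival_results = {}
    if want_survival:
        clinical = _stage("read", io_tables.read_clinical_table, config.clinical)
        metrics = [m for m in config.survival_metrics if m in metric_wide.columns]
        missing = sorted(set(config.survival_metrics) - set(metrics))
        if missing:
            log.warning("survival metrics not available, skipped: %s", missing)
        for endpoint in config.survival_endpoints:
            res = _stage(
                "survive", run_survival_analysis, metric_wide, clinical,
                metrics, endpoint=endpoint,
            )
            survival_results[endpoint] = res
            emit(f"survival_cox_univariate_{endpoint}.tsv", res["univariate"])
            if res["multivariate"] is not None:
                emit(f"survival_cox_multivariate_{endpoint}.tsv",
                     res["multivariate"].summary)
            logrank_rows = []
            for metric, km in res["km"].items():
                logrank_rows.append({
                    "metric": metric, "cutoff": km["cutoff"],
                    "n_high": km["n_high"], "n_low": km["n_low"],
                    "logrank_chi2": km["logrank_chi2"],
                    "logrank_p": km["logrank_p"],
                })
                curves = pd.concat([
                    km["km_high"].assign(group="high"),
                    km["km_low"].assign(group="low"),
                ], ignore_index=True)
                emit(f"survival_km_{metric}_{endpoint}.tsv", curves)
            emit(f"survival_logrank_{endpoint}.tsv", pd.DataFrame(logrank_rows))

    summary = {
        "n_patients": int(fields["patient_id"].nunique()),
        "n_fields": int(len(fields)),
        "n_cells": int(len(cells)),
        "overall_nearest_radius_um": None if pd.isna(radius) else float(radius),
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    outputs.append(summary_path)

    config_path = outdir / "config.yaml"
    import yaml

    config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    outputs.append(config_path)

    manifest = {
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    log.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return {
        "manifest": manifest,
        "metric_wide": metric_wide,
        "density": density,
        "fraction": fraction,
        "distance": distance,
        "overall_nearest_radius_um": radius,
        "panel_correlations": panel_results,
        "survival": survival_results,
        "outdir": outdir,
    }
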