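"""Correlation of spatial metrics with immune gene-expression panels.

Three panels ship as editable plain-text symbol lists: the 20-gene
Immunologic Constant of Rejection (ICR) signature (Th1 signaling,
chemoattraction, cytotoxicity, immune regulation), a chemokine-signaling
panel and a cell-cell-interaction panel.  Gene-level correlations are
Pearson by default (Spearman available), computed over patients present in
both the metric table and the expression matrix, with pairwise-complete
handling of missing values.

Sign convention for distance metrics: distances are negated before
correlating, so a *positive* coefficient always reads "higher expression
goes with shorter distance" — the same direction as "higher expression
goes with higher density".  The flip is recorded in the output and can be
disabled, in which case the coefficient is exactly the negative of the
flipped one.

No multiple-testing correction is applied here; raw r and n are emitted.
A Benjamini-Hochberg utility is provided for downstream use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenePanel",
    "load_panel",
    "builtin_panels",
    "correlate",
    "correlate_panel",
    "benjamini_hochberg",
]

#: mapping from loose aliases seen in signature listings to HGNC symbols
SYMBOL_ALIASES = {"PRF": "PRF1", "CD8A/B": ("CD8A", "CD8B")}

BUILTIN_PANEL_FILES = {
    "icr20": "icr20.txt",
    "kegg_chemokine": "kegg_chemokine.txt",
    "kegg_cell_cell_interaction": "kegg_cell_cell_interaction.txt",
}


@dataclass(frozen=True)
class GenePanel:
    name: str
    symbols: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"panel {self.name!r} has duplicate symbols")


def _parse_symbols(text: str) -> tuple[str, ...]:
    symbols: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias = SYMBOL_ALIASES.get(line, line)
        if isinstance(alias, tuple):
            symbols.extend(alias)
        else:
            symbols.append(alias)
    return tuple(symbols)


def load_panel(source: str | Path, name: str | None = None) -> GenePanel:
    """Load a gene panel from a built-in name or a plain-text symbol list
    (one symbol per line, ``#`` comments)."""
    key = str(source)
    if key in BUILTIN_PANEL_FILES:
        text = (resources.files("spatialtme.panels") / BUILTIN_PANEL_FILES[key]).read_text()
        return GenePanel(key, _parse_symbols(text))
    path = Path(source)
    return GenePanel(name or path.stem, _parse_symbols(path.read_text()))


def builtin_panels() -> dict[str, GenePanel]:
    return {name: load_panel(name) for name in BUILTIN_PANEL_FILES}


def correlate(x, y, method: str = "pearson") -> tuple[float, int]:
    """Correlation between two patient-aligned vectors.

    Missing pairs are dropped pairwise; returns ``(r, n)`` where n is the
    number of complete pairs.  r is NaN when n < 3 or either vector has
    zero variance over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        return float("nan"), n
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), n
    if method == "pearson":
        r = stats.pearsonr(xs, ys).statistic
    elif method == "spearman":
        r = stats.spearmanr(xs, ys).statistic
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), n


def correlate_panel(
    metric_wide: pd.DataFrame,
    expression: pd.DataFrame,
    panel: GenePanel,
    metric_kind: str = "density",
    method: str = "pearson",
    flip_distance_sign: bool = True,
) -> pd.DataFrame:
    """Gene x metric correlation table for one panel.

    ``metric_wide`` is patient x metric (e.g. from
    :func:`spatialtme.quantification.density_wide`); ``expression`` is the
    gene x patient matrix.  For ``metric_kind="distance"`` the metrics are
    negated before correlating (when ``flip_distance_sign``), so r > 0
    means shorter distance at higher expression.  Panel genes absent from
    the matrix are emitted as all-missing rows.

    Returns a long frame ``gene, metric, r, n, distance_sign_flipped``.
    """
    if metric_kind not in ("density", "distance"):
        raise ValueError(f"metric_kind must be 'density' or 'distance', got {metric_kind!r}")
    flipped = metric_kind == "distance" and flip_distance_sign
    shared = [p for p in metric_wide.index.astype(str) if p in expression.columns]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 overlapping patients between metrics and expression, got {len(shared)}"
        )
    metrics = metric_wide.loc[shared].astype(float)
    if flipped:
        metrics = -metrics

    rows = []
    for gene in panel.symbols:
        if gene not in expression.index:
            for metric in metrics.columns:
                rows.append((gene, metric, np.nan, 0, flipped))
            continue
        g = expression.loc[gene, shared].to_numpy(dtype=float)
        for metric in metrics.columns:
            r, n = correlate(metrics[metric].to_numpy(), g, method=method)
            rows.append((gene, metric, r, n, flipped))
    return pd.DataFrame(rows, columns=["gene", "metric", "r", "n", "distance_sign_flipped"])


def benjamini_hochberg(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg adjusted p-values (off by default everywhere)."""
    p = np.asarray(pvalues, dtype=float)
    keep = np.isfinite(p)
    adjusted = np.full_like(p, np.nan)
    if keep.any():
        adjusted[keep] = multipletests(p[keep], alpha=alpha, method="fdr_bh")[1]
    return adjusted
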