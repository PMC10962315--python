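"""Post-gating summaries: cross-panel consistency ratios and marker heatmaps.

The two PBMC panels share CD45 and an NK-cell definition, so the
lymphocyte:CD45 and NK:CD45 fractions computed independently from each panel
act as an internal consistency control; large discrepancies point at staining
or gating problems rather than biology.

The population-by-marker matrix is the numeric content of a clustered
expression heatmap: mean arcsinh-transformed intensity per canonical
population and marker, min-max scaled per marker, with average-linkage
Euclidean hierarchical clustering of rows and columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .fcs_io import EventMatrix
from .panel import PanelConfig

__all__ = [
    "CrossPanelRatios",
    "PopulationMarkerMatrix",
    "cross_panel_ratios",
    "population_marker_matrix",
]


@dataclass
class CrossPanelRatios:
    """Lymphocyte:CD45 and NK:CD45 fractions per panel, with discrepancies."""

    sample_id: str
    lymphocyte_ratio: dict[str, float]      # panel id -> fraction in [0, 1]
    nk_ratio: dict[str, float]
    lymphocyte_discrepancy: float
    nk_discrepancy: float
    concordant: bool


def _fraction(table: pd.DataFrame, population: str) -> float:
    row = table.loc[table["population"] == population]
    if row.empty:
        raise ValueError(f"population {population!r} not in table")
    return float(row["pct_of_cd45"].iloc[0]) / 100.0


def cross_panel_ratios(
    tb_table: pd.DataFrame,
    mnd_table: pd.DataFrame,
    lymphocyte_gate: tuple[str, str] = ("Lymphocytes", "Lymphocytes"),
    nk_gate: tuple[str, str] = ("NK cells", "NK cells"),
    tolerance: float = 0.05,
) -> CrossPanelRatios:
    """Agreement between the two PBMC panels on shared population fractions.

    Both tables must come from the same sample.  Ratios are fractions of the
    CD45+ root; the sample is flagged concordant when both absolute
    differences are within ``tolerance``.
    """
    tb_sample = tb_table["sample_id"].iloc[0] if len(tb_table) else "?"
    cd45_counts = {
        "tb": tb_table.loc[tb_table["parent"] == "root", "count"].sum(),
        "mnd": mnd_table.loc[mnd_table["parent"] == "root", "count"].sum(),
    }
    for pan, c in cd45_counts.items():
        if c == 0:
            raise ValueError(f"{pan} panel has zero CD45+ events; ratios undefined")

    lymph = {
        "tb": _fraction(tb_table, lymphocyte_gate[0]),
        "mnd": _fraction(mnd_table, lymphocyte_gate[1]),
    }
    nk = {
        "tb": _fraction(tb_table, nk_gate[0]),
        "mnd": _fraction(mnd_table, nk_gate[1]),
    }
    d_l = abs(lymph["tb"] - lymph["mnd"])
    d_n = abs(nk["tb"] - nk["mnd"])
    return CrossPanelRatios(
        sample_id=tb_sample,
        lymphocyte_ratio=lymph,
        nk_ratio=nk,
        lymphocyte_discrepancy=d_l,
        nk_discrepancy=d_n,
        concordant=bool(d_l <= tolerance and d_n <= tolerance),
    )


@dataclass
class PopulationMarkerMatrix:
    """Population x marker mean-intensity matrix with dendrogram orders."""

    mean_intensity: pd.DataFrame      # transformed-space means
    scaled: pd.DataFrame              # min-max per marker column, in [0, 1]
    row_order: list[str]
    column_order: list[str]
    excluded: list[str]               # populations with zero events


def population_marker_matrix(
    events: EventMatrix,
    memberships: pd.DataFrame,
    panel: PanelConfig,
    populations: Optional[Sequence[str]] = None,
    markers: Optional[Sequence[str]] = None,
    transformed: bool = True,
) -> PopulationMarkerMatrix:
    """Mean marker intensity per population, scaled and clustered.

    Intensities are arcsinh-transformed by default (the gating space); the
    scaled view min-max normalizes each marker column to [0, 1] (a constant
    column maps to 1).  Rows and columns are ordered by average-linkage
    Euclidean hierarchical clustering; clustering is deterministic because
    populations are lexicographically pre-sorted (the tie rule) and the
    linkage is seedless.  Populations with zero events are excluded with a
    warning.
    """
    if populations is None:
        populations = list(memberships.columns)
    if markers is None:
        markers = [m for m in panel.markers if m in events.channel_names]
    populations = sorted(populations)

    rows, excluded = [], []
    for pop in populations:
        mask = memberships[pop].to_numpy()
        if mask.sum() == 0:
            excluded.append(pop)
            continue
        sub = events.values[mask][:, [events.index_of(m) for m in markers]]
        if transformed:
            sub = panel.transform(sub)
        rows.append(pd.Series(sub.mean(axis=0), index=markers, name=pop))
    if excluded:
        warnings.warn(f"populations with zero events excluded: {excluded}", stacklevel=2)
    if not rows:
        raise ValueError("no populations with events; nothing to profile")
    mat = pd.DataFrame(rows)

    col_min, col_max = mat.min(axis=0), mat.max(axis=0)
    span = (col_max - col_min).replace(0.0, np.nan)
    scaled = (mat - col_min) / span
    scaled = scaled.fillna(1.0)  # degenerate column (or single row) -> 1

    if mat.shape[0] > 1:
        row_order = [mat.index[i] for i in leaves_list(linkage(scaled.to_numpy(), "average"))]
    else:
        row_order = list(mat.index)
    if mat.shape[1] > 1:
        col_order = [mat.columns[i] for i in leaves_list(linkage(scaled.to_numpy().T, "average"))]
    else:
        col_order = list(mat.columns)
    return PopulationMarkerMatrix(
        mean_intensity=mat, scaled=scaled, row_order=row_order,
        column_order=col_order, excluded=excluded,
    )
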