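"""Staining-quality and panel-compatibility statistics.

Covers the stain index (separation between a marker's positive and negative
peaks), the pairwise signature-compatibility screen (similarity index above a
threshold, default 0.98, flags a pair as unusable together), single- versus
multicolor concordance, and a numeric NxN spillover screen.

Robust spread is measured as 1.4826 x MAD throughout (cytometry noise is
heavy-tailed); the stain index itself uses the plain standard deviation, as
that is how the metric is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fcs_io import EventMatrix
from .spectral import SignatureMatrix, similarity_matrix

__all__ = [
    "StainIndexInput",
    "PanelDesignConfig",
    "stain_index",
    "split_peaks",
    "validate_panel",
    "concordance_stat",
    "nxn_screen",
    "robust_sd",
]

#: Consistency constant making the MAD unbiased for the normal SD.
MAD_SCALE = 1.4826


def robust_sd(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return float(MAD_SCALE * np.median(np.abs(x - np.median(x))))


@dataclass
class StainIndexInput:
    """Fluorescence values of the positive and negative peaks of one marker."""

    positive_values: np.ndarray
    negative_values: np.ndarray

    def __post_init__(self) -> None:
        self.positive_values = np.asarray(self.positive_values, dtype=float)
        self.negative_values = np.asarray(self.negative_values, dtype=float)
        if self.negative_values.size < 2:
            raise ValueError("negative peak needs >=2 values for an SD")
        if not (
            np.isfinite(self.positive_values).all() and np.isfinite(self.negative_values).all()
        ):
            raise ValueError("stain-index inputs must be finite")


@dataclass(frozen=True)
class PanelDesignConfig:
    """Compatibility rule for panel design: maximum tolerated pairwise similarity."""

    max_pairwise_similarity: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_pairwise_similarity <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def stain_index(x: StainIndexInput) -> float:
    """(median(positive) - median(negative)) / (2 * sd(negative)).

    The canonical separation metric for a stained versus unstained peak;
    well-titrated panels typically reach values around 10.
    """
    sd_neg = float(np.std(x.negative_values, ddof=0))
    if sd_neg == 0:
        raise ValueError("negative peak has zero SD; stain index undefined")
    med_pos = float(np.median(x.positive_values))
    med_neg = float(np.median(x.negative_values))
    return (med_pos - med_neg) / (2.0 * sd_neg)


def split_peaks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 1-D marker distribution into (negative, positive) peaks.

    Places the cut at the deepest histogram valley between the two largest
    modes of the arcsinh-compressed values; falls back to the midpoint of the
    range when the distribution is unimodal.  Callers with known memberships
    should pass them explicitly instead.
    """
    values = np.asarray(values, dtype=float)
    z = np.arcsinh(values / 150.0)
    hist, edges = np.histogram(z, bins=128)
    smooth = np.convolve(hist, np.ones(5) / 5.0, mode="same")
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0
    ]
    if len(peaks) >= 2:
        top = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
        lo, hi = top
        valley = lo + int(np.argmin(smooth[lo : hi + 1]))
        cut_z = 0.5 * (edges[valley] + edges[valley + 1])
    else:
        cut_z = 0.5 * (z.min() + z.max())
    cut = float(np.sinh(cut_z) * 150.0)
    neg = values[values < cut]
    pos = values[values >= cut]
    return neg, pos


def validate_panel(
    sigs: SignatureMatrix, cfg: PanelDesignConfig = PanelDesignConfig()
) -> pd.DataFrame:
    """List signature pairs whose similarity exceeds the compatibility threshold.

    An empty report means the panel passes the design rule.
    """
    sim = similarity_matrix(sigs)
    names = list(sim.index)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            s = float(sim.iloc[i, j])
            if s > cfg.max_pairwise_similarity:
                rows.append({"fluorophore_a": names[i], "fluorophore_b": names[j], "similarity": s})
    return pd.DataFrame(rows, columns=["fluorophore_a", "fluorophore_b", "similarity"])


def concordance_stat(
    single_color: EventMatrix, multicolor: EventMatrix, marker: str
) -> dict[str, float]:
    """Compare a marker's staining in a single-color control vs the full cocktail.

    Returns ``shift`` (difference of positive-peak medians, multicolor minus
    single color) and ``spread_ratio`` (ratio of robust SDs of the positive
    peaks).  Values near (0, 1) indicate the marker performs identically in
    the cocktail.
    """
    for m, tag in ((single_color, "single_color"), (multicolor, "multicolor")):
        if marker not in m.channel_names:
            raise ValueError(f"marker {marker!r} absent from {tag} events")
    _, sc_pos = split_peaks(single_color.channel(marker))
    _, mc_pos = split_peaks(multicolor.channel(marker))
    if sc_pos.size == 0 or mc_pos.size == 0:
        raise ValueError(f"no positive peak found for {marker!r}")
    sc_sd = robust_sd(sc_pos)
    shift = float(np.median(mc_pos) - np.median(sc_pos))
    ratio = float(robust_sd(mc_pos) / sc_sd) if sc_sd > 0 else np.inf
    return {"shift": shift, "spread_ratio": ratio}


def nxn_screen(
    unmixed: EventMatrix,
    markers: Optional[Sequence[str]] = None,
    flag_threshold: float = 1.0,
) -> pd.DataFrame:
    """Numeric surrogate for the visual NxN unmixing screen.

    For each ordered marker pair (i, j), splits events on marker i into
    positive/negative peaks and scores how much marker j's level differs
    between them, in robust-SD units of the i-negative events:

        score(i, j) = (med(j | i+) - med(j | i-)) / robust_sd(j | i-)

    Independent, well-unmixed channels score near 0; residual spillover from
    i into j pushes score(i, j) up without affecting score(j, i).  Pairs with
    |score| above ``flag_threshold`` are flagged; pairs where marker i has no
    positive or no negative events are marked not evaluable.
    """
    if markers is None:
        markers = unmixed.channels_of_kind("marker")
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("need >=2 markers for an NxN screen")
    rows = []
    masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for m in markers:
        vals = unmixed.channel(m)
        neg, pos = split_peaks(vals)
        if neg.size == 0 or pos.size == 0:
            masks[m] = (np.zeros(unmixed.n_events, bool), np.zeros(unmixed.n_events, bool))
        else:
            cut = 0.5 * (neg.max() + pos.min())
            masks[m] = (vals < cut, vals >= cut)
    for mi in markers:
        neg_mask, pos_mask = masks[mi]
        evaluable = neg_mask.sum() >= 2 and pos_mask.sum() >= 1
        for mj in markers:
            if mi == mj:
                continue
            if not evaluable:
                rows.append(
                    {"source": mi, "target": mj, "score": np.nan, "flagged": False,
                     "evaluable": False}
                )
                continue
            vj = unmixed.channel(mj)
            sd = robust_sd(vj[neg_mask])
            if sd == 0:
                sd = float(np.std(vj[neg_mask])) or 1.0
            score = float((np.median(vj[pos_mask]) - np.median(vj[neg_mask])) / sd)
            rows.append(
                {"source": mi, "target": mj, "score": score,
                 "flagged": bool(abs(score) > flag_threshold), "evaluable": True}
            )
    return pd.DataFrame(rows, columns=["source", "target", "score", "flagged", "evaluable"])
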