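"""Declarative hierarchical gating of marker-space events.

A gating tree is a named hierarchy of gates rooted at "all events" (after
pre-gating).  Each node combines a boolean expression over marker thresholds,
scatter rectangles/polygons, and AND/OR/NOT connectives with its parent's
membership; canonical populations are the biologically named endpoints, while
intermediate steps exist only to structure the hierarchy.

Threshold semantics: gating operates on arcsinh-transformed unmixed
intensities (cofactor per panel, default 6000).  Relations are ``+`` / ``-``
(at the marker's positive cutoff), ``hi`` (above the high cutoff), ``lo``
(positive but below high), ``int`` (inside the intermediate band), and
``all`` (no constraint).  Intervals are half-open with ties assigned to the
positive side, so an event exactly on a cutoff is positive.

Compact expressions are written as whitespace-separated terms that AND
together, e.g. ``"CD25+ CD127-"``; structured dict forms provide OR/NOT and
2-D geometry gates.  Events in overlapping canonical gates are assigned to
the deepest node, ties broken by configuration order (more specific
populations are listed first in the shipped panels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath

from .fcs_io import EventMatrix
from .panel import PanelConfig

__all__ = [
    "GateExpression",
    "Threshold",
    "RectGate",
    "PolygonGate",
    "And",
    "Or",
    "Not",
    "AllEvents",
    "GateNode",
    "GatingTree",
    "GatingResult",
    "parse_expression",
    "parse_gating_config",
    "apply_pregates",
    "run_gating_tree",
    "apply_overlays",
    "detect_rare_populations",
]

RELATIONS = ("+", "-", "hi", "lo", "int", "all")


class GateExpression:
    """Base class for gate expressions; subclasses implement ``evaluate``."""

    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        raise NotImplementedError

    def referenced_channels(self) -> set[str]:
        raise NotImplementedError


@dataclass(frozen=True)
class Threshold(GateExpression):
    marker: str
    relation: str
    cutoffs: Optional[tuple[float, ...]] = None  # explicit transformed cutoffs

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}; expected one of {RELATIONS}")
        if self.relation == "int" and self.cutoffs is not None:
            lo, hi = self.cutoffs
            if not lo < hi:
                raise ValueError(f"'int' cutoffs need low < high, got {self.cutoffs}")

    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        z = panel.transform(events.channel(self.marker))
        cut = panel.cutoffs_for(self.marker)
        if self.relation == "all":
            return np.ones(events.n_events, dtype=bool)
        if self.relation == "+":
            c = self.cutoffs[0] if self.cutoffs else cut.positive
            return z >= c
        if self.relation == "-":
            c = self.cutoffs[0] if self.cutoffs else cut.positive
            return z < c
        if self.relation == "hi":
            c = self.cutoffs[0] if self.cutoffs else cut.hi
            return z >= c
        if self.relation == "lo":
            lo = self.cutoffs[0] if self.cutoffs else cut.positive
            hi = self.cutoffs[1] if self.cutoffs and len(self.cutoffs) > 1 else cut.hi
            return (z >= lo) & (z < hi)
        lo = self.cutoffs[0] if self.cutoffs else cut.int_low
        hi = self.cutoffs[1] if self.cutoffs else cut.int_high
        return (z >= lo) & (z < hi)

    def referenced_channels(self) -> set[str]:
        return {self.marker}


@dataclass(frozen=True)
class RectGate(GateExpression):
    """Axis-aligned rectangle over two channels, in raw units (scatter gates)."""

    x_channel: str
    x_min: float
    x_max: float
    y_channel: str
    y_min: float
    y_max: float

    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        x = events.channel(self.x_channel)
        y = events.channel(self.y_channel)
        return (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)

    def referenced_channels(self) -> set[str]:
        return {self.x_channel, self.y_channel}


@dataclass(frozen=True)
class PolygonGate(GateExpression):
    """Arbitrary polygon over two channels, in raw units."""

    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]

    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        pts = np.column_stack([events.channel(self.x_channel), events.channel(self.y_channel)])
        return MplPath(np.asarray(self.vertices)).contains_points(pts)

    def referenced_channels(self) -> set[str]:
        return {self.x_channel, self.y_channel}


@dataclass(frozen=True)
class And(GateExpression):
    terms: tuple[GateExpression, ...]

    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        out = np.ones(events.n_events, dtype=bool)
        for t in self.terms:
            out &= t.evaluate(events, panel)
        return out

    def referenced_channels(self) -> set[str]:
        return set().union(*(t.referenced_channels() for t in self.terms))


@dataclass(frozen=True)
class Or(GateExpression):
    terms: tuple[GateExpression, ...]

    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        out = np.zeros(events.n_events, dtype=bool)
        for t in self.terms:
            out |= t.evaluate(events, panel)
        return out

    def referenced_channels(self) -> set[str]:
        return set().union(*(t.referenced_channels() for t in self.terms))


@dataclass(frozen=True)
class Not(GateExpression):
    term: GateExpression

    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        return ~self.term.evaluate(events, panel)

    def referenced_channels(self) -> set[str]:
        return self.term.referenced_channels()


@dataclass(frozen=True)
class AllEvents(GateExpression):
    def evaluate(self, events: EventMatrix, panel: PanelConfig) -> np.ndarray:
        return np.ones(events.n_events, dtype=bool)

    def referenced_channels(self) -> set[str]:
        return set()


# ---------------------------------------------------------------------------
# Expression parsing
# ---------------------------------------------------------------------------

_SUFFIXES = ("int", "all", "hi", "lo", "+", "-")


def _parse_term(token: str) -> Threshold:
    for suffix in _SUFFIXES:
        if token.endswith(suffix) and len(token) > len(suffix):
            return Threshold(marker=token[: -len(suffix)], relation=suffix)
    raise ValueError(
        f"cannot parse gate term {token!r}: expected <marker><relation> with "
        f"relation in {_SUFFIXES}"
    )


def parse_expression(spec: Union[str, dict, list]) -> GateExpression:
    """Parse a YAML/string gate expression.

    Strings are whitespace-separated threshold terms ANDed together
    (``"CD25+ CD127-"``).  Dicts support ``all_of`` / ``any_of`` / ``not`` /
    ``rect`` / ``polygon`` / ``term`` forms; lists AND their elements.
    """
    if isinstance(spec, str):
        spec = spec.strip()
        if spec in ("", "*", "true"):
            return AllEvents()
        terms = tuple(_parse_term(tok) for tok in spec.split())
        return terms[0] if len(terms) == 1 else And(terms)
    if isinstance(spec, list):
        return And(tuple(parse_expression(s) for s in spec))
    if isinstance(spec, dict):
        if "all_of" in spec:
            return And(tuple(parse_expression(s) for s in spec["all_of"]))
        if "any_of" in spec:
            return Or(tuple(parse_expression(s) for s in spec["any_of"]))
        if "not" in spec:
            return Not(parse_expression(spec["not"]))
        if "rect" in spec:
            r = spec["rect"]
            return RectGate(
                x_channel=r["x_channel"], x_min=float(r["x_min"]), x_max=float(r["x_max"]),
                y_channel=r["y_channel"], y_min=float(r["y_min"]), y_max=float(r["y_max"]),
            )
        if "polygon" in spec:
            p = spec["polygon"]
            verts = tuple((float(x), float(y)) for x, y in p["vertices"])
            return PolygonGate(x_channel=p["x_channel"], y_channel=p["y_channel"], vertices=verts)
        if "term" in spec:
            t = spec["term"]
            cut = t.get("cutoffs")
            cutoffs = tuple(float(c) for c in cut) if cut is not None else None
            return Threshold(marker=t["marker"], relation=t["relation"], cutoffs=cutoffs)
    raise ValueError(f"unrecognised gate expression: {spec!r}")


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

ROOT = "root"


@dataclass
class GateNode:
    name: str
    parent: str
    expression: GateExpression
    canonical: bool = True


@dataclass
class GatingTree:
    """Validated gate hierarchy; node order is the configuration order."""

    nodes: list[GateNode]

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gate names: {dupes}")
        if ROOT in names:
            raise ValueError(f"{ROOT!r} is reserved for the implicit root")
        known = set(names) | {ROOT}
        for n in self.nodes:
            if n.parent not in known:
                raise ValueError(f"gate {n.name!r} references unknown parent {n.parent!r}")
        # cycle check: walk each node to root
        by_name = {n.name: n for n in self.nodes}
        for n in self.nodes:
            seen = {n.name}
            cur = n.parent
            while cur != ROOT:
                if cur in seen:
                    raise ValueError(f"cyclic parent chain at gate {n.name!r}")
                seen.add(cur)
                cur = by_name[cur].parent

    def __iter__(self):
        return iter(self.nodes)

    def node(self, name: str) -> GateNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def depth(self, name: str) -> int:
        d, cur = 0, name
        by_name = {n.name: n for n in self.nodes}
        while cur != ROOT:
            cur = by_name[cur].parent
            d += 1
        return d

    def canonical_populations(self) -> list[str]:
        return [n.name for n in self.nodes if n.canonical]

    def children(self, name: str) -> list[GateNode]:
        return [n for n in self.nodes if n.parent == name]

    def path(self, name: str) -> list[GateNode]:
        """Nodes from the top of the tree down to ``name`` (inclusive)."""
        by_name = {n.name: n for n in self.nodes}
        chain = []
        cur = name
        while cur != ROOT:
            chain.append(by_name[cur])
            cur = by_name[cur].parent
        return chain[::-1]

    def referenced_channels(self) -> set[str]:
        return set().union(*(n.expression.referenced_channels() for n in self.nodes))


def parse_gating_config(
    source: Union[str, Path, dict], markers: Optional[Sequence[str]] = None,
    scatter_channels: Sequence[str] = ("FSC-A", "FSC-H", "SSC-A"),
) -> GatingTree:
    """Build a :class:`GatingTree` from a YAML file or an in-memory dict.

    When ``markers`` is given, every threshold channel referenced by any gate
    must appear in it (scatter channels are validated separately); schema
    errors cite the offending gate.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = source
    gates = cfg.get("gates")
    if not gates:
        raise ValueError("gating config has no 'gates' list")
    nodes = []
    for entry in gates:
        try:
            expr = parse_expression(entry.get("expr", entry.get("expression", "all")))
        except ValueError as exc:
            raise ValueError(f"gate {entry.get('name')!r}: {exc}") from exc
        nodes.append(
            GateNode(
                name=entry["name"],
                parent=entry.get("parent", ROOT),
                expression=expr,
                canonical=bool(entry.get("canonical", True)),
            )
        )
    tree = GatingTree(nodes)
    if markers is not None:
        allowed = set(markers) | set(scatter_channels)
        for n in tree:
            unknown = n.expression.referenced_channels() - allowed
            if unknown:
                raise ValueError(
                    f"gate {n.name!r} references channels absent from panel: {sorted(unknown)}"
                )
    return tree


# ---------------------------------------------------------------------------
# Pre-gating
# ---------------------------------------------------------------------------


def apply_pregates(events: EventMatrix, panel: PanelConfig) -> EventMatrix:
    """Standard clean-up chain: singlets, non-RBC/debris, live, CD45+.

    * singlets: FSC-A/FSC-H ratio within a band around the modal ratio
      (doublets carry roughly doubled area at singlet height);
    * non-RBC/debris: scatter minima on FSC-A and SSC-A (no RBC marker exists
      in the panels, so a low-scatter exclusion stands in for the published
      gate);
    * live: viability-dye negative;
    * CD45+: leukocytes only.
    """
    p = panel.pregate_params
    required = ["FSC-A", "FSC-H", "SSC-A", panel.viability_marker, "CD45"]
    missing = [c for c in required if c not in events.channel_names]
    if missing:
        raise ValueError(f"pre-gating requires channels {missing} (absent)")

    fsc_a = events.channel("FSC-A")
    fsc_h = events.channel("FSC-H")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc_h > 0, fsc_a / fsc_h, np.inf)
    band = float(p.get("singlet_band", 0.15))
    finite = ratio[np.isfinite(ratio)]
    modal = float(np.median(finite)) if finite.size else 1.0
    singlet = np.abs(ratio - modal) <= band * modal

    non_rbc = (fsc_a >= float(p.get("scatter_min_fsc", 25000))) & (
        events.channel("SSC-A") >= float(p.get("scatter_min_ssc", 1000))
    )

    via_z = panel.transform(events.channel(panel.viability_marker))
    live = via_z < panel.cutoffs_for(panel.viability_marker).positive

    cd45_z = panel.transform(events.channel("CD45"))
    cd45_pos = cd45_z >= panel.cutoffs_for("CD45").positive

    return events.select_events(singlet & non_rbc & live & cd45_pos)


# ---------------------------------------------------------------------------
# Tree evaluation
# ---------------------------------------------------------------------------


@dataclass
class GatingResult:
    """Per-event memberships, canonical assignments, and population table."""

    memberships: pd.DataFrame          # bool, events x gate nodes
    assignments: np.ndarray            # deepest canonical population per event ("" = none)
    table: pd.DataFrame                # population, parent, canonical, count, percents
    sample_id: str


def run_gating_tree(
    tree: GatingTree, events: EventMatrix, panel: PanelConfig
) -> GatingResult:
    """Evaluate a gating tree on (already unmixed, untransformed) events.

    Each node's membership is the intersection of its expression with its
    parent's membership, so containment holds by construction.  Frequencies
    are reported as percent-of-parent and percent of the tree root (the CD45+
    live singlet population when pre-gating was applied).
    """
    n = events.n_events
    memberships: dict[str, np.ndarray] = {ROOT: np.ones(n, dtype=bool)}
    for node in tree:
        parent = memberships[node.parent]
        own = node.expression.evaluate(events, panel) if n else np.zeros(0, dtype=bool)
        mask = parent & own
        assert not np.any(mask & ~parent), "containment violated"
        memberships[node.name] = mask

    # deepest canonical node per event; ties broken by configuration order
    assignments = np.full(n, "", dtype=object)
    best_depth = np.full(n, -1, dtype=int)
    for node in tree:
        if not node.canonical:
            continue
        d = tree.depth(node.name)
        mask = memberships[node.name] & (d > best_depth)
        assignments[mask] = node.name
        best_depth[mask] = d

    root_count = n
    rows = []
    for node in tree:
        count = int(memberships[node.name].sum())
        parent_count = int(memberships[node.parent].sum())
        rows.append(
            {
                "population": node.name,
                "parent": node.parent,
                "canonical": node.canonical,
                "count": count,
                "pct_of_parent": 100.0 * count / parent_count if parent_count else 0.0,
                "pct_of_cd45": 100.0 * count / root_count if root_count else 0.0,
                "sample_id": events.sample_id,
            }
        )
    table = pd.DataFrame(rows)
    member_df = pd.DataFrame({k: v for k, v in memberships.items() if k != ROOT})
    return GatingResult(
        memberships=member_df, assignments=assignments, table=table,
        sample_id=events.sample_id,
    )


def apply_overlays(
    result: GatingResult, events: EventMatrix, panel: PanelConfig,
    overlays: Optional[list[dict]] = None,
) -> pd.DataFrame:
    """Evaluate overlay gates (activation/checkpoint markers) on base populations.

    Overlays attach to any gated population rather than extending the tree;
    each row reports the overlay-positive count and percent of its base.
    """
    overlays = overlays if overlays is not None else panel.overlays
    rows = []
    for ov in overlays:
        base = ov["base"]
        if base not in result.memberships.columns:
            raise ValueError(f"overlay {ov['name']!r}: base population {base!r} not gated")
        base_mask = result.memberships[base].to_numpy()
        expr = parse_expression(ov.get("expr", ov.get("expression")))
        mask = base_mask & expr.evaluate(events, panel)
        rows.append(
            {
                "overlay": ov["name"],
                "base": base,
                "count": int(mask.sum()),
                "pct_of_base": 100.0 * mask.sum() / base_mask.sum() if base_mask.any() else 0.0,
                "sample_id": events.sample_id,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rare populations
# ---------------------------------------------------------------------------

_RARE_DEFS = {
    "DP T cells (CD4hi/CD8lo)": "CD45+ CD3+ CD4hi CD8lo",
    "DP T cells (CD4lo/CD8hi)": "CD45+ CD3+ CD4lo CD8hi",
    "Basophils": "CD45int CD123hi HLA-DR-",
    "ILCs": "CD45+ CD3- CD8- CD4- TCRgd- CD19- CD20- HLA-DR- CD127+",
}


def detect_rare_populations(events: EventMatrix, panel: PanelConfig) -> pd.DataFrame:
    """Screen pre-gated events for rare populations the panels can resolve.

    Reports double-positive T cells (CD4hi/CD8lo and CD4lo/CD8hi), basophils
    (CD45int/CD123hi/HLA-DR-), and innate lymphoid cells, with frequencies as
    percent of all (CD45-gated) events.  Populations whose required markers
    are absent from the panel are skipped unless none can be evaluated, which
    is an error.
    """
    available = set(events.channel_names)
    rows = []
    evaluable = 0
    for name, expr_str in _RARE_DEFS.items():
        expr = parse_expression(expr_str)
        needed = expr.referenced_channels()
        if not needed <= available:
            continue
        evaluable += 1
        mask = expr.evaluate(events, panel)
        rows.append(
            {
                "population": name,
                "count": int(mask.sum()),
                "pct_of_cd45": 100.0 * mask.sum() / events.n_events if events.n_events else 0.0,
                "sample_id": events.sample_id,
            }
        )
    if evaluable == 0:
        raise ValueError(
            "none of the rare-population definitions are evaluable on this panel "
            f"(channels available: {sorted(available)})"
        )
    return pd.DataFrame(rows)
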