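"""Panel configuration: fluorophore/marker assignments, spectra, cutoffs, gating.

A panel bundles everything needed to take one sample from detector space to
population frequencies: the fluorophore-to-marker map, the reference spectral
signature library, the compensation matrix, the arcsinh display/gating
transform, per-marker gate cutoffs, and the declarative gating tree.

Three panels ship with the package (identified as ``tb``, ``mnd``, ``bmc``):
a PBMC T- and B-cell panel (27 fluorophores), a PBMC monocyte/NK/dendritic
panel (25), and a bone-marrow panel (32), each with a 48-detector signature
library.  The shipped signature CSVs are synthetic stand-ins for vendor
reference spectra (see the ``_synthetic`` suffix); the gating trees encode the
published population definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .spectral import CompensationMatrix, SignatureMatrix

__all__ = [
    "MarkerCutoffs",
    "PanelConfig",
    "load_panel",
    "packaged_panels",
]

PACKAGED_PANELS = ("tb", "mnd", "bmc")


@dataclass(frozen=True)
class MarkerCutoffs:
    """Gate cutoffs for one marker, in arcsinh-transformed units.

    ``positive`` separates - from +; ``hi`` separates + from hi (so ``lo``
    means [positive, hi)); ``int`` is the [low, high) band for intermediate
    expression.
    """

    positive: float
    hi: float
    int_low: float
    int_high: float

    def __post_init__(self) -> None:
        if not self.int_low < self.int_high:
            raise ValueError("'int' cutoffs need low < high")


@dataclass
class PanelConfig:
    """One panel's full analysis configuration."""

    panel_id: str
    name: str
    n_detectors: int
    cofactor: float
    fluorophores: list[str]          # marker-conjugated dyes, config order
    markers: list[str]               # same order as fluorophores
    viability_fluorophore: str
    viability_marker: str
    scatter_channels: list[str]
    cutoffs: dict[str, MarkerCutoffs]
    signatures: SignatureMatrix
    compensation: CompensationMatrix
    gating_spec: dict
    pregate_params: dict
    template_baseline: dict[str, str] = field(default_factory=dict)
    default_frequencies: dict[str, float] = field(default_factory=dict)
    extra_templates: list[dict] = field(default_factory=list)
    template_overrides: dict[str, dict[str, str]] = field(default_factory=dict)
    overlays: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.fluorophores) != len(self.markers):
            raise ValueError("fluorophore and marker lists must align")
        if len(set(self.fluorophores)) != len(self.fluorophores):
            raise ValueError("duplicate fluorophore names in panel")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names in panel")

    @property
    def all_fluorophores(self) -> list[str]:
        """Marker dyes plus the viability dye, in signature-library order."""
        return self.fluorophores + [self.viability_fluorophore]

    @property
    def all_markers(self) -> list[str]:
        return self.markers + [self.viability_marker]

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Display/gating transform: arcsinh(raw / cofactor)."""
        return np.arcsinh(np.asarray(raw, dtype=float) / self.cofactor)

    def cutoffs_for(self, marker: str) -> MarkerCutoffs:
        try:
            return self.cutoffs[marker]
        except KeyError:
            return self.cutoffs["default"]


def _build_cutoffs(raw_cfg: dict, cofactor: float) -> dict[str, MarkerCutoffs]:
    def convert(entry: dict, base: Optional[MarkerCutoffs] = None) -> MarkerCutoffs:
        tf = lambda v: float(np.arcsinh(v / cofactor))  # noqa: E731
        pos = tf(entry["positive"]) if "positive" in entry else base.positive
        hi = tf(entry["hi"]) if "hi" in entry else base.hi
        if "int" in entry:
            lo_i, hi_i = (tf(v) for v in entry["int"])
        else:
            lo_i, hi_i = base.int_low, base.int_high
        return MarkerCutoffs(positive=pos, hi=hi, int_low=lo_i, int_high=hi_i)

    default = convert(raw_cfg.get("default", {"positive": 500, "hi": 10000, "int": [200, 2000]}))
    out = {"default": default}
    for marker, entry in (raw_cfg.get("overrides") or {}).items():
        out[marker] = convert(entry, base=default)
    return out


def _panel_dir() -> Path:
    return Path(resources.files("cytospec") / "panels")  # type: ignore[arg-type]


def packaged_panels() -> list[str]:
    """Identifiers of the panels shipped with the package."""
    return list(PACKAGED_PANELS)


def load_panel(panel: str | Path) -> PanelConfig:
    """Load a panel configuration by id (``tb``/``mnd``/``bmc``) or YAML path."""
    if isinstance(panel, str) and panel in PACKAGED_PANELS:
        path = _panel_dir() / f"{panel}.yaml"
    else:
        path = Path(panel)
    if not path.exists():
        raise FileNotFoundError(f"panel config not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    cofactor = float(cfg.get("cofactor", 6000))
    fluors = [entry["fluorophore"] for entry in cfg["fluorophores"]]
    markers = [entry["marker"] for entry in cfg["fluorophores"]]
    via = cfg.get("viability", {"fluorophore": "VRed", "marker": "ViaDyeRed"})

    sig_path = path.parent / cfg["signatures"]
    signatures = SignatureMatrix.from_csv(sig_path)
    lib_names = set(signatures.fluorophores)
    missing = [f for f in fluors + [via["fluorophore"]] if f not in lib_names]
    if missing:
        raise ValueError(f"{path}: fluorophores missing from signature library: {missing}")

    comp_entries = [
        (e["source"], e["target"], float(e["percent"])) for e in (cfg.get("compensation") or [])
    ]
    comp = CompensationMatrix.from_spillovers(markers, comp_entries) if comp_entries else (
        CompensationMatrix.identity(markers)
    )

    return PanelConfig(
        panel_id=cfg.get("panel", path.stem),
        name=cfg.get("name", path.stem),
        n_detectors=int(cfg.get("detectors", 48)),
        cofactor=cofactor,
        fluorophores=fluors,
        markers=markers,
        viability_fluorophore=via["fluorophore"],
        viability_marker=via["marker"],
        scatter_channels=list(cfg.get("scatter_channels", ["FSC-A", "FSC-H", "SSC-A"])),
        cutoffs=_build_cutoffs(cfg.get("cutoffs") or {}, cofactor),
        signatures=signatures,
        compensation=comp,
        gating_spec={"gates": cfg.get("gates", [])},
        pregate_params=dict(cfg.get("pregates") or {}),
        template_baseline=dict(cfg.get("template_baseline") or {}),
        default_frequencies=dict(cfg.get("default_frequencies") or {}),
        extra_templates=list(cfg.get("extra_templates") or []),
        template_overrides=dict(cfg.get("template_overrides") or {}),
        overlays=list(cfg.get("overlays") or []),
    )
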