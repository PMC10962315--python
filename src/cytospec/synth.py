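"""Ground-truth-labeled synthetic spectral-flow data.

Every other module of the package is testable without instrument data because
this module emulates the full measurement chain: population templates (marker
expression levels per cell type) -> per-cell marker abundances (lognormal per
level) -> linear mixing through a spectral signature library into 48-detector
space, plus cellular autofluorescence and heteroscedastic detector noise
(Gaussian with SD = a + b * signal, defaults a=5, b=0.02).  Scatter channels,
doublets, dead cells, and RBC-like debris are generated so pre-gating can be
exercised; per-batch gain/offset shifts emulate the technical variation of
acquisition runs separated by weeks.

Expression-level distributions are lognormal on the raw scale:

====== ============ =====
level  median       sigma
====== ============ =====
neg    50           0.5
int    800          0.5
pos    5000         0.4
hi     20000        0.4
====== ============ =====

chosen so that a pos-vs-neg marker shows a stain index around 10, typical of
a well-titrated panel.  All randomness flows from a single seed; outputs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fcs_io import EventMatrix
from .gating import And, GatingTree, RectGate, Threshold
from .panel import PanelConfig
from .spectral import AUTOFLUORESCENCE, SignatureMatrix, SpectralSignature

__all__ = [
    "LEVELS",
    "PopulationTemplate",
    "BatchEffectSpec",
    "make_signature_set",
    "templates_from_gating",
    "extra_template",
    "simulate_sample",
    "simulate_panel_sample",
    "simulate_batches",
]

#: Lognormal (mu, sigma) of raw fluorescence per expression level.
LEVELS: dict[str, tuple[float, float]] = {
    "neg": (math.log(50.0), 0.5),
    "int": (math.log(800.0), 0.5),
    "pos": (math.log(5000.0), 0.4),
    "hi": (math.log(20000.0), 0.4),
}

#: Raw-scale medians per level, used for symbolic gate-satisfaction checks.
LEVEL_MEDIANS = {name: math.exp(mu) for name, (mu, _) in LEVELS.items()}

#: (FSC-A mean, FSC-A sd, SSC-A mean, SSC-A sd) per scatter profile.
SCATTER_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "lymphocyte": (50_000, 5_000, 15_000, 4_000),
    "monocyte": (90_000, 7_000, 45_000, 7_000),
    "debris": (12_000, 4_000, 3_000, 1_500),
}

#: Autofluorescence abundance distribution (lognormal mu, sigma).
AF_LEVEL = (math.log(300.0), 0.3)

_RELATION_TO_LEVEL = {"+": "pos", "-": "neg", "hi": "hi", "int": "int", "lo": "pos"}


@dataclass
class PopulationTemplate:
    """Generative description of one cell population.

    ``marker_levels`` maps every panel marker to an expression level; markers
    the defining gates do not constrain default to ``neg``.
    """

    name: str
    marker_levels: dict[str, str]
    frequency: float
    scatter: str = "lymphocyte"
    canonical: bool = True

    def __post_init__(self) -> None:
        bad = {lvl for lvl in self.marker_levels.values() if lvl not in LEVELS}
        if bad:
            raise ValueError(f"{self.name}: unknown expression levels {sorted(bad)}")
        if self.scatter not in SCATTER_PROFILES:
            raise ValueError(f"{self.name}: unknown scatter profile {self.scatter!r}")
        if self.frequency < 0:
            raise ValueError(f"{self.name}: negative frequency")


@dataclass
class BatchEffectSpec:
    """Per-batch technical variation: multiplicative gains and additive offsets.

    When explicit per-batch values are not supplied they are drawn per batch
    and channel: gains lognormal around 1 with spread ``gain_sd``, offsets
    normal with scale ``offset_scale`` (raw fluorescence units).  A
    donor-unique population can be injected into one batch to emulate a
    sample-specific cluster.
    """

    gain_sd: float = 0.0
    offset_scale: float = 0.0
    gains: Optional[np.ndarray] = None        # (n_batches, n_markers)
    offsets: Optional[np.ndarray] = None      # (n_batches, n_markers)
    unique_population: Optional[PopulationTemplate] = None
    unique_batch: int = 0
    seed: int = 0

    def realise(self, n_batches: int, n_markers: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        if self.gains is not None:
            gains = np.asarray(self.gains, dtype=float)
        else:
            gains = np.exp(rng.normal(0.0, self.gain_sd, size=(n_batches, n_markers)))
        if self.offsets is not None:
            offsets = np.asarray(self.offsets, dtype=float)
        else:
            offsets = rng.normal(0.0, self.offset_scale, size=(n_batches, n_markers))
        if np.any(gains <= 0):
            raise ValueError("batch gains must be positive")
        return gains, offsets


# ---------------------------------------------------------------------------
# Signature generation
# ---------------------------------------------------------------------------


def make_signature_set(
    n_fluors: int,
    n_detectors: int = 48,
    target_max_similarity: float = 0.98,
    seed: int = 0,
    fluorophore_names: Optional[Sequence[str]] = None,
    include_autofluorescence: bool = True,
    max_tries: int = 200,
) -> SignatureMatrix:
    """Generate emission-like signatures with bounded pairwise similarity.

    Each signature is a smooth Gaussian-shaped peak over the detector array
    (with a small secondary bump for realism); peak positions are spread over
    the detectors and widths shrunk until every pairwise similarity index is
    at or below ``target_max_similarity``.  ``target 0`` with
    ``n_fluors <= n_detectors`` yields single-detector (orthonormal) spectra.
    Deterministic per seed.
    """
    if n_fluors > n_detectors:
        raise ValueError("cannot place more fluorophores than detectors")
    if not 0.0 <= target_max_similarity <= 1.0:
        raise ValueError("target similarity must lie in [0, 1]")
    names = (
        list(fluorophore_names)
        if fluorophore_names is not None
        else [f"F{i:02d}" for i in range(n_fluors)]
    )
    if len(names) != n_fluors:
        raise ValueError("need one fluorophore name per signature")
    rng = np.random.default_rng(seed)
    grid = np.arange(n_detectors, dtype=float)

    if target_max_similarity == 0.0:
        # Disjoint single-detector spectra are the only exactly-orthogonal
        # non-negative construction.
        positions = rng.permutation(n_detectors)[:n_fluors]
        sigs = []
        for name, pos in zip(names, positions):
            prof = np.zeros(n_detectors)
            prof[pos] = 1.0
            sigs.append(SpectralSignature(name, prof))
        af = None
        if include_autofluorescence:
            af = SpectralSignature(AUTOFLUORESCENCE, np.ones(n_detectors))
        return SignatureMatrix(signatures=sigs, autofluorescence=af)

    width = 1.3
    for attempt in range(max_tries):
        base = np.linspace(0.5, n_detectors - 1.5, n_fluors)
        jitter = rng.uniform(-0.3, 0.3, size=n_fluors)
        positions = base + jitter
        profiles = []
        for pos in positions:
            w = width * rng.uniform(0.85, 1.15)
            prof = np.exp(-0.5 * ((grid - pos) / w) ** 2)
            # secondary cross-laser bump, 5% amplitude
            alt = (pos + n_detectors / 2.0) % n_detectors
            prof = prof + 0.05 * np.exp(-0.5 * ((grid - alt) / (2.0 * w)) ** 2)
            profiles.append(prof / np.linalg.norm(prof))
        P = np.stack(profiles)
        gram = P @ P.T
        np.fill_diagonal(gram, 0.0)
        if gram.max() <= target_max_similarity:
            sigs = [SpectralSignature(n, p) for n, p in zip(names, P)]
            af = None
            if include_autofluorescence:
                af_prof = np.exp(-0.5 * ((grid - n_detectors * 0.3) / (n_detectors * 0.35)) ** 2)
                af = SpectralSignature(AUTOFLUORESCENCE, af_prof)
            return SignatureMatrix(signatures=sigs, autofluorescence=af)
        width *= 0.92
        if width < 0.2:
            break
    raise ValueError(
        f"could not reach max pairwise similarity {target_max_similarity} with "
        f"{n_fluors} fluorophores over {n_detectors} detectors"
    )


# ---------------------------------------------------------------------------
# Templates from gating definitions
# ---------------------------------------------------------------------------


def _threshold_terms(expr) -> list[Threshold]:
    if isinstance(expr, Threshold):
        return [expr]
    if isinstance(expr, And):
        out = []
        for t in expr.terms:
            out.extend(_threshold_terms(t))
        return out
    if isinstance(expr, RectGate):
        return []
    from .gating import AllEvents

    if isinstance(expr, AllEvents):
        return []
    raise ValueError(
        f"cannot derive a generative template from expression {expr!r}; "
        "only AND-combined thresholds and scatter rectangles are invertible"
    )


def _path_constraints(tree: GatingTree, name: str) -> tuple[dict[str, str], str]:
    """Marker levels + scatter profile implied by the root path of ``name``."""
    levels: dict[str, str] = {}
    scatter = "lymphocyte"
    for node in tree.path(name):
        expr = node.expression
        for term in _threshold_terms(expr):
            if term.relation == "all":
                continue
            level = _RELATION_TO_LEVEL[term.relation]
            prev = levels.get(term.marker)
            if prev is not None and prev != level:
                raise ValueError(
                    f"gate {name!r}: contradictory requirements on {term.marker!r} "
                    f"along its path ({prev} vs {level})"
                )
            levels[term.marker] = level
        rects = [expr] if isinstance(expr, RectGate) else (
            [t for t in expr.terms if isinstance(t, RectGate)] if isinstance(expr, And) else []
        )
        for r in rects:
            if r.x_channel == "FSC-A":
                scatter = "monocyte" if r.x_min >= 60_000 else "lymphocyte"
    return levels, scatter


def _satisfies(level: str, relation: str) -> bool:
    """Would the level's median raw value pass the relation at default cutoffs?"""
    med = LEVEL_MEDIANS[level]
    if relation == "all":
        return True
    if relation == "+":
        return med >= 500
    if relation == "-":
        return med < 500
    if relation == "hi":
        return med >= 10_000
    if relation == "lo":
        return 500 <= med < 10_000
    if relation == "int":
        return 200 <= med < 2_000
    raise ValueError(relation)


def _lands_deeper(tree: GatingTree, name: str, levels: dict[str, str]) -> Optional[str]:
    """Name of a canonical strict descendant the default template would enter."""
    target_path = {n.name for n in tree.path(name)}
    for node in tree:
        if not node.canonical or node.name == name:
            continue
        path = tree.path(node.name)
        if name not in {p.name for p in path}:
            continue  # not a descendant
        ok = True
        for sub in path:
            if sub.name in target_path:
                continue
            for term in _threshold_terms(sub.expression):
                lvl = levels.get(term.marker, "neg")
                if not _satisfies(lvl, term.relation):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return node.name
    return None


def templates_from_gating(
    tree: GatingTree,
    markers: Sequence[str],
    frequencies: Optional[dict[str, float]] = None,
    overrides: Optional[dict[str, dict[str, str]]] = None,
    baseline: Optional[dict[str, str]] = None,
) -> list[PopulationTemplate]:
    """Invert gate definitions into generative population templates.

    One template per requested canonical population; each template's marker
    levels are the conjunction of the threshold terms along its root path,
    with unconstrained markers drawn negative (or per ``baseline`` /
    ``overrides`` — e.g. every cellular template carries CD45 pos so it
    survives the CD45+ pre-gate, which is not part of the tree).  When
    ``frequencies`` is omitted, every *generable* canonical population — one
    whose default template does not satisfy a deeper canonical descendant's
    gates (e.g. a parent fully partitioned by its children) — is generated at
    equal frequency.  Contradictory paths raise, naming the node.
    """
    overrides = overrides or {}
    baseline = baseline or {}
    if frequencies is not None:
        requested = list(frequencies)
    else:
        requested = []
        for node in tree:
            if not node.canonical:
                continue
            levels, _ = _path_constraints(tree, node.name)
            merged = dict(baseline)
            merged.update(levels)
            merged.update(overrides.get(node.name, {}))
            if _lands_deeper(tree, node.name, merged) is None:
                requested.append(node.name)
        if not requested:
            raise ValueError("tree has no generable canonical populations")

    canonical = set(tree.canonical_populations())
    templates = []
    n = len(requested)
    for name in requested:
        if name not in canonical:
            raise ValueError(f"{name!r} is not a canonical population of this tree")
        levels, scatter = _path_constraints(tree, name)
        full = {m: "neg" for m in markers}
        full.update(baseline)
        full.update(levels)
        full.update(overrides.get(name, {}))
        deeper = _lands_deeper(tree, name, full)
        if deeper is not None:
            raise ValueError(
                f"template for {name!r} is not generable: its default marker levels "
                f"satisfy the deeper canonical gate {deeper!r}"
            )
        freq = frequencies[name] if frequencies is not None else 1.0 / n
        templates.append(
            PopulationTemplate(name=name, marker_levels=full, frequency=freq, scatter=scatter)
        )
    return templates


def extra_template(
    name: str, markers: Sequence[str], levels: dict[str, str], frequency: float,
    scatter: str = "lymphocyte",
) -> PopulationTemplate:
    """Non-canonical filler population (e.g. cells outside every gate)."""
    full = {m: "neg" for m in markers}
    full.update(levels)
    return PopulationTemplate(
        name=name, marker_levels=full, frequency=frequency, scatter=scatter, canonical=False
    )


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------


def _draw_markers(
    rng: np.random.Generator, templates: list[PopulationTemplate],
    choice: np.ndarray, markers: list[str],
) -> np.ndarray:
    n = choice.shape[0]
    A = np.empty((n, len(markers)))
    level_mu = np.empty((len(templates), len(markers)))
    level_sd = np.empty_like(level_mu)
    for t_i, t in enumerate(templates):
        for m_i, m in enumerate(markers):
            mu, sd = LEVELS[t.marker_levels[m]]
            level_mu[t_i, m_i] = mu
            level_sd[t_i, m_i] = sd
    z = rng.standard_normal((n, len(markers)))
    A[:] = np.exp(level_mu[choice] + level_sd[choice] * z)
    return A


def simulate_sample(
    templates: Sequence[PopulationTemplate],
    sigs: SignatureMatrix,
    n_events: int,
    artifacts: Optional[dict[str, float]] = None,
    noise: tuple[float, float] = (5.0, 0.02),
    seed: int = 0,
    marker_map: Optional[dict[str, str]] = None,
    viability_marker: str = "ViaDyeRed",
    sample_id: str = "synthetic",
    gains: Optional[np.ndarray] = None,
    offsets: Optional[np.ndarray] = None,
) -> EventMatrix:
    """Simulate one detector-space sample with ground-truth labels.

    Marker-space abundances are drawn per template and mixed to detector
    space as ``y = a . S + af + noise``; truth labels carry the template name
    (artifact events are labeled ``doublet`` / ``dead`` / ``rbc_debris``).
    ``artifacts`` gives artifact fractions, e.g. ``{"doublet": 0.05,
    "dead": 0.03, "rbc": 0.02}``; the remaining fraction is drawn from the
    templates.  Deterministic per seed.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    templates = list(templates)
    freq = np.array([t.frequency for t in templates], dtype=float)
    if abs(freq.sum() - 1.0) > 1e-9:
        raise ValueError(f"template frequencies must sum to 1 (got {freq.sum():.12f})")
    artifacts = artifacts or {}
    f_doublet = float(artifacts.get("doublet", 0.0))
    f_dead = float(artifacts.get("dead", 0.0))
    f_rbc = float(artifacts.get("rbc", 0.0))
    if f_doublet + f_dead + f_rbc >= 1.0:
        raise ValueError("artifact fractions must sum to <1")

    rng = np.random.default_rng(seed)
    marker_map = marker_map or {f: f for f in sigs.fluorophores}
    markers = [marker_map[f] for f in sigs.fluorophores]
    S = np.stack([s.profile for s in sigs.signatures])  # fluors x detectors
    n_det = sigs.n_detectors

    n_rbc = int(round(n_events * f_rbc))
    n_dead = int(round(n_events * f_dead))
    n_doublet = int(round(n_events * f_doublet))
    n_clean = n_events - n_rbc - n_dead - n_doublet

    # clean cells (+ extra draws consumed by doublets)
    n_cells = n_clean + 2 * n_doublet + n_dead
    choice = rng.choice(len(templates), size=n_cells, p=freq)
    A = _draw_markers(rng, templates, choice, markers)
    if gains is not None:
        A = A * np.asarray(gains, dtype=float)[None, :]
    if offsets is not None:
        A = A + np.asarray(offsets, dtype=float)[None, :]
        A = np.clip(A, 0.0, None)
    if viability_marker in markers:
        v_idx = markers.index(viability_marker)
        mu_hi, sd_hi = LEVELS["hi"]
        # dead cells take up the viability dye
        A[n_cells - n_dead :, v_idx] = np.exp(
            mu_hi + sd_hi * rng.standard_normal(n_dead)
        )

    af_scale = np.exp(AF_LEVEL[0] + AF_LEVEL[1] * rng.standard_normal(n_cells))
    Y = A @ S
    if sigs.autofluorescence is not None:
        Y = Y + af_scale[:, None] * sigs.autofluorescence.profile[None, :]

    # scatter per cell
    prof_idx = np.array(
        [list(SCATTER_PROFILES).index(templates[c].scatter) for c in choice]
    )
    params = np.array([SCATTER_PROFILES[k] for k in SCATTER_PROFILES])
    fsc = params[prof_idx, 0] + params[prof_idx, 1] * rng.standard_normal(n_cells)
    ssc = params[prof_idx, 2] + params[prof_idx, 3] * rng.standard_normal(n_cells)
    fsc = np.clip(fsc, 1.0, None)
    ssc = np.clip(ssc, 1.0, None)
    fsc_h = fsc / (1.0 + 0.03 * rng.standard_normal(n_cells))

    labels = np.array([templates[c].name for c in choice], dtype=object)
    labels[n_cells - n_dead :] = "dead"

    # doublets: sum two singlet draws, height stays near the larger singlet
    d_lo = n_clean
    d_hi = n_clean + 2 * n_doublet
    Yd = Y[d_lo:d_hi:2] + Y[d_lo + 1 : d_hi : 2]
    fsc_d = fsc[d_lo:d_hi:2] + fsc[d_lo + 1 : d_hi : 2]
    ssc_d = ssc[d_lo:d_hi:2] + ssc[d_lo + 1 : d_hi : 2]
    fsc_h_d = np.maximum(fsc_h[d_lo:d_hi:2], fsc_h[d_lo + 1 : d_hi : 2])

    # RBC-like debris: low scatter, near-zero everything
    Yr = np.exp(AF_LEVEL[0] + AF_LEVEL[1] * rng.standard_normal(n_rbc))[:, None] * (
        sigs.autofluorescence.profile[None, :]
        if sigs.autofluorescence is not None
        else np.full((1, n_det), 1.0 / math.sqrt(n_det))
    ) * 0.3
    p_deb = SCATTER_PROFILES["debris"]
    fsc_r = np.clip(p_deb[0] + p_deb[1] * rng.standard_normal(n_rbc), 1.0, None)
    ssc_r = np.clip(p_deb[2] + p_deb[3] * rng.standard_normal(n_rbc), 1.0, None)
    fsc_h_r = fsc_r / (1.0 + 0.03 * rng.standard_normal(n_rbc))

    Y_all = np.vstack([Y[:n_clean], Y[d_hi:], Yd, Yr])
    fsc_all = np.concatenate([fsc[:n_clean], fsc[d_hi:], fsc_d, fsc_r])
    ssc_all = np.concatenate([ssc[:n_clean], ssc[d_hi:], ssc_d, ssc_r])
    fsc_h_all = np.concatenate([fsc_h[:n_clean], fsc_h[d_hi:], fsc_h_d, fsc_h_r])
    labels_all = np.concatenate(
        [
            labels[:n_clean],
            labels[d_hi:],
            np.full(n_doublet, "doublet", dtype=object),
            np.full(n_rbc, "rbc_debris", dtype=object),
        ]
    )

    noise_sd = noise[0] + noise[1] * np.abs(Y_all)
    Y_all = Y_all + noise_sd * rng.standard_normal(Y_all.shape)

    perm = rng.permutation(n_events)
    values = np.hstack(
        [Y_all, fsc_all[:, None], fsc_h_all[:, None], ssc_all[:, None]]
    )[perm]
    labels_all = labels_all[perm]

    names = [f"D{i}" for i in range(n_det)] + ["FSC-A", "FSC-H", "SSC-A"]
    kinds = ["detector"] * n_det + ["scatter"] * 3
    return EventMatrix(
        values=values,
        channel_names=names,
        channel_kinds=kinds,
        sample_id=sample_id,
        truth_labels=labels_all,
        metadata={"seed": seed},
    )


def default_templates(panel: PanelConfig, tree: GatingTree) -> list[PopulationTemplate]:
    """The panel's shipped study-condition templates (frequencies from config)."""
    freqs = panel.default_frequencies or None
    canon = templates_from_gating(
        tree, panel.all_markers, frequencies=freqs,
        overrides=panel.template_overrides, baseline=panel.template_baseline,
    )
    extras = [
        extra_template(
            e["name"], panel.all_markers, e.get("levels", {}), float(e["frequency"]),
            scatter=e.get("scatter", "lymphocyte"),
        )
        for e in panel.extra_templates
    ]
    templates = canon + extras
    total = sum(t.frequency for t in templates)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"panel default frequencies sum to {total:.12f}, expected 1")
    return templates


def simulate_panel_sample(
    panel: PanelConfig,
    tree: GatingTree,
    n_events: int,
    artifacts: Optional[dict[str, float]] = None,
    seed: int = 0,
    sample_id: Optional[str] = None,
    templates: Optional[Sequence[PopulationTemplate]] = None,
) -> EventMatrix:
    """Simulate one sample under a shipped panel's study conditions."""
    if templates is None:
        templates = default_templates(panel, tree)
    marker_map = dict(zip(panel.all_fluorophores, panel.all_markers))
    return simulate_sample(
        templates,
        panel.signatures,
        n_events,
        artifacts=artifacts,
        seed=seed,
        marker_map=marker_map,
        viability_marker=panel.viability_marker,
        sample_id=sample_id or f"{panel.panel_id}-sim",
    )


def simulate_batches(
    templates: Sequence[PopulationTemplate],
    sigs: SignatureMatrix,
    n_events_per_batch: int,
    batch_spec: BatchEffectSpec,
    n_batches: int,
    seed: int = 0,
    marker_map: Optional[dict[str, str]] = None,
    viability_marker: str = "ViaDyeRed",
) -> list[EventMatrix]:
    """Simulate ``n_batches`` samples sharing templates but differing by
    per-channel gain/offset shifts; optionally inject a donor-unique
    population into one batch.
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    gains, offsets = batch_spec.realise(n_batches, len(sigs.fluorophores))
    out = []
    for b in range(n_batches):
        batch_templates = list(templates)
        if batch_spec.unique_population is not None and b == batch_spec.unique_batch:
            uniq = batch_spec.unique_population
            scale = 1.0 - uniq.frequency
            batch_templates = [
                PopulationTemplate(
                    t.name, t.marker_levels, t.frequency * scale, t.scatter, t.canonical
                )
                for t in batch_templates
            ] + [uniq]
        m = simulate_sample(
            batch_templates,
            sigs,
            n_events_per_batch,
            seed=seed + 1000 * (b + 1),
            marker_map=marker_map,
            viability_marker=viability_marker,
            sample_id=f"batch{b}",
            gains=gains[b],
            offsets=offsets[b],
        )
        m.batch_id = f"batch{b}"
        out.append(m)
    return out
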