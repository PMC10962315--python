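"""Shared fixtures: loaded panels and simulated, unmixed, gated samples."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cytospec import (
    apply_pregates,
    load_panel,
    parse_gating_config,
    run_gating_tree,
    unmix,
)
from cytospec.synth import simulate_panel_sample


@pytest.fixture(scope="session")
def panels():
    """All three shipped panel configs with parsed gating trees."""
    out = {}
    for pid in ("tb", "mnd", "bmc"):
        panel = load_panel(pid)
        tree = parse_gating_config(panel.gating_spec, markers=panel.all_markers)
        out[pid] = (panel, tree)
    return out


@pytest.fixture(scope="session")
def tb_panel(panels):
    return panels["tb"]


def _gated_sample(panel, tree, n_events, seed, artifacts=None):
    raw = simulate_panel_sample(panel, tree, n_events, artifacts=artifacts, seed=seed)
    unmixed = unmix(raw, panel.signatures, markers=panel.all_markers)
    pre = apply_pregates(unmixed, panel)
    result = run_gating_tree(tree, pre, panel)
    return raw, unmixed, pre, result


@pytest.fixture(scope="session")
def tb_gated(tb_panel):
    """Simulated T/B sample (30k events incl. artifacts), unmixed and gated."""
    panel, tree = tb_panel
    return _gated_sample(
        panel, tree, 30_000, seed=42,
        artifacts={"doublet": 0.05, "dead": 0.03, "rbc": 0.02},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
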