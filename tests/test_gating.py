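"""Gating DSL parsing, pre-gates, tree evaluation, and rare populations."""

import numpy as np
import pytest

from cytospec import (
    EventMatrix,
    apply_overlays,
    apply_pregates,
    detect_rare_populations,
    parse_expression,
    parse_gating_config,
    run_gating_tree,
)
from cytospec.gating import And, Threshold


class TestExpressionParsing:
    @pytest.mark.parametrize(
        "text, marker, relation",
        [
            ("CD25+", "CD25", "+"),
            ("CD127-", "CD127", "-"),
            ("HLA-DR-", "HLA-DR", "-"),
            ("CD45RAhi", "CD45RA", "hi"),
            ("CD8lo", "CD8", "lo"),
            ("CD45int", "CD45", "int"),
            ("CD45RAall", "CD45RA", "all"),
        ],
    )
    def test_threshold_tokens(self, text, marker, relation):
        expr = parse_expression(text)
        assert isinstance(expr, Threshold)
        assert (expr.marker, expr.relation) == (marker, relation)

    def test_compound_string_is_conjunction(self):
        expr = parse_expression("CD25+ CD127-")
        assert isinstance(expr, And)
        assert {(t.marker, t.relation) for t in expr.terms} == {("CD25", "+"), ("CD127", "-")}

    def test_unparseable_token_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_expression("CD25")


class TestConfigParsing:
    def test_shipped_treg_definition(self, tb_panel):
        _, tree = tb_panel
        node = tree.node("Regulatory T cells")
        terms = {(t.marker, t.relation) for t in node.expression.terms}
        assert terms == {("CD25", "+"), ("CD127", "-")}

    def test_all_shipped_configs_parse(self, panels):
        for pid, (panel, tree) in panels.items():
            assert len(tree.nodes) > 10
            assert tree.canonical_populations()

    def test_unknown_marker_rejected(self):
        cfg = {"gates": [{"name": "bad", "parent": "root", "expr": "CD999+"}]}
        with pytest.raises(ValueError, match="CD999"):
            parse_gating_config(cfg, markers=["CD3"])

    def test_cycle_rejected(self):
        cfg = {"gates": [
            {"name": "a", "parent": "b", "expr": "CD3+"},
            {"name": "b", "parent": "a", "expr": "CD3-"},
        ]}
        with pytest.raises(ValueError, match="cyclic|unknown parent"):
            parse_gating_config(cfg, markers=["CD3"])

    def test_duplicate_name_rejected(self):
        cfg = {"gates": [
            {"name": "a", "parent": "root", "expr": "CD3+"},
            {"name": "a", "parent": "root", "expr": "CD3-"},
        ]}
        with pytest.raises(ValueError, match="duplicate"):
            parse_gating_config(cfg, markers=["CD3"])

    def test_minimal_config_yields_two_node_tree(self):
        tree = parse_gating_config(
            {"gates": [{"name": "T", "parent": "root", "expr": "CD3+"}]}, markers=["CD3"]
        )
        assert [n.name for n in tree.nodes] == ["T"]
        assert tree.depth("T") == 1


class TestPregates:
    def test_artifact_removal_matches_generator_truth(self, tb_gated):
        raw, unmixed, pre, _ = tb_gated
        survivors = pre.n_events / unmixed.n_events
        truth = unmixed.truth_labels
        clean = ~np.isin(truth, ["doublet", "dead", "rbc_debris"])
        # survivors should track the clean, CD45+ fraction within a few percent
        cd45_pos = np.isin(truth, ["Basophils"], invert=True)  # basophils partly CD45-dim
        expected = clean.mean()
        assert survivors == pytest.approx(expected, abs=0.03)
        # no artifact class survives pre-gating in any quantity
        kept = pre.truth_labels
        for artifact in ("doublet", "dead", "rbc_debris"):
            assert (kept == artifact).mean() < 0.005

    def test_missing_viability_channel_rejected(self, tb_panel, rng):
        panel, _ = tb_panel
        ev = EventMatrix(rng.uniform(0, 1e4, (10, 2)), ["CD45", "FSC-A"], ["marker", "scatter"])
        with pytest.raises(ValueError, match="requires channels"):
            apply_pregates(ev, panel)


class TestTreeEvaluation:
    def test_containment_and_partition(self, tb_panel, tb_gated):
        panel, tree = tb_panel
        _, _, pre, result = tb_gated
        m = result.memberships
        by_name = {n.name: n for n in tree.nodes}
        for node in tree.nodes:
            parent = m[node.parent] if node.parent != "root" else np.ones(len(m), bool)
            assert not (m[node.name] & ~parent).any(), node.name
        # CD45RA/CD197 quadrants partition their parent exactly
        quad = ["Naive CD8", "TEMRA CD8", "Central memory CD8", "Effector CD8"]
        total = sum(m[q].to_numpy().astype(int) for q in quad)
        parent = m["CD8 T cells"].to_numpy()
        assert (total[parent] == 1).all()
        assert (total[~parent] == 0).all()

    def test_assignment_recovers_truth(self, tb_panel, tb_gated):
        panel, tree = tb_panel
        _, _, pre, result = tb_gated
        canon = set(tree.canonical_populations())
        mask = np.isin(pre.truth_labels, list(canon))
        acc = (result.assignments[mask] == pre.truth_labels[mask]).mean()
        assert acc >= 0.99

    def test_event_order_invariance(self, tb_panel, tb_gated):
        panel, tree = tb_panel
        _, _, pre, result = tb_gated
        rng = np.random.default_rng(0)
        perm = rng.permutation(pre.n_events)
        shuffled = pre.select_events(perm)
        res2 = run_gating_tree(tree, shuffled, panel)
        merged = result.table.merge(res2.table, on="population", suffixes=("_a", "_b"))
        assert (merged["count_a"] == merged["count_b"]).all()
        assert np.allclose(merged["pct_of_parent_a"], merged["pct_of_parent_b"])

    def test_zero_parent_gives_zero_descendants(self, tb_panel, rng):
        panel, tree = tb_panel
        markers = panel.all_markers
        # all-zero events: CD3- so every T-cell node is empty
        ev = EventMatrix(
            np.ones((50, len(markers) + 3)),
            markers + ["FSC-A", "FSC-H", "SSC-A"],
            ["marker"] * len(markers) + ["scatter"] * 3,
        )
        result = run_gating_tree(tree, ev, panel)
        t_rows = result.table.set_index("population")
        assert t_rows.loc["Total T cells", "count"] == 0
        assert t_rows.loc["Naive CD8", "count"] == 0
        assert t_rows.loc["Naive CD8", "pct_of_parent"] == 0.0

    def test_empty_event_matrix(self, tb_panel):
        panel, tree = tb_panel
        markers = panel.all_markers
        ev = EventMatrix(
            np.empty((0, len(markers) + 3)),
            markers + ["FSC-A", "FSC-H", "SSC-A"],
            ["marker"] * len(markers) + ["scatter"] * 3,
        )
        result = run_gating_tree(tree, ev, panel)
        assert (result.table["count"] == 0).all()

    def test_frequency_recovery_against_truth(self, tb_panel, tb_gated):
        """Percent-of-total per population tracks the generator frequencies."""
        panel, tree = tb_panel
        _, _, pre, result = tb_gated
        truth = pre.truth_labels
        tab = result.table.set_index("population")
        for pop in ("Naive CD4", "Naive B", "Regulatory T cells"):
            truth_frac = (truth == pop).mean()
            got = tab.loc[pop, "pct_of_cd45"] / 100.0
            sd = np.sqrt(truth_frac * (1 - truth_frac) / len(truth))
            assert abs(got - truth_frac) <= max(3 * sd, 0.005), pop

    def test_bmc_hsc_gate_purity(self, panels):
        """Only events generated as CD34+CD38-CD45RA-CD90+ reach the HSC gate."""
        panel, tree = panels["bmc"]
        from cytospec.synth import simulate_panel_sample
        from cytospec import unmix

        raw = simulate_panel_sample(panel, tree, 40_000, seed=11)
        pre = apply_pregates(unmix(raw, panel.signatures, markers=panel.all_markers), panel)
        result = run_gating_tree(tree, pre, panel)
        in_hsc = result.memberships["HSC"].to_numpy()
        assert in_hsc.sum() > 0
        frac_true = (pre.truth_labels[in_hsc] == "HSC").mean()
        assert frac_true >= 0.95
        # and HSC truth events end up in the HSC gate
        hsc_truth = pre.truth_labels == "HSC"
        assert in_hsc[hsc_truth].mean() >= 0.95


class TestOverlays:
    def test_checkpoint_overlays_report_fraction_of_base(self, tb_panel, tb_gated):
        panel, tree = tb_panel
        _, _, pre, result = tb_gated
        ov = apply_overlays(result, pre, panel)
        assert set(ov["overlay"]) == {
            "Activated T cells", "PD-1+", "TIM-3+", "LAG-3+", "CTLA-4+"
        }
        assert (ov["pct_of_base"] >= 0).all() and (ov["pct_of_base"] <= 100).all()

    def test_unknown_base_rejected(self, tb_panel, tb_gated):
        panel, _ = tb_panel
        _, _, pre, result = tb_gated
        with pytest.raises(ValueError, match="nonsense"):
            apply_overlays(result, pre, panel, overlays=[
                {"name": "x", "base": "nonsense", "expr": "CD3+"}
            ])


class TestRarePopulations:
    def test_basophil_recovery_within_reported_band(self, tb_panel, tb_gated):
        panel, _ = tb_panel
        _, _, pre, _ = tb_gated
        rare = detect_rare_populations(pre, panel).set_index("population")
        baso = rare.loc["Basophils", "pct_of_cd45"]
        assert 0.1 <= baso <= 0.5

    def test_ilc_recovery_matches_truth(self, tb_panel, tb_gated):
        panel, _ = tb_panel
        _, _, pre, _ = tb_gated
        rare = detect_rare_populations(pre, panel).set_index("population")
        truth_frac = (pre.truth_labels == "ILCs").mean() * 100
        got = rare.loc["ILCs", "pct_of_cd45"]
        sd = 100 * np.sqrt(truth_frac / 100 * (1 - truth_frac / 100) / pre.n_events)
        assert abs(got - truth_frac) <= max(3 * sd, 0.1)

    def test_absent_dp_population_reports_zero(self, tb_panel, rng):
        panel, _ = tb_panel
        markers = panel.all_markers
        n = 200
        vals = np.full((n, len(markers)), 50.0)
        ev = EventMatrix(vals, markers, ["marker"] * len(markers))
        rare = detect_rare_populations(ev, panel).set_index("population")
        assert rare.loc["DP T cells (CD4hi/CD8lo)", "count"] == 0
        assert rare.loc["DP T cells (CD4lo/CD8hi)", "count"] == 0

    def test_mnd_panel_screens_basophils_only_dp_skipped(self, panels, rng):
        panel, _ = panels["mnd"]
        markers = panel.all_markers
        ev = EventMatrix(
            np.full((50, len(markers)), 50.0), markers, ["marker"] * len(markers)
        )
        rare = detect_rare_populations(ev, panel)
        assert "Basophils" in set(rare["population"])
        assert "DP T cells (CD4hi/CD8lo)" not in set(rare["population"])
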