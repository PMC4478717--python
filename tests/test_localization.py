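"""S character, ancestral reconstruction and the correlated-evolution index."""

import numpy as np
import pytest

import mitorisk as mr
from mitorisk.localization import (
    CASE_ASSOCIATED,
    CONTROL_ASSOCIATED,
    AnalysisTree,
    build_analysis_tree,
    correlated_evolution_index,
)

from conftest import oracle_fitch_score


def counts(per_hap):
    return mr.HaplotypeStatusCounts(per_haplotype=per_hap)


class TestSCharacter:
    def test_case_excess(self):
        s = mr.compute_S(counts({"h": (3, 1), "rest": (47, 49)}))
        assert s["h"] == CASE_ASSOCIATED

    def test_tie_is_control(self):
        s = mr.compute_S(counts({"h": (1, 1), "rest": (49, 49)}))
        assert s["h"] == CONTROL_ASSOCIATED

    @pytest.mark.parametrize(
        "hap,expected",
        [((3, 1), CASE_ASSOCIATED), ((2, 1), CONTROL_ASSOCIATED)],
    )
    def test_epsilon_downweights_case_calls(self, hap, expected):
        per = {"h": hap, "rest": (50 - hap[0], 50 - hap[1])}
        s = mr.compute_S(counts(per), mr.SCharacterConfig(epsilon=2.0))
        assert s["h"] == expected

    def test_zero_member_haplotype_excluded(self):
        s = mr.compute_S(counts({"h": (0, 0), "rest": (5, 5)}))
        assert "h" not in s


def balanced_tree():
    #      r
    #    /   \
    #   u     v
    #  / \   / \
    # a   b c   d
    return AnalysisTree(
        root="r", children={"r": ["u", "v"], "u": ["a", "b"], "v": ["c", "d"],
                            "a": [], "b": [], "c": [], "d": []}
    )


class TestReconstruction:
    def test_constant_character_no_changes(self):
        tree = balanced_tree()
        leaves = {n: np.array([1]) for n in "abcd"}
        recon = mr.reconstruct_ancestral(tree, leaves, ["x"], method="fitch_acctran")
        assert all(recon.node_states[n][0] == 1 for n in ["r", "u", "v"])
        assert recon.scores[0] == 0

    def test_one_change_on_internal_edge(self):
        tree = balanced_tree()
        leaves = {"a": [1], "b": [1], "c": [0], "d": [0]}
        recon = mr.reconstruct_ancestral(tree, leaves, ["x"])
        assert recon.scores[0] == 1
        changes = recon.edge_changes(0)
        assert len(changes) == 1
        assert changes[0][:2] in {("r", "u"), ("r", "v")}

    @pytest.mark.parametrize("seed", range(6))
    def test_score_equals_bruteforce_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 10))
        children = {0: []}
        for i in range(1, n):
            parent = int(rng.integers(i))
            children.setdefault(parent, []).append(i)
            children[i] = []
        tree = AnalysisTree(root=0, children=children)
        leaves = [v for v in children if not children[v]]
        states = {v: np.array([int(rng.integers(2))]) for v in leaves}
        recon = mr.reconstruct_ancestral(tree, states, ["x"])
        assert recon.scores[0] == oracle_fitch_score(
            children, 0, {v: s[0] for v, s in states.items()}
        )

    def test_acctran_places_change_near_root(self):
        # caterpillar r-i1-i2 with leaves: l0 (under r side) 0, deep leaves 1
        tree = AnalysisTree(
            root="r",
            children={"r": ["l0", "i1"], "i1": ["l1", "i2"], "i2": ["l2", "l3"],
                      "l0": [], "l1": [], "l2": [], "l3": []},
        )
        leaves = {"l0": [0], "l1": [1], "l2": [1], "l3": [1]}
        recon = mr.reconstruct_ancestral(tree, leaves, ["x"])
        # one change, pushed onto the edge closest to the root (r->i1)
        assert recon.scores[0] == 1
        assert recon.edge_changes(0) == [("r", "i1", "01")]

    def test_ml_matches_parsimony_on_clear_signal(self):
        tree = balanced_tree()
        leaves = {"a": [1], "b": [1], "c": [0], "d": [0]}
        fitch = mr.reconstruct_ancestral(tree, leaves, ["x"], method="fitch_acctran")
        ml = mr.reconstruct_ancestral(tree, leaves, ["x"], method="ml_unit_branch")
        assert ml.node_states["u"][0] == fitch.node_states["u"][0] == 1
        assert ml.node_states["v"][0] == 0

    def test_ml_leaves_keep_observed_states(self):
        tree = balanced_tree()
        leaves = {"a": [1], "b": [0], "c": [0], "d": [1]}
        ml = mr.reconstruct_ancestral(tree, leaves, ["x"], method="ml_unit_branch")
        for n, s in leaves.items():
            assert ml.node_states[n][0] == s[0]

    def test_isolated_stateless_node_rejected(self):
        tree = AnalysisTree(root="r", children={"r": ["a", "b"], "a": [], "b": []})
        with pytest.raises(Exception):
            mr.reconstruct_ancestral(tree, {"a": [1]}, ["x"])


def star_tree(n_leaves=4):
    children = {"r": [f"l{i}" for i in range(n_leaves)]}
    for i in range(n_leaves):
        children[f"l{i}"] = []
    return AnalysisTree(root="r", children=children)


class TestCorrelatedEvolution:
    def make_recon(self, site_states, s_states):
        """4-leaf star; root all-ancestral; per-leaf (site, S) states."""
        tree = star_tree(4)
        node_states = {"r": np.array([0, 0])}
        for i, (x, s) in enumerate(zip(site_states, s_states)):
            node_states[f"l{i}"] = np.array([x, s])
        return mr.localization.AncestralReconstruction(
            tree=tree, node_states=node_states, char_names=["site", "S"],
            method="fitch_acctran",
        )

    def test_perfect_cooccurrence(self):
        recon = self.make_recon([1, 0, 0, 0], [1, 0, 0, 0])
        res = correlated_evolution_index(recon, s_index=1, site_indices=[0])
        fwd = [r for r in res if r.direction == "ancestral->derived"][0]
        assert fwd.index == pytest.approx(1.0)
        assert fwd.rank == 1

    def test_disjoint_changes_phi(self):
        # site changes on edge 1, S on edge 2, 4 edges -> phi = -1/3
        recon = self.make_recon([1, 0, 0, 0], [0, 1, 0, 0])
        res = correlated_evolution_index(recon, s_index=1, site_indices=[0])
        fwd = [r for r in res if r.direction == "ancestral->derived"][0]
        assert fwd.index == pytest.approx(-1 / 3)

    def test_constant_site_undefined(self):
        recon = self.make_recon([0, 0, 0, 0], [1, 0, 0, 0])
        res = correlated_evolution_index(recon, s_index=1, site_indices=[0])
        assert all(r.index is None and r.rank is None for r in res)

    def test_antisymmetry_under_s_polarity_swap(self):
        recon = self.make_recon([1, 0, 1, 0], [1, 1, 0, 0])
        res = correlated_evolution_index(recon, s_index=1, site_indices=[0])
        flipped_states = {
            n: np.array([v[0], 1 - v[1]]) for n, v in recon.node_states.items()
        }
        recon_flipped = mr.localization.AncestralReconstruction(
            tree=recon.tree, node_states=flipped_states, char_names=recon.char_names,
            method="fitch_acctran",
        )
        res_f = correlated_evolution_index(recon_flipped, s_index=1, site_indices=[0])
        for a, b in zip(res, res_f):
            if a.index is None:
                assert b.index is None
            else:
                assert a.index == pytest.approx(-b.index)

    def test_ranking_invariant_to_edge_enumeration(self):
        # relabeling children reverses preorder edge order; indices unchanged
        recon = self.make_recon([1, 0, 1, 0], [1, 1, 0, 0])
        res1 = correlated_evolution_index(recon, s_index=1, site_indices=[0])
        reversed_children = {
            n: list(reversed(k)) for n, k in recon.tree.children.items()
        }
        recon2 = mr.localization.AncestralReconstruction(
            tree=AnalysisTree(root="r", children=reversed_children),
            node_states=recon.node_states, char_names=recon.char_names,
            method="fitch_acctran",
        )
        res2 = correlated_evolution_index(recon2, s_index=1, site_indices=[0])
        for a, b in zip(res1, res2):
            assert (a.index is None) == (b.index is None)
            if a.index is not None:
                assert a.index == pytest.approx(b.index)


class TestEndToEnd:
    def test_causal_site_top_ranked(self, curated):
        # risk-increasing T1 lineage: the T1-defining substitutions must rank
        # first in the ancestral->derived direction
        tree, panel = curated
        cfg = mr.SimConfig(
            n_individuals=1500,
            hazard_ratios={"T1": 2.5},
            missing_rate=0,
            het_rate=0,
            error_rate=0,
        )
        gm, meta, _ = mr.simulate_cohort(tree, panel, cfg, seed=42)
        clean, _ = mr.run_qc(gm, tree)
        index = mr.build_short_haplotype_index(tree, clean.panel)
        from mitorisk.assign import assignments_to_frame

        df = assignments_to_frame(mr.assign_individuals(clean, index))
        data = df[df["matched"]].merge(meta, on="sample_id")
        loc = mr.localize_susceptibility_sites(tree, clean.panel, data, "T")
        # parsimony co-places every T1-lineage change on the same edge, so
        # the causal-lineage substitutions share the maximal index
        best = loc["index"].dropna().max()
        assert best > 0.5
        for mut in ("T9899C", "G12633A"):
            row = loc[(loc["mutation"] == mut)
                      & (loc["direction"] == "ancestral->derived")].iloc[0]
            assert row["index"] == pytest.approx(best)

    def test_fitch_and_ml_agree_on_causal_lineage(self, curated):
        tree, panel = curated
        cfg = mr.SimConfig(
            n_individuals=800, hazard_ratios={"T1": 2.5},
            missing_rate=0, het_rate=0, error_rate=0,
        )
        gm, meta, _ = mr.simulate_cohort(tree, panel, cfg, seed=77)
        clean, _ = mr.run_qc(gm, tree)
        index = mr.build_short_haplotype_index(tree, clean.panel)
        from mitorisk.assign import assignments_to_frame

        df = assignments_to_frame(mr.assign_individuals(clean, index))
        data = df[df["matched"]].merge(meta, on="sample_id")
        for method in ("fitch_acctran", "ml_unit_branch"):
            loc = mr.localize_susceptibility_sites(
                tree, clean.panel, data, "T", method=method
            )
            best = loc["index"].dropna().max()
            row = loc[(loc["mutation"] == "T9899C")
                      & (loc["direction"] == "ancestral->derived")].iloc[0]
            assert row["index"] == pytest.approx(best)
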