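import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netphix import (
    AlterationMatrix,
    TargetSet,
    TwoSidedModule,
    anova_three_group,
    assign_groups,
    benjamini_hochberg,
    module_target_distance,
    suggest_drug_pairs,
)


class TestTargetDistance:
    def test_target_gene_distance_zero(self, path_network):
        M = TwoSidedModule(increased=frozenset({"a"}))
        rep = module_target_distance(M, TargetSet("d", frozenset({"a"})),
                                     path_network)
        assert rep.overall_mean == 0.0

    def test_path_hand_example(self, path_network):
        # targets = {a}; module genes b (1 hop) and c (2 hops) -> mean 1.5
        M = TwoSidedModule(increased=frozenset({"b", "c"}))
        rep = module_target_distance(M, TargetSet("d", frozenset({"a"})),
                                     path_network)
        assert rep.overall_mean == pytest.approx(1.5)
        assert rep.per_gene == {"b": 1.0, "c": 2.0}

    def test_min_over_multiple_targets(self):
        G = nx.path_graph(["t1", "x", "y", "t2", "g"])
        M = TwoSidedModule(increased=frozenset({"g"}))
        rep = module_target_distance(M, TargetSet("d", frozenset({"t1", "t2"})), G)
        assert rep.overall_mean == 1.0  # adjacent to t2

    def test_per_side_means(self):
        G = nx.path_graph(["t", "x", "y"])
        M = TwoSidedModule(increased=frozenset({"x"}), decreased=frozenset({"y"}))
        rep = module_target_distance(M, TargetSet("d", frozenset({"t"})), G)
        assert rep.increased_mean == 1.0
        assert rep.decreased_mean == 2.0
        assert rep.overall_mean == 1.5

    def test_unreachable_genes_counted_not_averaged(self):
        G = nx.Graph()
        G.add_edge("t", "x")
        G.add_node("island")
        M = TwoSidedModule(increased=frozenset({"x", "island"}))
        rep = module_target_distance(M, TargetSet("d", frozenset({"t"})), G)
        assert rep.overall_mean == 1.0
        assert rep.n_unreachable == 1

    def test_all_unreachable_gives_nan_sentinel(self):
        G = nx.Graph()
        G.add_node("t")
        G.add_node("z")
        M = TwoSidedModule(increased=frozenset({"z"}))
        rep = module_target_distance(M, TargetSet("d", frozenset({"t"})), G)
        assert math.isnan(rep.overall_mean)

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            G = nx.gnp_random_graph(50, 0.08, seed=int(rng.integers(2**31)))
            G = nx.relabel_nodes(G, {i: f"n{i}" for i in range(50)})
            nodes = sorted(G.nodes)
            targets = frozenset(rng.choice(nodes, 3, replace=False))
            genes = [g for g in rng.choice(nodes, 6, replace=False)
                     if g not in targets]
            M = TwoSidedModule(increased=frozenset(genes))
            rep = module_target_distance(M, TargetSet("d", targets), G)
            for g in genes:
                best = math.inf
                for t in targets:  # independent per-pair BFS
                    try:
                        best = min(best, nx.shortest_path_length(G, g, t))
                    except nx.NetworkXNoPath:
                        pass
                if math.isinf(best):
                    assert g not in rep.per_gene
                else:
                    assert rep.per_gene[g] == best

    def test_relabeling_invariance(self, path_network):
        M = TwoSidedModule(increased=frozenset({"b", "c"}))
        rep1 = module_target_distance(M, TargetSet("d", frozenset({"a"})),
                                      path_network)
        mapping = {"a": "A", "b": "B", "c": "C"}
        G2 = nx.relabel_nodes(path_network, mapping)
        M2 = TwoSidedModule(increased=frozenset({"B", "C"}))
        rep2 = module_target_distance(M2, TargetSet("d", frozenset({"A"})), G2)
        assert rep1.overall_mean == rep2.overall_mean


def toy_matrix():
    # samples: s_inc (increased gene only), s_dec, s_both, s_none, s_two_inc
    data = pd.DataFrame(
        {
            "s_inc": [1, 0, 0],
            "s_dec": [0, 1, 0],
            "s_both": [1, 1, 0],
            "s_none": [0, 0, 0],
            "s_two_inc": [1, 0, 1],
        },
        index=["gi", "gd", "gi2"], dtype="int8")
    return AlterationMatrix(data)


class TestAssignGroups:
    MODULE = TwoSidedModule(increased=frozenset({"gi", "gi2"}),
                            decreased=frozenset({"gd"}))

    def test_quoted_rule(self):
        gr = assign_groups(self.MODULE, toy_matrix())
        assert gr.labels == {
            "s_inc": "increased_only",
            "s_dec": "decreased_only",
            "s_both": "excluded",
            "s_none": "unaltered",
            "s_two_inc": "increased_only",
        }

    def test_partition_property(self):
        gr = assign_groups(self.MODULE, toy_matrix())
        assert set(gr.labels) == set(toy_matrix().samples)
        assert set(gr.labels.values()) <= {
            "increased_only", "decreased_only", "unaltered", "excluded"}

    def test_both_sides_fourth_group_toggle(self):
        gr = assign_groups(self.MODULE, toy_matrix(), both_sides_group=True)
        assert gr.labels["s_both"] == "both_sides"


class TestAnova:
    def test_equal_identical_groups_f_zero(self):
        gr = _grouped({"decreased_only": [1, 2, 3],
                       "increased_only": [1, 2, 3],
                       "unaltered": [1, 2, 3]})
        f, p = anova_three_group(gr)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_sum_of_squares_decomposition(self):
        groups = {"decreased_only": [0.0, 1.0],
                  "increased_only": [10.0, 11.0],
                  "unaltered": [20.0, 21.0]}
        f, p = anova_three_group(_grouped(groups))
        # independent SS decomposition
        allv = [v for g in groups.values() for v in g]
        grand = np.mean(allv)
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2
                         for g in groups.values())
        ss_within = sum((v - np.mean(g)) ** 2
                        for g in groups.values() for v in g)
        f_expected = (ss_between / 2) / (ss_within / 3)
        assert f == pytest.approx(f_expected, abs=1e-9)

    def test_insufficient_groups_sentinel(self):
        gr = _grouped({"unaltered": [1.0, 2.0]})
        f, p = anova_three_group(gr)
        assert math.isnan(f) and math.isnan(p)

    def test_min_group_size_excludes_singletons(self):
        gr = _grouped({"decreased_only": [1.0],
                       "increased_only": [1.0, 2.0],
                       "unaltered": [3.0, 4.0]})
        f, p = anova_three_group(gr)
        assert not math.isnan(f)  # two usable groups remain


def _grouped(groups):
    from netphix.evaluate import GroupedResponse

    labels, responses = {}, {}
    i = 0
    for name, vals in groups.items():
        for v in vals:
            labels[f"s{i}"] = name
            responses[f"s{i}"] = v
            i += 1
    return GroupedResponse(labels=labels, responses=responses)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])

    def test_hand_worked_step_up(self):
        qs = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(qs, [0.04, 0.04, 0.04, 0.04])
        qs2 = benjamini_hochberg([0.01, 0.04, 0.03, 0.02])
        # step-up on sorted [.01,.02,.03,.04] then mapped back
        np.testing.assert_allclose(qs2, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_bounded_and_order_preserving(self, ps):
        qs = benjamini_hochberg(ps)
        assert ((0 <= qs) & (qs <= 1)).all()
        order = np.argsort(ps)
        sorted_qs = qs[order]
        assert (np.diff(sorted_qs) >= -1e-12).all()


class TestDrugPairs:
    def test_opposite_direction_pair_reported(self):
        mods = {
            "afatinib_like": [TwoSidedModule(decreased=frozenset({"KRAS"}))],
            "selumetinib_like": [TwoSidedModule(increased=frozenset({"KRAS"}))],
        }
        pairs = suggest_drug_pairs(mods, min_shared=1)
        assert len(pairs) == 1
        assert pairs[0]["shared_genes"] == ["KRAS"]

    def test_same_direction_not_reported(self):
        mods = {
            "d1": [TwoSidedModule(increased=frozenset({"KRAS"}))],
            "d2": [TwoSidedModule(increased=frozenset({"KRAS"}))],
        }
        assert suggest_drug_pairs(mods) == []

    def test_no_shared_genes(self):
        mods = {
            "d1": [TwoSidedModule(increased=frozenset({"A"}))],
            "d2": [TwoSidedModule(decreased=frozenset({"B"}))],
        }
        assert suggest_drug_pairs(mods) == []

    def test_symmetric_in_pair(self):
        m1 = {"x": [TwoSidedModule(increased=frozenset({"G"}))],
              "y": [TwoSidedModule(decreased=frozenset({"G"}))]}
        m2 = {"y": [TwoSidedModule(decreased=frozenset({"G"}))],
              "x": [TwoSidedModule(increased=frozenset({"G"}))]}
        assert suggest_drug_pairs(m1) == suggest_drug_pairs(m2)

    def test_min_shared_threshold(self):
        mods = {
            "d1": [TwoSidedModule(increased=frozenset({"A", "B"}))],
            "d2": [TwoSidedModule(decreased=frozenset({"A"}))],
        }
        assert suggest_drug_pairs(mods, min_shared=2) == []
        assert len(suggest_drug_pairs(mods, min_shared=1)) == 1


class TestTargetSet:
    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            TargetSet("d", frozenset())
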