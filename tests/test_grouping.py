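"""Kappa similarity, iterative group merging and direction labels."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layerome.enrichment import EnrichmentResult
from layerome.grouping import (
    build_kappa_graph,
    kappa,
    label_and_direct,
    merge_groups,
)

REF10 = [f"g{i}" for i in range(1, 11)]


def _result(term_id, hits, p_bonf, pct_up, layer="cytoplasm"):
    return EnrichmentResult(
        term_id=term_id, term_name=term_id, source="GO_BP", layer=layer,
        x=len(hits), K=len(hits), n=10, N=100, p_raw=p_bonf / 10,
        p_bonferroni=p_bonf, hit_genes=tuple(sorted(hits)), pct_up=pct_up,
    )


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa({"g1", "g2"}, {"g1", "g2"}, REF10) == 1.0

    def test_hand_contingency_example(self):
        # a=2, b=2, c=2, d=4: po=0.6, pe=0.52 -> kappa = 1/6
        a = {"g1", "g2", "g3", "g4"}
        b = {"g3", "g4", "g5", "g6"}
        assert kappa(a, b, REF10) == pytest.approx(1 / 6)

    def test_perfect_disagreement(self):
        a = {"g1", "g2", "g3", "g4", "g5"}
        b = {"g6", "g7", "g8", "g9", "g10"}
        assert kappa(a, b, REF10) == pytest.approx(-1.0)

    def test_constant_membership_convention(self):
        # pe = 1 when both memberships are constant over the reference
        full = set(REF10)
        assert kappa(full, full, REF10) == 1.0
        assert kappa(set(), set(), REF10) == 1.0
        assert kappa(full, set(), REF10) == 0.0

    def test_symmetry_and_self_kappa(self, rng):
        ref = [f"g{i}" for i in range(20)]
        for _ in range(50):
            a = {ref[i] for i in rng.choice(20, rng.integers(1, 19), replace=False)}
            b = {ref[i] for i in rng.choice(20, rng.integers(1, 19), replace=False)}
            assert kappa(a, b, ref) == pytest.approx(kappa(b, a, ref))
            assert kappa(a, a, ref) == pytest.approx(1.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=st.sets(st.integers(0, 11), max_size=12),
        b=st.sets(st.integers(0, 11), max_size=12),
    )
    def test_kappa_properties_hold_for_arbitrary_memberships(self, a, b):
        ref = [f"g{i}" for i in range(12)]
        sa = {f"g{i}" for i in a}
        sb = {f"g{i}" for i in b}
        k = kappa(sa, sb, ref)
        assert -1.0 <= k <= 1.0
        assert k == pytest.approx(kappa(sb, sa, ref))
        if sa == sb:
            assert k == 1.0

    def test_reference_violation_rejected(self):
        with pytest.raises(ValueError):
            kappa({"zz"}, {"g1"}, REF10)
        with pytest.raises(ValueError):
            kappa({"g1"}, {"g1"}, ["g1"])


class TestKappaGraph:
    def test_identical_hit_sets_link_with_kappa_1(self):
        rs = [_result("T1", ["g1", "g2"], 0.01, 1.0), _result("T2", ["g1", "g2"], 0.02, 1.0)]
        g = build_kappa_graph(rs, REF10, 0.3)
        assert g.has_edge("T1", "T2")
        assert g["T1"]["T2"]["kappa"] == pytest.approx(1.0)

    @pytest.mark.parametrize("threshold,expect_edge", [(0.3, False), (0.1, True)])
    def test_threshold_is_strict(self, threshold, expect_edge):
        rs = [
            _result("T1", ["g1", "g2", "g3", "g4"], 0.01, 1.0),
            _result("T2", ["g3", "g4", "g5", "g6"], 0.02, 1.0),
        ]
        g = build_kappa_graph(rs, REF10, threshold)
        assert g.has_edge("T1", "T2") is expect_edge

    def test_reference_size_recorded(self):
        g = build_kappa_graph([], REF10, 0.3)
        assert g.graph["reference_size"] == 10


def _graph(edges, nodes=()):
    g = nx.Graph(reference_size=10)
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b, {"kappa": 0.9}) for a, b in edges)
    return g


class TestMerge:
    def test_share_rule_merges_overlapping_neighborhoods(self):
        # {T1,T2,T3} and {T2,T3,T4} share 2/3 >= 0.5 of the smaller
        g = _graph([("T1", "T2"), ("T1", "T3"), ("T2", "T4"), ("T3", "T4")])
        groups = merge_groups(g, 0.5)
        assert groups == [frozenset({"T1", "T2", "T3", "T4"})]

    def test_disconnected_cliques_stay_separate(self):
        g = _graph([("A1", "A2"), ("A1", "A3"), ("A2", "A3"),
                    ("B1", "B2"), ("B1", "B3"), ("B2", "B3")])
        groups = merge_groups(g, 0.5)
        assert groups == [frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2", "B3"})]

    def test_path_graph_collapses_to_one_group(self):
        # closed neighborhoods {T1,T2}, {T1,T2,T3}, {T2,T3} all pairwise
        # share >= half of the smaller -> single fixed-point group
        g = _graph([("T1", "T2"), ("T2", "T3")])
        groups = merge_groups(g, 0.5)
        assert groups == [frozenset({"T1", "T2", "T3"})]

    def test_singletons_form_their_own_groups(self):
        g = _graph([("T1", "T2")], nodes=["T9"])
        groups = merge_groups(g, 0.5)
        assert frozenset({"T9"}) in groups

    def test_fixed_point_no_residual_sharing(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"T{i:02d}" for i in range(n)})
            groups = merge_groups(g, 0.5)
            assert set().union(*groups) == set(g.nodes)
            for i, gi in enumerate(groups):
                for gj in groups[i + 1:]:
                    assert len(gi & gj) / min(len(gi), len(gj)) < 0.5

    def test_order_invariance(self, rng):
        edges = [("T3", "T1"), ("T1", "T5"), ("T5", "T2"), ("T2", "T4"), ("T4", "T6")]
        g1 = _graph(edges)
        g2 = _graph(list(reversed(edges)))
        assert merge_groups(g1, 0.5) == merge_groups(g2, 0.5)

    def test_share_threshold_validated(self):
        with pytest.raises(ValueError):
            merge_groups(_graph([]), 0.0)


class TestLabelAndDirect:
    def test_min_p_up_term_is_the_label(self):
        # two up terms, p_bonferroni 0.0250 and 0.0156: label is the smaller
        rs = [
            _result("GO:A", ["g1", "g2", "g3"], 0.025024, 1.0),
            _result("GO:B", ["g2", "g3", "g4"], 0.015571, 1.0),
        ]
        directions = {g: "up" for g in REF10}
        grp = label_and_direct(["GO:A", "GO:B"], rs, directions, "cytoplasm")
        assert grp.label_terms == ("GO:B",)
        assert grp.direction == "up"
        assert grp.leading_p_bonferroni == pytest.approx(0.015571)

    def test_term_typing_thresholds(self):
        rs = [
            _result("T_up", ["g1", "g2", "g3", "g4", "g5"], 0.01, 0.8),
            _result("T_mix", ["g4", "g5", "g6", "g7", "g8", "g9"], 0.02, 0.5),
        ]
        directions = {"g1": "up", "g2": "up", "g3": "up", "g4": "up", "g5": "down",
                      "g6": "down", "g7": "down", "g8": "up", "g9": "down"}
        grp = label_and_direct(["T_mix", "T_up"], rs, directions, "cytoplasm")
        # only T_up is direction-typed (0.8 >= 0.6); T_mix at 0.5 is mixed
        assert grp.label_terms == ("T_up",)

    def test_both_directions_labeled_when_both_exist(self):
        rs = [
            _result("T_up", ["g1", "g2"], 0.01, 1.0),
            _result("T_dn", ["g5", "g6"], 0.02, 0.0),
        ]
        directions = {"g1": "up", "g2": "up", "g5": "down", "g6": "down"}
        grp = label_and_direct(["T_dn", "T_up"], rs, directions, "nucleus")
        assert set(grp.label_terms) == {"T_up", "T_dn"}
        assert grp.direction == "mixed"  # pooled 2 up / 2 down

    def test_all_mixed_falls_back_to_most_significant(self):
        rs = [
            _result("T1", ["g1", "g2"], 0.04, 0.5),
            _result("T2", ["g3", "g4"], 0.01, 0.5),
        ]
        directions = {"g1": "up", "g2": "down", "g3": "up", "g4": "down"}
        grp = label_and_direct(["T1", "T2"], rs, directions, "cytoplasm")
        assert grp.label_terms == ("T2",)
        assert grp.direction == "mixed"

    def test_pooled_direction_uses_union_of_hits(self):
        # same gene in both terms counts once in the pooled set
        rs = [
            _result("T1", ["g1", "g2", "g3"], 0.01, 1.0),
            _result("T2", ["g1", "g2", "g4"], 0.02, 2 / 3),
        ]
        directions = {"g1": "up", "g2": "up", "g3": "up", "g4": "down"}
        grp = label_and_direct(["T1", "T2"], rs, directions, "cytoplasm")
        assert grp.direction == "up"  # pooled 3 up of 4 = 0.75 >= 0.6

    def test_unknown_member_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            label_and_direct(["nope"], [], {}, "cytoplasm")


def test_planted_disjoint_families_give_two_directed_groups():
    """Two disjoint planted term families: exactly two groups, each with its direction."""
    up_hits = ["g1", "g2", "g3", "g4"]
    dn_hits = ["g6", "g7", "g8", "g9"]
    rs = [
        _result("UP:1", up_hits, 0.001, 1.0),
        _result("UP:2", up_hits[:3] + ["g5"], 0.002, 1.0),
        _result("DN:1", dn_hits, 0.003, 0.0),
        _result("DN:2", dn_hits[:3] + ["g10"], 0.004, 0.0),
    ]
    directions = {g: "up" for g in ["g1", "g2", "g3", "g4", "g5"]}
    directions |= {g: "down" for g in ["g6", "g7", "g8", "g9", "g10"]}
    kgraph = build_kappa_graph(rs, REF10, 0.3)
    member_sets = merge_groups(kgraph, 0.5)
    assert len(member_sets) == 2
    groups = [label_and_direct(m, rs, directions, "cytoplasm") for m in member_sets]
    by_members = {g.members: g.direction for g in groups}
    assert by_members[("UP:1", "UP:2")] == "up"
    assert by_members[("DN:1", "DN:2")] == "down"
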