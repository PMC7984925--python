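import pytest

from qmnet.errors import ConfigError
from qmnet.model import CompoundTargetMap, GeneSetCollection
from qmnet.network import (
    HeteroNetwork,
    build_network,
    compound_degrees,
    ppi_summary,
    select_markers,
)
from qmnet.screening import intersect_with_disease


def make_screen(entries, disease=None):
    tmap = CompoundTargetMap(entries=entries)
    disease = disease if disease is not None else tmap.union()
    return intersect_with_disease(tmap, disease)


class TestHeteroNetwork:
    def test_rejects_self_edges_and_unknown_endpoints(self):
        net = HeteroNetwork()
        net.add_node("g1", "gene")
        with pytest.raises(ValueError, match="self-edge"):
            net.add_edge("g1", "g1")
        with pytest.raises(ValueError, match="not a declared node"):
            net.add_edge("g1", "missing")

    def test_rejects_untyped_node_pairs(self):
        net = HeteroNetwork()
        net.add_node("c1", "compound")
        net.add_node("c2", "compound")
        with pytest.raises(ValueError, match="no edge type"):
            net.add_edge("c1", "c2")

    def test_duplicate_edges_collapse(self):
        net = HeteroNetwork()
        net.add_node("c1", "compound")
        net.add_node("g1", "gene")
        net.add_edge("c1", "g1")
        net.add_edge("g1", "c1")
        assert net.n_edges == 1


class TestBuildNetwork:
    def test_toy_hand_enumeration(self):
        # 2 compounds {G1,G2}, {G2,G3}; 1 pathway {G1,G3}
        screen = make_screen({"c1": {"G1", "G2"}, "c2": {"G2", "G3"}})
        pathways = GeneSetCollection(sets={"p1": ("toy", {"G1", "G3"})})
        net = build_network(screen, pathways)
        # 1 rx + 2 compounds + 1 disease + 3 genes + 1 pathway
        assert net.n_nodes == 8
        # rx-compound 2 + compound-gene 4 + disease-gene 3 + pathway-gene 2
        assert net.n_edges == 11

    def test_empty_pipeline_gives_two_isolated_nodes(self):
        screen = make_screen({}, disease={"X"})
        net = build_network(screen, GeneSetCollection(sets={}))
        assert net.n_nodes == 2
        assert net.n_edges == 0
        assert sorted(t for _, t in net.nodes()) == ["disease", "prescription"]

    def test_node_count_identity(self, synthetic_study):
        from qmnet.pipeline import run_analysis

        screen, net, _, _ = run_analysis(
            synthetic_study.predicted_targets,
            synthetic_study.disease_genes,
            synthetic_study.pathways,
            degree_threshold_mode="fixed",
            fixed_degree_threshold=0,
        )
        n_pathways = len(net.nodes_of_type("pathway"))
        assert net.n_nodes == (
            len(screen.active_compounds) + len(screen.common_union()) + n_pathways + 2
        )

    def test_rejects_compound_with_empty_common_set(self):
        screen = make_screen({"c1": {"G1"}})
        screen.active_compounds = ["c1", "ghost"]
        screen.common_targets.entries["ghost"] = set()
        with pytest.raises(ValueError, match="empty common target set"):
            build_network(screen, GeneSetCollection(sets={}))

    def test_rejects_unrestricted_pathway_sets(self):
        screen = make_screen({"c1": {"G1"}})
        pathways = GeneSetCollection(sets={"p1": ("bad", {"G1", "FOREIGN"})})
        with pytest.raises(ValueError, match="restricted"):
            build_network(screen, pathways)

    def test_handshake_identity(self, reference_analysis, synthetic_study):
        from qmnet.pipeline import run_analysis

        nets = [reference_analysis.network]
        _, net, _, _ = run_analysis(
            synthetic_study.predicted_targets,
            synthetic_study.disease_genes,
            synthetic_study.pathways,
            degree_threshold_mode="computed_mean",
        )
        nets.append(net)
        for n in nets:
            assert sum(n.degree(v) for v, _ in n.nodes()) == 2 * n.n_edges


class TestCompoundDegrees:
    def test_degree_counts_gene_edges_only(self):
        screen = make_screen({"c1": {"G1", "G2"}})
        net = build_network(screen, GeneSetCollection(sets={}))
        # full degree includes the prescription edge; screening degree must not
        assert net.degree("c1") == 3
        assert compound_degrees(net)["c1"] == 2

    def test_isolated_compound_has_degree_zero(self):
        net = HeteroNetwork()
        net.add_node("c1", "compound")
        assert compound_degrees(net) == {"c1": 0}

    def test_reference_degrees_match_recorded_column(self, reference_analysis):
        recorded = reference_analysis.profile.predicted_targets.recorded_degrees
        degrees = reference_analysis.degrees
        assert all(degrees[cid] == recorded[cid] for cid in recorded)


class TestSelectMarkers:
    DEGREES = {"a": 5, "b": 12, "c": 13, "d": 13, "e": 1}

    def test_fixed_threshold_strict_comparison(self):
        sel = select_markers(self.DEGREES, "fixed", 12)
        assert sel.selected == ["c", "d"]  # 12 is not > 12
        assert sel.rejected == ["b", "a", "e"]

    def test_ordering_degree_desc_then_alphabetical(self):
        sel = select_markers(self.DEGREES, "fixed", 0)
        assert sel.selected == ["c", "d", "b", "a", "e"]

    def test_computed_mean_uses_full_network(self):
        screen = make_screen({"c1": {"G1", "G2"}, "c2": {"G3"}})
        net = build_network(screen, GeneSetCollection(sets={}))
        sel = select_markers(compound_degrees(net), "computed_mean", net=net)
        assert sel.threshold_used == pytest.approx(2 * net.n_edges / net.n_nodes)

    def test_monotone_in_threshold(self):
        prev = None
        for thr in (0, 2, 5, 12, 13, 100):
            sel = set(select_markers(self.DEGREES, "fixed", thr).selected)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_fixed_mode_without_value_is_config_error(self):
        with pytest.raises(ConfigError):
            select_markers(self.DEGREES, "fixed", None)

    def test_recovers_planted_markers_exactly(self, synthetic_study):
        from qmnet.pipeline import run_analysis

        p = synthetic_study.params
        thr = (p.marker_target_count + p.nonmarker_target_count) / 2
        _, _, _, sel = run_analysis(
            synthetic_study.predicted_targets,
            synthetic_study.disease_genes,
            synthetic_study.pathways,
            degree_threshold_mode="fixed",
            fixed_degree_threshold=thr,
        )
        assert set(sel.selected) == synthetic_study.truth.planted_markers


class TestPpiSummary:
    def test_dedup_and_self_loop_drop(self):
        with pytest.warns(UserWarning, match="self-loop"):
            s = ppi_summary([("A", "B"), ("B", "A"), ("B", "C"), ("C", "C")])
        assert (s.n_nodes, s.n_edges) == (3, 2)
        assert sum(f for _, f in s.top_genes) == 2 * s.n_edges

    def test_empty_list(self):
        s = ppi_summary([])
        assert (s.n_nodes, s.n_edges, s.top_genes) == (0, 0, [])

    def test_star_graph_center_frequency(self):
        edges = [("HUB", f"L{i}") for i in range(4)]
        s = ppi_summary(edges, top_k=1)
        assert s.top_genes == [("HUB", 4)]
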