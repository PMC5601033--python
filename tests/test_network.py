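"""PDN construction, simplification rules and export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pepnet import (
    Annotation,
    Composition,
    PeakList,
    build_pdn,
    composition_mass,
    correlation_filter,
    delta_aa,
    drop_free_amino_acids,
    export_network,
    read_network,
    remove_isolated,
    spearman_rho,
    triangle_reduce,
)
from conftest import make_uaac_annotations

C = Composition.from_string


class TestDeltaAA:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("T1L2E1", "T1L1", "L1E1"),
            ("A2P2", "P2", "A2"),
            ("P1V2L2", "P1V1L2", "V1"),
        ],
    )
    def test_entirely_positive_differences(self, a, b, expected):
        assert delta_aa(C(a), C(b)) == C(expected)

    def test_negative_component_gives_none(self):
        assert delta_aa(C("P2"), C("A2P2")) is None

    def test_equal_compositions_give_none(self):
        assert delta_aa(C("P2"), C("P2")) is None

    def test_mixed_sign_gives_none(self):
        assert delta_aa(C("A1L1"), C("A2")) is None


def _dominance_pairs(comps):
    """Brute-force oracle: every ordered pair with entirely positive delta."""
    return {
        (i, j)
        for i, j in itertools.permutations(range(len(comps)), 2)
        if delta_aa(comps[i], comps[j]) is not None
    }


class TestBuildPDN:
    def test_four_node_chain_gives_six_edges(self, a19):
        comps = [C("P1V2L2"), C("P1V1L2"), C("P1V1L1"), C("P1V1")]
        anns = make_uaac_annotations(comps, a19)
        g = build_pdn(anns, compute_rho=False)
        assert g.number_of_edges() == 6  # all dominance pairs of a nested chain

    def test_incomparable_nodes_get_no_edge(self, a19):
        g = build_pdn(make_uaac_annotations([C("A1"), C("G1")], a19), compute_rho=False)
        assert g.number_of_edges() == 0

    def test_a2p2_family(self, a19):
        anns = make_uaac_annotations([C("A2P2"), C("P2"), C("A2")], a19)
        g = build_pdn(anns, compute_rho=False)
        ids = {a.compositions[0]: a.peak_id for a in anns}
        assert set(g.edges) == {
            (ids[C("A2P2")], ids[C("P2")]),
            (ids[C("A2P2")], ids[C("A2")]),
        }
        assert g.edges[ids[C("A2P2")], ids[C("P2")]]["delta"] == C("A2")

    def test_maap_and_none_peaks_excluded(self, a19):
        anns = make_uaac_annotations([C("A2P2")], a19)
        anns.append(Annotation("maap", 500.0, (C("A1"), C("G1")), (0.0, 0.0)))
        anns.append(Annotation("none", 40.0, (), ()))
        g = build_pdn(anns, compute_rho=False)
        assert set(g.nodes) == {anns[0].peak_id}

    def test_edges_match_bruteforce_on_random_graphs(self, a17):
        rng = np.random.default_rng(21)
        for _ in range(5):
            comps = list(
                {
                    Composition(
                        {
                            s: int(c)
                            for s, c in zip(*np.unique(
                                rng.choice(a17.symbols[:8], size=rng.integers(1, 6)),
                                return_counts=True,
                            ))
                        }
                    )
                    for _ in range(60)
                }
            )
            anns = make_uaac_annotations(comps, a17)
            g = build_pdn(anns, compute_rho=False)
            want = _dominance_pairs(comps)
            got = {
                (comps.index(g.nodes[u]["composition"]), comps.index(g.nodes[v]["composition"]))
                for u, v in g.edges
            }
            assert got == want
            assert nx.is_directed_acyclic_graph(g)

    def test_isomers_are_distinct_unlinked_nodes(self, a19):
        comp = C("A1P1")
        mass = composition_mass(comp, a19)
        anns = [
            Annotation("rt1", mass, (comp,), (0.0,)),
            Annotation("rt2", mass, (comp,), (0.0,)),
        ]
        g = build_pdn(anns, compute_rho=False)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0

    def test_delta_additivity_along_paths(self, a17):
        rng = np.random.default_rng(9)
        comps = list(
            {
                Composition(
                    {
                        s: int(c)
                        for s, c in zip(*np.unique(
                            rng.choice(a17.symbols[:6], size=rng.integers(1, 7)),
                            return_counts=True,
                        ))
                    }
                )
                for _ in range(40)
            }
        )
        g = build_pdn(make_uaac_annotations(comps, a17), compute_rho=False)
        for source in list(g.nodes)[:10]:
            for target in nx.descendants(g, source):
                path = nx.shortest_path(g, source, target)
                total = None
                for u, v in zip(path, path[1:]):
                    d = g.edges[u, v]["delta"]
                    total = d if total is None else total.add(d)
                assert total == delta_aa(
                    g.nodes[source]["composition"], g.nodes[target]["composition"]
                )


class TestSimplifications:
    def test_remove_isolated(self, a19):
        anns = make_uaac_annotations([C("A2P2"), C("P2"), C("W1Y1")], a19)
        g = build_pdn(anns, compute_rho=False)
        g2 = remove_isolated(g)
        assert g2.number_of_nodes() == 2
        assert g2.number_of_edges() == g.number_of_edges()

    def test_remove_isolated_on_edgeless_graph(self, a19):
        g = build_pdn(make_uaac_annotations([C("A1"), C("G1")], a19), compute_rho=False)
        assert remove_isolated(g).number_of_nodes() == 0

    def test_triangle_rule_deletes_shortcut(self):
        g = nx.DiGraph()
        for u, v in [("T1L2E1", "T1L1"), ("T1L1", "L1"), ("T1L2E1", "L1")]:
            g.add_edge(u, v, delta=delta_aa(C(u), C(v)))
        g2 = triangle_reduce(g)
        assert ("T1L2E1", "L1") not in g2.edges
        assert g2.number_of_edges() == 2

    def test_chain_reduces_to_consecutive_edges(self, a19):
        comps = [C("P1V2L2"), C("P1V1L2"), C("P1V1L1"), C("P1V1")]
        g = build_pdn(make_uaac_annotations(comps, a19), compute_rho=False)
        g2 = triangle_reduce(g)
        assert g2.number_of_edges() == 3
        labels = sorted(d["delta"].to_string(a19) for _, _, d in g2.edges(data=True))
        assert labels == ["L1", "L1", "V1"]

    def test_triangle_free_graph_unchanged(self):
        g = nx.DiGraph([("a", "b"), ("c", "d")])
        assert set(triangle_reduce(g).edges) == set(g.edges)

    def test_triangle_reduce_preserves_reachability(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.15:
                        g.add_edge(i, j)
            reduced = triangle_reduce(g)
            assert set(nx.transitive_closure(reduced).edges) == set(
                nx.transitive_closure(g).edges
            )

    def test_drop_free_amino_acids(self, a19):
        comps = [C("L1"), C("L1R1"), C("L1R1P1")]
        anns = make_uaac_annotations(comps, a19)
        g = build_pdn(anns, compute_rho=False)
        g2 = drop_free_amino_acids(g)
        assert all(g2.nodes[n]["composition"].length >= 2 for n in g2.nodes)
        assert g2.number_of_nodes() == 2 and g2.number_of_edges() == 1

    def test_drop_free_aa_empty_result(self, a19):
        g = build_pdn(make_uaac_annotations([C("A1"), C("G1")], a19), compute_rho=False)
        assert drop_free_amino_acids(g).number_of_nodes() == 0


class TestSpearman:
    def test_self_correlation_is_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_perfect_inversion(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # ranks of y are (1,3,2,5,4): sum of squared rank differences is 4,
        # so rho = 1 - 6*4 / (5*(25-1)) = 0.8
        assert spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_symmetry(self):
        x, y = [1.0, 5.0, 2.0, 8.0], [2.0, 3.0, 9.0, 1.0]
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x))

    def test_too_few_pairs_undefined(self):
        assert np.isnan(spearman_rho([1, 2], [3, 4]))

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_missing_pairs_dropped(self):
        x = [1, 2, np.nan, 4, 5]
        y = [1, 2, 3, 4, 5]
        assert spearman_rho(x, y) == pytest.approx(1.0)


def _graph_with_profiles(a19, profiles):
    comps = [C("A2P2"), C("A1P1"), C("A1")]
    anns = make_uaac_annotations(comps, a19)
    ids = [a.peak_id for a in anns]
    intens = pd.DataFrame(profiles, index=ids, columns=[f"s{i}" for i in range(len(profiles[0]))])
    peaks = PeakList(ids, [a.neutral_mass for a in anns], intens)
    return build_pdn(anns, peaks)


class TestCorrelationFilter:
    def test_threshold_is_inclusive(self, a19):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        g = _graph_with_profiles(a19, [np.exp(base), np.exp(base), np.exp(rng.normal(size=8))])
        edges = list(g.edges(data=True))
        perfect = [(u, v) for u, v, d in edges if d["rho"] == pytest.approx(1.0)]
        g2 = correlation_filter(g, 1.0)
        assert set(g2.edges) == set(perfect)

    def test_minus_one_keeps_all_defined(self, a19):
        rng = np.random.default_rng(1)
        g = _graph_with_profiles(a19, list(np.exp(rng.normal(size=(3, 10)))))
        g2 = correlation_filter(g, -1.0)
        assert g2.number_of_edges() == g.number_of_edges()

    def test_undefined_rho_removed_by_default(self, a19):
        g = _graph_with_profiles(
            a19, [np.ones(5), np.arange(1.0, 6.0), np.arange(2.0, 7.0)]
        )
        const_node = [n for n in g.nodes if np.all(g.nodes[n]["intensity"] == 1.0)][0]
        g2 = correlation_filter(g, -1.0)
        assert all(const_node not in e for e in g2.edges)
        g3 = correlation_filter(g, -1.0, keep_undefined=True)
        assert g3.number_of_edges() == g.number_of_edges()

    def test_monotone_in_threshold(self, a19):
        rng = np.random.default_rng(2)
        g = _graph_with_profiles(a19, list(np.exp(rng.normal(size=(3, 12)))))
        for t1, t2 in [(-0.5, 0.0), (0.0, 0.5), (0.5, 0.9)]:
            assert set(correlation_filter(g, t2).edges) <= set(
                correlation_filter(g, t1).edges
            )


class TestExport:
    def test_round_trip_preserves_structure_and_labels(self, tmp_path, a19):
        rng = np.random.default_rng(8)
        g = _graph_with_profiles(a19, list(np.exp(rng.normal(size=(3, 10)))))
        export_network(g, tmp_path, alphabet=a19, graphml=True)
        back = read_network(tmp_path)
        assert set(back.nodes) == set(map(str, g.nodes))
        assert set(back.edges) == {(str(u), str(v)) for u, v in g.edges}
        for u, v in g.edges:
            assert back.edges[str(u), str(v)]["delta"] == g.edges[u, v]["delta"]
            assert back.edges[str(u), str(v)]["rho"] == pytest.approx(
                g.edges[u, v]["rho"], abs=1e-6
            )
        for n in g.nodes:
            assert back.nodes[str(n)]["composition"] == g.nodes[n]["composition"]
        assert (tmp_path / "pdn.graphml").exists()

    def test_empty_graph_gives_header_only_files(self, tmp_path):
        paths = export_network(nx.DiGraph(), tmp_path)
        assert paths["edges"].read_text().count("\n") == 1
        assert paths["nodes"].read_text().count("\n") == 1

    def test_edge_file_has_one_row_per_edge(self, tmp_path, a19):
        comps = [C("A2P2"), C("P2"), C("A2")]
        g = build_pdn(make_uaac_annotations(comps, a19), compute_rho=False)
        paths = export_network(g, tmp_path, alphabet=a19)
        assert paths["edges"].read_text().count("\n") == 1 + 2
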