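"""Transition-network construction and syntax metrics."""

import math

import networkx as nx
import numpy as np
import pytest

from songsyntax import (
    average_path_length,
    build_syllable_network,
    network_density,
    network_metrics_for_study,
)
from songsyntax.network import SyllableNetwork, to_directed_multigraph

from _oracles import floyd_warshall_metrics, random_graph
from conftest import make_corpus


def net_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from((u, v, {"count": 1}) for u, v in edges)
    return SyllableNetwork(graph=g)


def test_build_network_bridges_song_breaks():
    # concatenated string A,A,B,A,C: the B->A transition spans the song break
    corpus = make_corpus([["A", "A", "B"], ["A", "C"]])
    net = build_syllable_network(corpus)
    assert net.nodes == {"A", "B", "C"}
    assert net.edge_counts == {frozenset({"A", "B"}): 2, frozenset({"A", "C"}): 1}
    assert net.self_loop_counts == {"A": 1}
    assert net.total_transitions == 4


def test_build_network_degenerate_cases():
    single = build_syllable_network(make_corpus([["A"]]))
    assert single.nodes == {"A"}
    assert single.graph.number_of_edges() == 0
    assert single.total_transitions == 0

    repeats = build_syllable_network(make_corpus([["A", "A", "A"]]))
    assert repeats.self_loop_counts == {"A": 2}
    assert repeats.graph.number_of_edges() == 0


def test_average_path_length_examples():
    complete3 = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
    assert average_path_length(complete3) == 1.0
    star = net_from_edges([("hub", "x"), ("hub", "y"), ("hub", "z")])
    assert average_path_length(star) == 1.5  # 3 pairs at 1, 3 at 2
    disjoint = net_from_edges([("a", "b"), ("c", "d")])
    assert average_path_length(disjoint) == 1.0  # unreachable pairs excluded


def test_average_path_length_undefined_without_reachable_pairs():
    g = nx.Graph()
    g.add_nodes_from(["a", "b", "c"])
    assert math.isnan(average_path_length(SyllableNetwork(graph=g)))


def test_density_examples():
    complete4 = net_from_edges(
        [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
    )
    assert network_density(complete4) == 1.0
    path4 = net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
    assert network_density(path4) == 0.5
    # self-loops count as transitions but not as density edges
    net = build_syllable_network(make_corpus([["A", "A", "B"]]))
    assert network_density(net) == 1.0
    assert net.total_transitions == 2


def test_density_undefined_below_two_nodes():
    net = build_syllable_network(make_corpus([["A"]]))
    assert math.isnan(network_density(net))


def test_study_exclusion_rule_boundary():
    three_types = make_corpus([["A", "B", "C", "A", "B"]] * 3, bird_id="small")
    four_types = make_corpus([["A", "B", "C", "D", "A"]] * 3, bird_id="big", sex="female")
    table, excluded = network_metrics_for_study([three_types, four_types])
    assert excluded == ["small"]
    small_row = table.set_index("bird_id").loc["small"]
    assert math.isnan(small_row["network_path_length"]) and math.isnan(small_row["network_density"])
    big_row = table.set_index("bird_id").loc["big"]
    assert big_row["network_path_length"] >= 1.0
    assert 0.0 <= big_row["network_density"] <= 1.0


def test_study_empty_input_gives_empty_table():
    table, excluded = network_metrics_for_study([])
    assert table.empty and excluded == []


def test_metrics_match_floyd_warshall_oracle_on_random_graphs():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(100):
        n, edges = random_graph(rng)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((u, v, {"count": 1}) for u, v in edges)
        net = SyllableNetwork(graph=g)
        apl_o, dens_o = floyd_warshall_metrics(n, edges)
        apl = average_path_length(net)
        if math.isnan(apl_o):
            assert math.isnan(apl)
        else:
            assert apl == pytest.approx(apl_o)
            checked += 1
        assert network_density(net) == pytest.approx(dens_o)
    assert checked > 50  # most random graphs have reachable pairs


def test_path_length_one_iff_all_reachable_pairs_adjacent():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n, edges = random_graph(rng, max_nodes=6)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((u, v, {"count": 1}) for u, v in edges)
        net = SyllableNetwork(graph=g)
        apl = average_path_length(net)
        if math.isnan(apl):
            continue
        assert apl >= 1.0
        comps = [c for c in nx.connected_components(g) if len(c) > 1]
        all_adjacent = all(
            g.has_edge(u, v) for c in comps for u in c for v in c if u != v
        )
        assert (apl == 1.0) == all_adjacent


def test_directed_export_keeps_transition_frequencies():
    corpus = make_corpus([["A", "A", "B"], ["A", "C"]])
    g = to_directed_multigraph(corpus)
    assert g["A"]["A"]["count"] == 1
    assert g["A"]["B"]["count"] == 1
    assert g["B"]["A"]["count"] == 1
    assert g.nodes["A"]["usage"] == 3


def test_stereotypy_raises_path_length_and_lowers_density():
    """The transition-stereotypy axis moves the network metrics in the
    direction of the male-female syntax contrast."""
    from dataclasses import replace

    from songsyntax import generate_bird_corpus, male_default_params

    base = replace(male_default_params(), repertoire_jitter_sd=0.0, phrase_jitter_sd=0.0)
    apls, denss = [], []
    for ster in (0.1, 0.5, 0.9):
        vals_a, vals_d = [], []
        for seed in range(5):
            c = generate_bird_corpus(replace(base, stereotypy=ster), "b", "male", "T", seed=seed)
            net = build_syllable_network(c)
            vals_a.append(average_path_length(net))
            vals_d.append(network_density(net))
        apls.append(np.mean(vals_a))
        denss.append(np.mean(vals_d))
    assert apls[0] < apls[1] < apls[2]
    assert denss[0] > denss[1] > denss[2]
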