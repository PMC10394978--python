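"""Syllable-transition networks and their syntax metrics.

For each bird the syllable strings of its analyzed songs are concatenated in
recording order into one sequence; every adjacent pair of syllable types is a
first-order transition (song breaks are deliberately bridged to avoid
fragmenting small networks).  Nodes are syllable types; an undirected edge
joins two distinct types that ever follow one another, weighted by how often;
immediate repeats of a type are kept as self-loop counts.

Two metrics summarize how constrained the transition structure is:

* **average path length** — mean shortest-path length (in edges, unweighted)
  over all mutually reachable node pairs; higher values mean syllable types
  are strung along fixed routes (more linear, stereotyped syntax);
* **network density** — observed edges over possible edges
  ``n * (n - 1) / 2`` of the simple graph (self-loops excluded on both
  sides); higher values mean a larger share of possible transitions is used
  (more flexible syntax).

Networks with three or fewer syllable types carry too few node pairs for
either metric to be meaningful and are excluded from study-level analyses.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .types import BirdCorpus

#: birds whose network has at most this many nodes get no network metrics
DEFAULT_EXCLUSION_THRESHOLD = 3


@dataclass
class SyllableNetwork:
    """Undirected weighted graph of syllable-type transitions for one bird."""

    graph: nx.Graph
    self_loop_counts: dict[str, int] = field(default_factory=dict)
    bird_id: str | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_counts(self) -> dict[frozenset, int]:
        return {frozenset((u, v)): d["count"] for u, v, d in self.graph.edges(data=True)}

    @property
    def total_transitions(self) -> int:
        return sum(d["count"] for _, _, d in self.graph.edges(data=True)) + sum(
            self.self_loop_counts.values()
        )


def transition_counts(labels: Sequence[str]) -> tuple[Counter, Counter, Counter]:
    """Directed bigram, undirected pair and self-loop counts of a label string."""
    directed: Counter = Counter()
    undirected: Counter = Counter()
    loops: Counter = Counter()
    for a, b in itertools.pairwise(labels):
        directed[(a, b)] += 1
        if a == b:
            loops[a] += 1
        else:
            undirected[frozenset((a, b))] += 1
    return directed, undirected, loops


def build_syllable_network(corpus: BirdCorpus) -> SyllableNetwork:
    """One transition network from the concatenated syllable string of all songs."""
    labels = [lab for song in corpus.songs for lab in song.labels]
    usage = Counter(labels)
    _, undirected, loops = transition_counts(labels)
    g = nx.Graph()
    for lab, n in usage.items():
        g.add_node(lab, usage=n)
    for pair, n in undirected.items():
        u, v = sorted(pair)
        g.add_edge(u, v, count=n)
    return SyllableNetwork(graph=g, self_loop_counts=dict(loops), bird_id=corpus.bird_id)


def average_path_length(net: SyllableNetwork) -> float:
    """Mean shortest-path length over mutually reachable node pairs.

    Edges are unweighted; self-loops cannot shorten a path and are ignored;
    unreachable pairs are left out of the average.  ``nan`` when no pair of
    distinct nodes is connected.
    """
    g = net.graph
    total = 0
    n_pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())  # counts ordered pairs, d(i,i)=0
            n_pairs += len(dists) - 1
    if n_pairs == 0:
        return math.nan
    return total / n_pairs


def network_density(net: SyllableNetwork) -> float:
    """Observed over possible edges of the simple graph; ``nan`` if < 2 nodes."""
    n = net.n_nodes
    if n < 2:
        return math.nan
    return net.graph.number_of_edges() / (n * (n - 1) / 2)


def network_metrics_for_study(
    corpora: Iterable[BirdCorpus],
    exclusion_threshold: int = DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-bird network metrics with the small-network exclusion applied.

    Birds whose network has at most ``exclusion_threshold`` nodes receive
    ``nan`` for both metrics.  Returns the table (bird_id, n_nodes,
    network_path_length, network_density) and the excluded bird ids.
    """
    rows = []
    excluded: list[str] = []
    for corpus in corpora:
        net = build_syllable_network(corpus)
        if net.n_nodes <= exclusion_threshold:
            excluded.append(corpus.bird_id)
            apl = dens = math.nan
        else:
            apl = average_path_length(net)
            dens = network_density(net)
        rows.append(
            {
                "bird_id": corpus.bird_id,
                "n_nodes": net.n_nodes,
                "network_path_length": apl,
                "network_density": dens,
            }
        )
    return pd.DataFrame(rows, columns=["bird_id", "n_nodes", "network_path_length", "network_density"]), excluded


def to_directed_multigraph(corpus: BirdCorpus) -> nx.DiGraph:
    """Directed, frequency-weighted transition graph (visualization form).

    Node attribute ``usage`` is how often the type occurs; edge attribute
    ``count`` the directed transition frequency (self-transitions included).
    """
    labels = [lab for song in corpus.songs for lab in song.labels]
    directed, _, _ = transition_counts(labels)
    g = nx.DiGraph()
    for lab, n in Counter(labels).items():
        g.add_node(lab, usage=n)
    for (a, b), n in directed.items():
        g.add_edge(a, b, count=n)
    return g


def export_graphml(corpus: BirdCorpus, path: str | Path, directed: bool = False) -> None:
    """Write one bird's transition network as GraphML.

    Metrics are always computed on the undirected simple graph; the directed
    variant only mirrors how such networks are customarily drawn (arrows,
    transition frequencies).
    """
    if directed:
        g = to_directed_multigraph(corpus)
    else:
        g = build_syllable_network(corpus).graph
    nx.write_graphml(g, str(path))
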