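"""Protein-level interaction graph, negative-pair generation, leakage-free split.

Positive pairs are heterodimers with at least one residue-level contact.
Negative pairs are generated on the positive interaction graph by a greedy
degree-matching procedure: repeatedly take the vertex with the largest
remaining working degree and pair it with a non-adjacent vertex of maximal
remaining degree, preferring partners far away in the graph. The resulting
negative set has the same protein composition as the positive set and, per
vertex, never more negative than positive interactions — a classifier
trained on it must learn pair compatibility, not single-protein reactivity.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import networkx as nx

from .structure_io import ContactMap

Pair = tuple[str, str]
LabeledPair = tuple[str, str, int]


def _norm(a: str, b: str) -> Pair:
    """Canonical (sorted) form of an unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionGraph:
    """Undirected protein interaction graph with a working degree vector."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[Pair]:
        return {_norm(u, v) for u, v in self.graph.edges}

    def degree(self, v: str) -> int:
        return self.graph.degree(v)


def build_positive_graph(contact_maps: list[ContactMap]) -> InteractionGraph:
    """Edges between distinct chains linked by at least one residue contact."""
    g = nx.Graph()
    for cmap in contact_maps:
        a, b = cmap.chain_a_id, cmap.chain_b_id
        g.add_nodes_from([a, b])
        if cmap.contacts and a != b:
            g.add_edge(a, b)
    g.remove_edges_from(nx.selfloop_edges(g))
    return InteractionGraph(g)


def graph_from_edges(pairs: list[Pair] | list[LabeledPair]) -> InteractionGraph:
    """Interaction graph from an edge list (self-loops dropped)."""
    g = nx.Graph()
    for pair in pairs:
        a, b = pair[0], pair[1]
        g.add_nodes_from([a, b])
        if a != b:
            g.add_edge(a, b)
    return InteractionGraph(g)


def generate_negatives(g1: InteractionGraph) -> set[Pair]:
    """Greedy degree-matched negative pairs, disjoint from the positive edges.

    Loop until no working degree remains:

    1. pick v with the largest Deg(v) (ties: lexicographically smallest id);
    2. among u != v with Deg(u) > 0, (v, u) not a positive edge and not
       already generated, pick the one with the largest Deg(u), then the
       largest graph distance d(u, v) in the positive graph (disconnected
       counts as infinite), then the lexicographically smallest id;
    3. if such u exists, record (v, u) and decrement both degrees, otherwise
       zero Deg(v).
    """
    g = g1.graph
    if g.number_of_nodes() < 2:
        return set()
    deg = {v: g.degree(v) for v in g.nodes}
    positive = {_norm(u, v) for u, v in g.edges}
    negatives: set[Pair] = set()

    while True:
        active = [v for v in deg if deg[v] > 0]
        if not active:
            break
        v = min(active, key=lambda x: (-deg[x], x))
        dist = nx.single_source_shortest_path_length(g, v)
        best = None
        best_key = None
        for u in g.nodes:
            if u == v or deg[u] <= 0:
                continue
            pair = _norm(v, u)
            if pair in positive or pair in negatives:
                continue
            d = dist.get(u, math.inf)
            key = (-deg[u], -d, u)
            if best is None or key < best_key:
                best, best_key = u, key
        if best is None:
            deg[v] = 0
        else:
            negatives.add(_norm(v, best))
            deg[v] -= 1
            deg[best] -= 1
    return negatives


def leakage_free_split(
    pairs: list[LabeledPair], test_fraction: float, seed: int,
) -> tuple[list[LabeledPair], list[LabeledPair], dict]:
    """Split labelled pairs at the protein level.

    Proteins are partitioned at random; a pair is a training pair iff both
    members are training proteins, a test pair iff both are test proteins,
    and discarded (counted in the report) if it straddles the partition.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    proteins = sorted({p for a, b, _ in pairs for p in (a, b)})
    rng = random.Random(seed)
    rng.shuffle(proteins)
    n_test = round(len(proteins) * test_fraction)
    test_set = set(proteins[:n_test])
    train_set = set(proteins[n_test:])

    train, test, discarded = [], [], 0
    for a, b, label in pairs:
        if a in train_set and b in train_set:
            train.append((a, b, label))
        elif a in test_set and b in test_set:
            test.append((a, b, label))
        else:
            discarded += 1
    report = {
        "n_train_proteins": len(train_set),
        "n_test_proteins": len(test_set),
        "n_train_pairs": len(train),
        "n_test_pairs": len(test),
        "n_discarded_pairs": discarded,
    }
    return train, test, report


def read_edge_list(path) -> list[LabeledPair]:
    """Read TSV ``protein_a<TAB>protein_b[<TAB>label]`` (default label 1)."""
    out: list[LabeledPair] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            label = int(parts[2]) if len(parts) > 2 else 1
            out.append((parts[0], parts[1], label))
    return out


def write_edge_list(pairs: list[LabeledPair], path) -> None:
    with open(path, "w") as fh:
        for a, b, label in pairs:
            fh.write(f"{a}\t{b}\t{label}\n")
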