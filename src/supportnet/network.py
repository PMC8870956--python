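"""Sentence-window word co-occurrence network construction and export.

The network G = (V, E) is undirected: nodes are word types, and an edge
joins two words that co-occur in at least one sentence. The default edge
weight w_ij counts the number of sentences in which the pair co-occurs
(binary incidence per sentence); an optional multiplicity mode counts
within-sentence occurrence pairs instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import networkx as nx

from .corpus import TokenizedSentence
from .errors import EmptyInputError, UsageError

__all__ = ["CooccurrenceNetwork", "build_network", "export_network", "read_tsv_edges"]


@dataclass
class CooccurrenceNetwork:
    """Undirected weighted word co-occurrence graph.

    Wraps a :class:`networkx.Graph` whose nodes are word strings and whose
    edges carry a positive integer ``weight``. Degree-0 nodes (words that
    never co-occur with another word) are retained: they count toward n and
    toward clustering-coefficient averaging.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n(self) -> int:
        """Number of nodes |V|."""
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        """Number of edges |E|."""
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> int:
        return self.graph[u][v]["weight"]

    def total_weight(self) -> int:
        """Sum of edge weights (the M = ½ΣΣ w_ij normalizer of modularity)."""
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def validate(self) -> None:
        """Assert structural invariants: no self-loops, integer weights ≥ 1."""
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            w = d.get("weight")
            if not isinstance(w, int) or w < 1:
                raise ValueError(f"edge ({u!r}, {v!r}) has invalid weight {w!r}")


def build_network(
    sentences: Iterable[TokenizedSentence],
    count_multiplicity: bool = False,
) -> CooccurrenceNetwork:
    """Build the co-occurrence network from tokenized sentences.

    Every unordered pair of *distinct* token types within a sentence
    contributes +1 to that pair's weight (the sentence-incidence convention).
    With ``count_multiplicity=True`` the contribution is the product of the
    two types' occurrence counts in the sentence instead. Sentences with
    zero or one token add nodes but no edges; an entirely empty corpus is an
    error.
    """
    graph = nx.Graph()
    saw_sentence = False
    for sent in sentences:
        saw_sentence = True
        tokens = sent.tokens
        if not tokens:
            continue
        graph.add_nodes_from(set(tokens))
        if count_multiplicity:
            counts: dict[str, int] = {}
            for t in tokens:
                counts[t] = counts.get(t, 0) + 1
            items = sorted(counts)
            for a, b in combinations(items, 2):
                inc = counts[a] * counts[b]
                _bump(graph, a, b, inc)
        else:
            for a, b in combinations(sorted(set(tokens)), 2):
                _bump(graph, a, b, 1)
    if not saw_sentence:
        raise EmptyInputError("cannot build a network from an empty corpus")
    return CooccurrenceNetwork(graph=graph)


def _bump(graph: nx.Graph, a: str, b: str, inc: int) -> None:
    if graph.has_edge(a, b):
        graph[a][b]["weight"] += inc
    else:
        graph.add_edge(a, b, weight=inc)


def export_network(net: CooccurrenceNetwork, path: str | Path, format: str) -> None:
    """Write the network to ``path`` in GEXF, GraphML or TSV edge-list form.

    Exports are deterministic: nodes and edges are written in lexicographic
    order. Node labels are the words themselves; weights are preserved as a
    numeric edge attribute. The TSV dialect is ``word1<TAB>word2<TAB>weight``
    with a header line (degree-0 nodes are listed with an empty partner).
    """
    path = Path(path)
    if format not in ("gexf", "graphml", "tsv"):
        raise UsageError(f"unknown export format {format!r}")

    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(net.graph.nodes()))
    for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges()):
        ordered.add_edge(u, v, weight=net.graph[u][v]["weight"])

    if format == "gexf":
        nx.write_gexf(ordered, path)
    elif format == "graphml":
        nx.write_graphml(ordered, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word1\tword2\tweight\n")
            for u, v, d in ordered.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['weight']}\n")
            for node in sorted(ordered.nodes()):
                if ordered.degree(node) == 0:
                    fh.write(f"{node}\t\t0\n")


def read_tsv_edges(path: str | Path) -> CooccurrenceNetwork:
    """Read back the TSV edge-list dialect written by :func:`export_network`."""
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["word1", "word2", "weight"]:
            raise UsageError(f"{path}: not a supportnet TSV edge list")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            if v == "":
                graph.add_node(u)
            else:
                graph.add_edge(u, v, weight=int(w))
    return CooccurrenceNetwork(graph=graph)
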