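"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
Floyd–Warshall for path lengths, direct triangle counting for clustering,
the raw double-sum for modularity, and exhaustive set-partition enumeration
for the modularity optimum.
"""

from itertools import combinations

import networkx as nx
import pytest

from supportnet.corpus import TokenizedSentence


def make_sentences(token_lists, group="g"):
    return [
        TokenizedSentence(post_id=f"p{i}", group=group, ordinal=0, tokens=tuple(toks))
        for i, toks in enumerate(token_lists)
    ]


@pytest.fixture
def two_cliques_bridged():
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in (0, 4):
        for i, j in combinations(range(base, base + 4), 2):
            g.add_edge(i, j, weight=1)
    g.add_edge(0, 4, weight=1)
    return g


def fw_all_pairs(graph):
    """Floyd–Warshall hop distances as a dict-of-dicts (INF for unreachable)."""
    nodes = list(graph.nodes())
    inf = float("inf")
    dist = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    for u, v in graph.edges():
        dist[u][v] = 1
        dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == inf:
                continue
            row_k = dist[k]
            row_i = dist[i]
            for j in nodes:
                alt = dik + row_k[j]
                if alt < row_i[j]:
                    row_i[j] = alt
    return dist


def fw_aspl(graph):
    """Mean finite off-diagonal distance of the largest connected component."""
    comp = max(nx.connected_components(graph), key=len)
    dist = fw_all_pairs(graph.subgraph(comp))
    vals = [d for u, row in dist.items() for v, d in row.items() if u != v]
    return sum(vals) / len(vals)


def triangle_cc(graph):
    """Mean local clustering coefficient by direct neighbor-pair counting."""
    total = 0.0
    for node in graph.nodes():
        nbrs = list(graph[node])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if graph.has_edge(a, b))
        total += links / (k * (k - 1) / 2)
    return total / graph.number_of_nodes()


def double_sum_modularity(graph, assignment, resolution=1.0):
    """Direct evaluation of Q over ordered node pairs."""
    nodes = list(graph.nodes())
    m2 = 2.0 * sum(d.get("weight", 1) for _, _, d in graph.edges(data=True))
    strength = dict(graph.degree(weight="weight"))
    q = 0.0
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            w = graph[i][j].get("weight", 1) if (i != j and graph.has_edge(i, j)) else 0.0
            q += w - resolution * strength[i] * strength[j] / m2
    return q / m2


def all_set_partitions(items):
    """Every partition of ``items`` into non-empty blocks (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def exhaustive_best_modularity(graph, resolution=1.0):
    """Maximum Q over every partition of the node set (n ≤ 8 or so)."""
    best = float("-inf")
    for blocks in all_set_partitions(graph.nodes()):
        assignment = {n: i for i, block in enumerate(blocks) for n in block}
        q = double_sum_modularity(graph, assignment, resolution)
        best = max(best, q)
    return best
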