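"""Word-module detection by resolution-parameterized modularity optimization.

The quality function is

    Q(c) = (1/2M) Σ_i Σ_j [ w_ij − λ ℓ_i ℓ_j / 2M ] δ_ij(c),

with M = ½ΣΣ w_ij the total edge weight, ℓ_i = Σ_j w_ij the node strength,
λ the resolution, and δ_ij(c) = 1 iff i and j share a module. Q is
*maximized* with a two-phase Louvain procedure (greedy local moves, then
graph aggregation, repeated until a pass yields no improvement); Q never
decreases between passes. Louvain is visit-order dependent, so the node
order is randomized per seed and the best of several restarts is returned.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .errors import EmptyInputError, UndefinedStatisticError
from .network import CooccurrenceNetwork

__all__ = [
    "ModulePartition",
    "ModuleSummary",
    "modularity",
    "louvain_partition",
    "filter_modules",
    "module_silhouette",
    "node_silhouettes",
    "top_keywords",
    "export_partition_csv",
    "export_partition_gexf",
]

Node = Hashable


@dataclass
class ModulePartition:
    """A node → module assignment with its resolution and modularity.

    After :func:`filter_modules`, nodes of dropped modules are absent from
    ``assignment`` (unassigned) and ``modularity_q`` refers to the subgraph
    induced on the assigned nodes.
    """

    assignment: dict[Node, int]
    resolution: float
    modularity_q: float
    pass_qs: list[float] = field(default_factory=list)

    @property
    def num_modules(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def module_members(self) -> dict[int, set[Node]]:
        members: dict[int, set[Node]] = {}
        for node, mod in self.assignment.items():
            members.setdefault(mod, set()).add(node)
        return members


@dataclass
class ModuleSummary:
    """Per-module report row: size, share of within-module edges (PC_k),
    silhouette, top keywords and assigned support category."""

    module_id: int
    size: int
    edge_proportion: float
    silhouette: float
    top_keywords: tuple[str, ...]
    category: str = "unclassified"


def _as_graph(net: CooccurrenceNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CooccurrenceNetwork) else net


def modularity(
    net: CooccurrenceNetwork | nx.Graph,
    assignment: Mapping[Node, int],
    resolution: float = 1.0,
) -> float:
    """Exact evaluation of Q(c) over ordered node pairs (w_ii = 0)."""
    g = _as_graph(net)
    missing = set(g.nodes()) - set(assignment)
    if missing:
        raise ValueError(f"assignment is missing {len(missing)} node(s)")
    m_total = sum(d.get("weight", 1) for _, _, d in g.edges(data=True))
    if m_total == 0:
        raise UndefinedStatisticError("modularity undefined for a graph with no edges")
    in_w: dict[int, float] = {}
    deg_w: dict[int, float] = {}
    strength = dict(g.degree(weight="weight"))
    for node, mod in assignment.items():
        deg_w[mod] = deg_w.get(mod, 0.0) + strength.get(node, 0)
    for u, v, d in g.edges(data=True):
        if assignment[u] == assignment[v]:
            mod = assignment[u]
            in_w[mod] = in_w.get(mod, 0.0) + d.get("weight", 1)
    q = 0.0
    for mod, deg in deg_w.items():
        q += in_w.get(mod, 0.0) / m_total - resolution * (deg / (2.0 * m_total)) ** 2
    return q


def _one_level(
    graph: nx.Graph,
    resolution: float,
    rng: random.Random,
    two_m: float,
) -> tuple[dict[Node, int], bool]:
    """Greedy local-move phase on the working graph; returns (node→community,
    moved-anything flag). Self-loop weight w is interpreted as internal
    weight (it contributes 2w to the node's strength, per the nx convention)."""
    nodes = sorted(graph.nodes(), key=repr)
    rng.shuffle(nodes)
    strength = dict(graph.degree(weight="weight"))
    com = {node: i for i, node in enumerate(nodes)}
    sigma_tot = {com[node]: strength[node] for node in nodes}

    moved_any = False
    for _sweep in range(200):
        moved = False
        for node in nodes:
            k_i = strength[node]
            old = com[node]
            link_w: dict[int, float] = {}
            for nbr, d in graph[node].items():
                if nbr == node:
                    continue
                c = com[nbr]
                link_w[c] = link_w.get(c, 0.0) + d.get("weight", 1)
            sigma_tot[old] -= k_i
            best_com = old
            best_gain = link_w.get(old, 0.0) - resolution * sigma_tot[old] * k_i / two_m
            for c in sorted(link_w):
                if c == old:
                    continue
                gain = link_w[c] - resolution * sigma_tot[c] * k_i / two_m
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_com = c
            sigma_tot.setdefault(best_com, 0.0)
            sigma_tot[best_com] += k_i
            if best_com != old:
                com[node] = best_com
                moved = True
                moved_any = True
        if not moved:
            break
    return com, moved_any


def _aggregate(graph: nx.Graph, com: Mapping[Node, int]) -> nx.Graph:
    agg = nx.Graph()
    agg.add_nodes_from(sorted(set(com.values())))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1)
        cu, cv = com[u], com[v]
        if agg.has_edge(cu, cv):
            agg[cu][cv]["weight"] += w
        else:
            agg.add_edge(cu, cv, weight=w)
    return agg


def _louvain_once(
    graph: nx.Graph, resolution: float, rng: random.Random
) -> tuple[dict[Node, int], list[float]]:
    two_m = 2.0 * sum(d.get("weight", 1) for _, _, d in graph.edges(data=True))
    # node of working graph → set of original nodes
    carrier: dict[Node, list[Node]] = {n: [n] for n in graph.nodes()}
    work = graph.copy()
    assignment = {n: i for i, n in enumerate(sorted(graph.nodes(), key=repr))}
    pass_qs: list[float] = []
    prev_q = modularity(graph, assignment, resolution)
    while True:
        com, moved = _one_level(work, resolution, rng, two_m)
        assignment = {}
        for wnode, c in com.items():
            for orig in carrier[wnode]:
                assignment[orig] = c
        q = modularity(graph, assignment, resolution)
        pass_qs.append(q)
        if not moved or q <= prev_q + 1e-12:
            break
        prev_q = q
        new_carrier: dict[Node, list[Node]] = {}
        for wnode, c in com.items():
            new_carrier.setdefault(c, []).extend(carrier[wnode])
        work = _aggregate(work, com)
        carrier = new_carrier
    return assignment, pass_qs


def _relabel(assignment: Mapping[Node, int]) -> dict[Node, int]:
    """Contiguous integer ids, 0..K-1, ordered by descending module size
    (ties by smallest member under repr ordering)."""
    members: dict[int, list[Node]] = {}
    for node, mod in assignment.items():
        members.setdefault(mod, []).append(node)
    order = sorted(
        members,
        key=lambda m: (-len(members[m]), min(repr(n) for n in members[m])),
    )
    remap = {old: new for new, old in enumerate(order)}
    return {node: remap[mod] for node, mod in assignment.items()}


def louvain_partition(
    net: CooccurrenceNetwork | nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 10,
    weighted: bool = True,
) -> ModulePartition:
    """Best-of-``restarts`` Louvain modularity maximization.

    Deterministic for fixed (net, resolution, seed, restarts): each restart
    uses an integer-derived RNG for its node visit order, and ties between
    restarts resolve to the earliest. Module ids in the result are
    contiguous integers ordered by descending module size. ``weighted=False``
    ignores edge weights (binarized graph).
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise UndefinedStatisticError("module detection needs at least one edge")
    if not weighted:
        g = nx.Graph()
        g.add_nodes_from(_as_graph(net).nodes())
        g.add_edges_from(_as_graph(net).edges(), weight=1)

    best_assignment: dict[Node, int] | None = None
    best_q = float("-inf")
    best_pass_qs: list[float] = []
    for r in range(max(1, restarts)):
        rng = random.Random(seed * 1_000_003 + r)
        assignment, pass_qs = _louvain_once(g, resolution, rng)
        q = pass_qs[-1]
        if q > best_q + 1e-12:
            best_q = q
            best_assignment = assignment
            best_pass_qs = pass_qs
    assert best_assignment is not None
    return ModulePartition(
        assignment=_relabel(best_assignment),
        resolution=resolution,
        modularity_q=best_q,
        pass_qs=best_pass_qs,
    )


def filter_modules(
    p: ModulePartition,
    min_module_size: int = 5,
    net: CooccurrenceNetwork | nx.Graph | None = None,
) -> ModulePartition:
    """Drop modules with fewer than ``min_module_size`` members.

    Nodes of dropped modules become unassigned and are excluded from
    downstream edge-proportion and silhouette computation. Remaining module
    ids are re-indexed by descending size. When ``net`` is given,
    ``modularity_q`` is re-evaluated on the subgraph induced by the
    surviving nodes.
    """
    members = p.module_members
    keep = {m for m, nodes in members.items() if len(nodes) >= min_module_size}
    if not keep:
        raise EmptyInputError(
            f"no module has ≥ {min_module_size} members; nothing left after filtering"
        )
    assignment = {n: m for n, m in p.assignment.items() if m in keep}
    assignment = _relabel(assignment)
    q = p.modularity_q
    if net is not None:
        sub = _as_graph(net).subgraph(assignment.keys())
        if sub.number_of_edges() > 0:
            q = modularity(sub, assignment, p.resolution)
    return ModulePartition(
        assignment=assignment,
        resolution=p.resolution,
        modularity_q=q,
        pass_qs=list(p.pass_qs),
    )


def _distance_matrix(graph: nx.Graph, nodelist: list[Node], distance: str):
    if distance == "hop":
        adj = nx.to_scipy_sparse_array(graph, nodelist=nodelist, format="csr")
        dists = shortest_path(adj, method="D", directed=False, unweighted=True)
    elif distance == "inverse_weight":
        inv = nx.Graph()
        inv.add_nodes_from(nodelist)
        for u, v, d in graph.edges(data=True):
            inv.add_edge(u, v, weight=1.0 / d.get("weight", 1))
        adj = nx.to_scipy_sparse_array(inv, nodelist=nodelist, format="csr")
        dists = shortest_path(adj, method="D", directed=False)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    finite = dists[np.isfinite(dists)]
    unreachable = (finite.max() if finite.size else 0.0) + 1.0
    dists[~np.isfinite(dists)] = unreachable
    return dists


def node_silhouettes(
    net: CooccurrenceNetwork | nx.Graph,
    p: ModulePartition,
    distance: str = "hop",
) -> dict[Node, float]:
    """Per-node silhouette s(i) = (b(i) − a(i)) / max(a(i), b(i)).

    a(i): mean distance to the other members of i's module; b(i): smallest
    mean distance to any other module. Distances are shortest-path lengths
    on the subgraph induced by assigned nodes (hop counts by default);
    unreachable pairs get (largest finite distance + 1). A node alone in its
    module scores 0.
    """
    if p.num_modules < 2:
        raise UndefinedStatisticError("silhouette undefined for a single module")
    g = _as_graph(net).subgraph(p.assignment.keys())
    nodelist = sorted(g.nodes(), key=repr)
    dists = _distance_matrix(g, nodelist, distance)
    labels = np.array([p.assignment[n] for n in nodelist])
    mods = np.unique(labels)
    n = len(nodelist)
    # mean distance from every node to every module (excluding self for own)
    mean_to = np.empty((n, mods.size))
    sizes = np.empty(mods.size)
    for j, mod in enumerate(mods):
        mask = labels == mod
        sizes[j] = mask.sum()
        mean_to[:, j] = dists[:, mask].sum(axis=1)
    own_col = np.searchsorted(mods, labels)
    result: dict[Node, float] = {}
    for i, node in enumerate(nodelist):
        j = own_col[i]
        if sizes[j] == 1:
            result[node] = 0.0
            continue
        a = mean_to[i, j] / (sizes[j] - 1)
        others = [
            mean_to[i, jj] / sizes[jj] for jj in range(mods.size) if jj != j
        ]
        b = min(others)
        denom = max(a, b)
        result[node] = 0.0 if denom == 0 else float((b - a) / denom)
    return result


def module_silhouette(
    net: CooccurrenceNetwork | nx.Graph,
    p: ModulePartition,
    distance: str = "hop",
) -> dict[int, float]:
    """Mean node silhouette per module."""
    per_node = node_silhouettes(net, p, distance=distance)
    out: dict[int, float] = {}
    for mod, nodes in p.module_members.items():
        out[mod] = sum(per_node[n] for n in nodes) / len(nodes)
    return out


def top_keywords(
    net: CooccurrenceNetwork | nx.Graph,
    p: ModulePartition,
    module_id: int,
    k: int = 5,
) -> list[str]:
    """The k module members with the highest within-module strength
    (weighted degree over edges internal to the module); ties break
    lexicographically. Returns all members when k exceeds the module size."""
    members = p.module_members.get(module_id)
    if not members:
        raise UndefinedStatisticError(f"module {module_id} does not exist")
    g = _as_graph(net)
    strength = {node: 0.0 for node in members}
    for u, v, d in g.subgraph(members).edges(data=True):
        w = d.get("weight", 1)
        strength[u] += w
        strength[v] += w
    ranked = sorted(members, key=lambda n: (-strength[n], str(n)))
    return [str(n) for n in ranked[:k]]


def export_partition_csv(p: ModulePartition, path: str | Path) -> None:
    """Write (word, module_id) rows, lexicographic by word."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word,module_id\n")
        for node in sorted(p.assignment, key=str):
            fh.write(f"{node},{p.assignment[node]}\n")


def export_partition_gexf(
    net: CooccurrenceNetwork | nx.Graph, p: ModulePartition, path: str | Path
) -> None:
    """GEXF export with the module id as a node attribute (for Gephi
    coloring); unassigned nodes get module -1."""
    g = _as_graph(net)
    out = nx.Graph()
    for node in sorted(g.nodes(), key=str):
        out.add_node(node, module=int(p.assignment.get(node, -1)))
    for u, v in sorted(tuple(sorted(e, key=str)) for e in g.edges()):
        out.add_edge(u, v, weight=g[u][v].get("weight", 1))
    nx.write_gexf(out, path)
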