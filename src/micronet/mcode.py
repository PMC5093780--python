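"""Dense-module (molecular-complex) detection, MCODE style.

The algorithm proceeds in two stages.  *Vertex weighting*: each node is
scored by the core-clustering coefficient of its open neighborhood — the
density of the highest k-core of the subgraph induced on its neighbors,
multiplied by that core's k.  This rewards membership in dense, clique-like
regions while being robust to single high-degree hubs.  *Complex
prediction*: starting from the highest-weighted unvisited seed, neighbors
are included greedily while their weight stays within a fraction
(``node_score_cutoff``) of the seed weight; an optional haircut trims the
complex to its 2-core.  A complex's score is the density of its induced
subgraph times its node count, and only complexes scoring strictly above a
cutoff (2.0 by default) are usually retained downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Module",
    "ModuleSet",
    "mcode_vertex_weights",
    "mcode_find_complexes",
    "filter_modules",
    "module_subgraph_stats",
]


@dataclass
class Module:
    members: frozenset
    score: float
    rank: int = 0

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    modules: list[Module] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        scores = [m.score for m in self.modules]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("modules must be in non-increasing score order")

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_vertex_weights(net: nx.Graph, degree_cutoff: int = 2) -> dict:
    """Core-clustering vertex weights.

    weight(v) = k_max * density(highest k-core of the open neighborhood
    of v), where k_max is that core's k.  Nodes with degree below
    ``degree_cutoff`` (and nodes whose neighborhood has no edges) get
    weight 0.
    """
    weights = {}
    for v in net.nodes():
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbrs = list(net.neighbors(v))
        sub = net.subgraph(nbrs)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        k_max = max(core.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, k in core.items() if k >= k_max]
        weights[v] = k_max * _density(sub.subgraph(core_nodes))
    return weights


def mcode_find_complexes(
    net: nx.Graph,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    degree_cutoff: int = 2,
) -> ModuleSet:
    """Greedy complex prediction from core-clustering vertex weights.

    Seeds are taken in descending weight order (ties by node id for
    reproducibility).  From each seed, neighbors whose weight is at
    least ``(1 - node_score_cutoff) * seed_weight`` are added
    breadth-first; a node joins at most one complex.  With ``haircut``
    the complex is trimmed to its 2-core, dropping singly-connected
    members.  Complexes of fewer than 2 nodes are discarded.
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not supported")
    weights = mcode_vertex_weights(net, degree_cutoff=degree_cutoff)
    order = sorted(weights, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    modules: list[Module] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(net.neighbors(u), key=str):
                    if w in visited or w in members:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        visited.add(w)
                        nxt.append(w)
            frontier = nxt
        sub = net.subgraph(members)
        if haircut:
            sub = nx.k_core(nx.Graph(sub), 2)
            members = set(sub.nodes())
        if len(members) < 2:
            continue
        if not nx.is_connected(net.subgraph(members)):
            # haircut can sever a weak bridge; keep the largest piece
            members = max(nx.connected_components(net.subgraph(members)), key=len)
            sub = net.subgraph(members)
            if len(members) < 2:
                continue
        score = _density(sub) * len(members)
        modules.append(Module(members=frozenset(members), score=score))
    modules.sort(key=lambda m: (-m.score, sorted(map(str, m.members))))
    for i, m in enumerate(modules, start=1):
        m.rank = i
    return ModuleSet(modules=modules)


def filter_modules(ms: ModuleSet, min_score: float = 2.0) -> ModuleSet:
    """Retain modules scoring strictly above ``min_score``."""
    kept = [m for m in ms.modules if m.score > min_score]
    for i, m in enumerate(kept, start=1):
        m.rank = i
    return ModuleSet(modules=kept, provenance=ms.provenance)


def module_subgraph_stats(net: nx.Graph, m: Module) -> tuple[int, int, float]:
    """(node count, edge count, density) of the module's induced subgraph."""
    missing = [v for v in m.members if v not in net]
    if missing:
        raise ValueError(f"module members not in network: {sorted(map(str, missing))[:5]}")
    sub = net.subgraph(m.members)
    return sub.number_of_nodes(), sub.number_of_edges(), _density(sub)
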