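"""Degree-preserving network randomization by double-edge swaps.

The null model for "is this node group unusually dense / central?" keeps
every node's degree fixed while destroying all other structure: repeatedly
pick two edges (a, b) and (c, d) and rewire them to (a, d) and (c, b),
rejecting any swap that would create a self-loop or a duplicate edge.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = ["randomize_degree_preserving"]


def randomize_degree_preserving(
    net: nx.Graph,
    n_swaps: int,
    seed: int | np.random.Generator = 0,
    count_accepted: bool = True,
    max_attempt_factor: int = 100,
) -> nx.Graph:
    """Return a degree-matched random simple graph.

    By default ``n_swaps`` counts *accepted* swaps, so replicates are
    comparably mixed; with ``count_accepted=False`` it counts attempts.
    Graphs admitting no valid swap (e.g. a star) are returned unchanged
    once the attempt budget (``max_attempt_factor * n_swaps``) runs out.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(net.nodes())
    g.add_edges_from(net.edges())
    edges = [tuple(e) for e in g.edges()]
    m = len(edges)
    if m < 2 or n_swaps < 1:
        return g
    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * n_swaps
    while (accepted if count_accepted else attempts) < n_swaps:
        attempts += 1
        if attempts > max_attempts:
            break
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        # proposed rewiring: (a, d) and (c, b)
        if a == d or c == b:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    return g
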