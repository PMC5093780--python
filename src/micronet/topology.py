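"""Global and local topology statistics for functional networks.

The panel mirrors what network-analysis suites report for biological
networks: density, Freeman degree centralization, diameter and
characteristic path length (on the largest connected component, since
thresholded co-abundance networks are typically disconnected), mean local
clustering, a log-log power-law fit to the degree distribution, and
per-node stress centrality.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "TopologySummary",
    "topology_summary",
    "degree_distribution_fit",
    "intersect_networks",
    "stress_centrality",
]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    centralization: float
    diameter: int | None
    clustering_coefficient: float
    characteristic_path_length: float | None
    degree_fit_slope: float | None = None
    degree_fit_r2: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def topology_summary(net: nx.Graph, fit_degrees: bool = True) -> TopologySummary:
    """Compute the standard topology panel for an undirected simple graph.

    Path-based metrics (diameter, characteristic path length) are computed
    on the largest connected component; clustering is the mean local
    clustering coefficient over nodes of degree >= 2.  For a single-node
    network path metrics are flagged as ``None``.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    m = net.number_of_edges()
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))

    degrees = np.array([d for _, d in net.degree()])
    if n > 2:
        centralization = float(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
    else:
        centralization = 0.0

    if n == 1:
        diameter = None
        cpl = None
    else:
        lcc = net.subgraph(max(nx.connected_components(net), key=len))
        diameter = int(nx.diameter(lcc))
        cpl = float(nx.average_shortest_path_length(lcc))

    eligible = [v for v, d in net.degree() if d >= 2]
    if eligible:
        cc = nx.clustering(net, eligible)
        clustering = float(np.mean(list(cc.values())))
    else:
        clustering = 0.0

    slope = r2 = None
    if fit_degrees and len(set(degrees[degrees >= 1])) >= 3:
        slope, r2 = degree_distribution_fit(net)

    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        density=density,
        centralization=centralization,
        diameter=diameter,
        clustering_coefficient=clustering,
        characteristic_path_length=cpl,
        degree_fit_slope=slope,
        degree_fit_r2=r2,
    )


def fit_power_law(degrees) -> tuple[float, float]:
    """Log-log least-squares power-law fit to a degree sequence.

    Regresses log10 P(k) on log10 k over the observed degrees k >= 1 with
    nonzero frequency (raw, unbinned frequencies).  Returns the slope and
    the coefficient of determination R^2; a scale-free network shows a
    negative slope with R^2 near 1.
    """
    degrees = np.asarray(degrees)
    degrees = degrees[degrees >= 1]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("need at least 3 distinct degree values for a fit")
    pk = counts / counts.sum()
    res = stats.linregress(np.log10(ks), np.log10(pk))
    return float(res.slope), float(res.rvalue**2)


def degree_distribution_fit(net: nx.Graph) -> tuple[float, float]:
    """Power-law fit to a network's degree distribution (see fit_power_law)."""
    return fit_power_law([d for _, d in net.degree()])


def intersect_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Edges common to both networks; nodes are the surviving endpoints.

    Intersecting networks inferred by different methods keeps only the
    associations both methods support.  Edge attributes are taken from
    the first network.
    """
    g = nx.Graph()
    for u, v, attrs in a.edges(data=True):
        if b.has_edge(u, v):
            g.add_edge(u, v, **attrs)
    return g


def stress_centrality(net: nx.Graph) -> dict:
    """Number of shortest paths passing through each node.

    stress(v) counts, over all unordered pairs {s, t} with s != v != t,
    the geodesics between s and t on which v is an interior vertex.
    Computed from all-pairs BFS distances and geodesic counts.
    """
    nodes = list(net.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = np.iinfo(np.int64).max // 4
    dist = np.full((n, n), INF, dtype=np.int64)
    sigma = np.zeros((n, n), dtype=float)

    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1.0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                ui = idx[u]
                for w in net.neighbors(u):
                    wi = idx[w]
                    if dist[si, wi] == INF:
                        dist[si, wi] = dist[si, ui] + 1
                        nxt.append(w)
                    if dist[si, wi] == dist[si, ui] + 1:
                        sigma[si, wi] += sigma[si, ui]
            queue = nxt

    stress = {}
    for v in nodes:
        vi = idx[v]
        reach = dist[vi] < INF
        through = (dist[:, vi][:, None] + dist[vi][None, :]) == dist
        through &= reach[:, None] & reach[None, :]
        contrib = np.where(through, sigma[:, vi][:, None] * sigma[vi][None, :], 0.0)
        contrib[vi, :] = 0.0
        contrib[:, vi] = 0.0
        np.fill_diagonal(contrib, 0.0)
        stress[v] = int(round(contrib.sum() / 2.0))
    return stress
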