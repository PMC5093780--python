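"""Disease-marker calling and permutation/enrichment tests on node groups.

A functional unit is a disease marker if its abundance differs between case
and control samples by a one-sided Wilcoxon rank-sum test at a stringent
cutoff (P < 1e-4 by default): "enriched" when higher in cases, "depleted"
when higher in controls.  Marker node groups are then interrogated on the
network with two permutation nulls — degree-preserving edge shuffling
(are the markers unusually densely interconnected?) and node-label
permutation (are their degrees or stress centralities unusual?) — and
per-module marker enrichment is assessed by Pearson's chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .mcode import ModuleSet
from .profiles import AbundanceProfile
from .randomize import randomize_degree_preserving
from .topology import stress_centrality

__all__ = [
    "MarkerTable",
    "PermutationResult",
    "call_markers",
    "edge_shuffle_null",
    "node_label_null",
    "module_marker_enrichment",
]


@dataclass
class MarkerTable:
    """Units called as markers: direction and one-sided P value."""

    table: pd.DataFrame  # columns: unit_id, direction, p_value
    alpha: float

    def units(self, direction: str | None = None) -> list[str]:
        t = self.table
        if direction is not None:
            t = t[t["direction"] == direction]
        return t["unit_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_replicates: int
    seed: int
    null_type: str  # "edge_shuffle" | "node_label"
    side: str = "ge"


def call_markers(
    profile: AbundanceProfile, alpha: float = 1e-4, case_label: str | None = None
) -> MarkerTable:
    """One-sided Wilcoxon rank-sum marker calling in both directions.

    For every unit the case-vs-control shift is tested with the
    Mann-Whitney U test (normal approximation with tie correction and
    continuity correction) in both one-sided directions; the unit is
    called "enriched" (higher in cases) or "depleted" (higher in
    controls) if the corresponding P value is below ``alpha``.  At most
    one direction can fire per unit.
    """
    if profile.labels is None:
        raise ValueError("profile has no sample labels")
    classes = sorted(profile.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes}")
    if case_label is None:
        case_cls, control_cls = classes[0], classes[1]
    elif case_label in classes:
        case_cls = case_label
        control_cls = next(c for c in classes if c != case_label)
    else:
        raise ValueError(f"case_label {case_label!r} not among labels {classes}")
    case = profile.abundance.loc[:, profile.labels == case_cls].to_numpy()
    ctrl = profile.abundance.loc[:, profile.labels == control_cls].to_numpy()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least 2 samples per class")
    p_greater = stats.mannwhitneyu(
        case, ctrl, axis=1, alternative="greater", method="asymptotic"
    ).pvalue
    p_less = stats.mannwhitneyu(
        case, ctrl, axis=1, alternative="less", method="asymptotic"
    ).pvalue
    rows = []
    for unit, pg, pl in zip(profile.unit_ids, p_greater, p_less):
        if pg < alpha:
            rows.append((unit, "enriched", float(pg)))
        elif pl < alpha:
            rows.append((unit, "depleted", float(pl)))
    table = pd.DataFrame(rows, columns=["unit_id", "direction", "p_value"])
    return MarkerTable(table=table, alpha=alpha)


def _group_density(net: nx.Graph, group: set) -> float:
    k = len(group)
    if k < 2:
        return 0.0
    sub = net.subgraph(group)
    return 2.0 * sub.number_of_edges() / (k * (k - 1))


def edge_shuffle_null(
    net: nx.Graph,
    group,
    statistic: str = "density",
    n_networks: int = 10_000,
    seed: int = 0,
    swaps_per_edge: int = 10,
    count_accepted: bool = True,
) -> PermutationResult:
    """Edge-shuffling permutation test for a node group's connectivity.

    Each replicate rewires the network with ``swaps_per_edge * |E|``
    accepted double-edge swaps (degree sequence preserved exactly) and
    recomputes the group statistic; the empirical P value is
    ``(#{null >= observed} + 1) / (n_networks + 1)``.
    """
    group = set(group)
    if not group:
        raise ValueError("group is empty")
    missing = group - set(net.nodes())
    if missing:
        raise ValueError(f"group members not in network: {sorted(map(str, missing))[:5]}")
    if statistic != "density":
        raise ValueError(f"unknown statistic: {statistic!r}")
    observed = _group_density(net, group)
    n_swaps = swaps_per_edge * net.number_of_edges()
    rng = np.random.default_rng(seed)
    null = np.empty(n_networks)
    for r in range(n_networks):
        rand = randomize_degree_preserving(
            net, n_swaps, seed=rng, count_accepted=count_accepted
        )
        null[r] = _group_density(rand, group)
    p = (np.count_nonzero(null >= observed) + 1.0) / (n_networks + 1.0)
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=float(p),
        n_replicates=n_networks,
        seed=seed,
        null_type="edge_shuffle",
    )


def node_label_null(
    net: nx.Graph,
    group,
    statistic: str = "density",
    n_draws: int = 10_000,
    seed: int = 0,
    side: str = "ge",
) -> PermutationResult:
    """Node-label permutation test for a group-level topological statistic.

    Draws ``n_draws`` uniform random node sets of the group's size and
    compares the statistic ("density", "mean_degree" or "mean_stress")
    against the observed group, one-sided per ``side`` ("ge": is the
    observed value unusually high; "le": unusually low), with add-one
    smoothing.
    """
    group = set(group)
    nodes = list(net.nodes())
    if not (0 < len(group) <= len(nodes)):
        raise ValueError("group must be a nonempty subset of the network")
    missing = group - set(nodes)
    if missing:
        raise ValueError(f"group members not in network: {sorted(map(str, missing))[:5]}")
    if side not in ("ge", "le"):
        raise ValueError("side must be 'ge' or 'le'")

    if statistic == "density":
        values = None
        observed = _group_density(net, group)
    elif statistic == "mean_degree":
        deg = dict(net.degree())
        values = np.array([deg[v] for v in nodes], dtype=float)
        observed = float(np.mean([deg[v] for v in group]))
    elif statistic == "mean_stress":
        stress = stress_centrality(net)
        values = np.array([stress[v] for v in nodes], dtype=float)
        observed = float(np.mean([stress[v] for v in group]))
    else:
        raise ValueError(f"unknown statistic: {statistic!r}")

    rng = np.random.default_rng(seed)
    k = len(group)
    n = len(nodes)
    if values is not None:
        # vectorized sampling without replacement: k smallest of n uniforms
        u = rng.random((n_draws, n))
        picks = np.argpartition(u, k - 1, axis=1)[:, :k]
        null = values[picks].mean(axis=1)
    else:
        null = np.empty(n_draws)
        for r in range(n_draws):
            pick = rng.choice(n, size=k, replace=False)
            null[r] = _group_density(net, [nodes[i] for i in pick])
    if side == "ge":
        extreme = np.count_nonzero(null >= observed)
    else:
        extreme = np.count_nonzero(null <= observed)
    p = (extreme + 1.0) / (n_draws + 1.0)
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=float(p),
        n_replicates=n_draws,
        seed=seed,
        null_type="node_label",
        side=side,
    )


def module_marker_enrichment(
    ms: ModuleSet,
    markers: MarkerTable,
    net: nx.Graph,
    direction: str = "enriched",
) -> pd.DataFrame:
    """Per-module marker enrichment by Pearson's chi-squared test.

    For each module a 2x2 table (in/out of module x marker/non-marker,
    over the network's node set) is tested without continuity correction
    (1 df).  Returns observed marker count, expected count under the
    network-wide marker fraction, chi2 and P; modules are flagged
    degenerate (P = NaN) when the network carries no markers (or only
    markers) of the requested direction.
    """
    nodes = set(net.nodes())
    marker_set = set(markers.units(direction)) & nodes
    rows = []
    for m in ms:
        if not m.members <= nodes:
            raise ValueError("module members missing from network")
        k = len(m.members)
        obs = len(m.members & marker_set)
        expected = k * len(marker_set) / len(nodes)
        in_mod = np.array([obs, k - obs], dtype=float)
        out_mod = np.array(
            [len(marker_set) - obs, len(nodes) - k - (len(marker_set) - obs)],
            dtype=float,
        )
        table = np.array([in_mod, out_mod])
        if len(marker_set) == 0 or len(marker_set) == len(nodes):
            chi2, p = np.nan, np.nan
        elif obs == expected:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append((m.rank, k, obs, expected, chi2, p))
    return pd.DataFrame(
        rows,
        columns=["module", "n_nodes", "observed", "expected", "chi2", "p_value"],
    )
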