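"""Association weight matrices and thresholded functional networks.

Two inference routes weight every pair of functional units by association
strength across samples:

* **PCC** — Pearson's correlation coefficient between the two units'
  abundance vectors, optionally with an empirical permutation P value.
* **RF** — the network over N units is cast as N feature-selection
  subproblems: each unit in turn is the regression target of a random
  forest grown on the remaining units, and the importance of predictor j
  for target i (impurity reduction averaged over trees, as in GENIE3) is
  the directed association weight j -> i.

A sparse undirected network is then obtained by keeping the ``floor(t*N)``
highest-ranked pairs ("relative threshold" t, default 1.5), or pairs whose
permutation P value clears a cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .profiles import AbundanceProfile

__all__ = [
    "WeightMatrix",
    "PermutationPValues",
    "pcc_weight_matrix",
    "pcc_permutation_pvalues",
    "rf_weight_matrix",
    "symmetrize",
    "threshold_network",
    "threshold_by_pvalue",
]


@dataclass
class WeightMatrix:
    """N x N pairwise association strengths over functional units."""

    unit_ids: list[str]
    weights: np.ndarray
    method: str  # "pcc" | "rf"
    symmetric: bool

    def __post_init__(self) -> None:
        n = len(self.unit_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match unit count")

    @property
    def n(self) -> int:
        return len(self.unit_ids)


@dataclass
class PermutationPValues:
    """Empirical P values for all unit pairs from a PCC permutation test."""

    unit_ids: list[str]
    p: np.ndarray
    n_perm: int
    seed: int


def _check_variance(X: np.ndarray, unit_ids) -> None:
    sd = X.std(axis=1)
    bad = [u for u, s in zip(unit_ids, sd) if s == 0]
    if bad:
        raise ValueError(f"zero-variance units (run filter_common_units?): {bad[:10]}")


def pcc_weight_matrix(profile: AbundanceProfile) -> WeightMatrix:
    """Pairwise Pearson correlations of unit abundances across samples.

    Entry (i, j) is ``r = sum_k (X_ik - mean_i)(X_jk - mean_j) /
    sqrt(sum (X_ik - mean_i)^2 * sum (X_jk - mean_j)^2)``.  The diagonal is
    zeroed: self-association carries no network information.
    """
    X = profile.values()
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    _check_variance(X, profile.unit_ids)
    r = np.corrcoef(X)
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    return WeightMatrix(list(profile.unit_ids), r, method="pcc", symmetric=True)


def pcc_permutation_pvalues(
    profile: AbundanceProfile, n_perm: int = 10_000, seed: int = 0
) -> PermutationPValues:
    """Permutation P values for every pairwise correlation.

    Each replicate permutes the sample order of one member of every pair
    (a single shared permutation per replicate, applied to the second
    member) and recomputes r; the two-sided empirical P value is
    ``(#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1)``, so it is never zero
    and its minimum attainable value is ``1/(n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = profile.values()
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    _check_variance(X, profile.unit_ids)
    # standardize rows so that correlation is a plain dot product / n
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    obs = np.abs(Z @ Z.T / n)
    np.fill_diagonal(obs, 0.0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.abs(Z @ Z[:, perm].T / n)
        exceed += r_perm >= obs
    p = (exceed + 1.0) / (n_perm + 1.0)
    # permuting member j of pair (i, j): make the matrix symmetric by
    # taking the pair's canonical (upper-triangle) replicate
    iu = np.triu_indices(p.shape[0], k=1)
    p[(iu[1], iu[0])] = p[iu]
    np.fill_diagonal(p, 1.0)
    return PermutationPValues(list(profile.unit_ids), p, n_perm, seed)


def rf_weight_matrix(
    profile: AbundanceProfile,
    n_trees: int = 1000,
    mtry: str | int | float = "sqrt",
    seed: int = 0,
) -> WeightMatrix:
    """Directed random-forest importance matrix over functional units.

    For each target unit i, a forest of ``n_trees`` regression trees is
    grown on the remaining N-1 units; entry (j, i) is the variance
    reduction attributed to predictor j, averaged across trees
    (unnormalised impurity importance).  Every unit vector is
    standardized to zero mean and unit variance first (the GENIE3
    convention), so importances are comparable across targets whose raw
    abundances differ by orders of magnitude; without this, the global
    edge ranking is dominated by high-variance targets.  ``mtry`` sets
    the number of candidate features tried at each split: ``"sqrt"``
    (default), ``"all"`` for the full N-1 feature set, or an explicit
    int/fraction.  A constant target yields an all-zero importance
    column with a warning.
    """
    X = profile.values()
    n_units, n_samples = X.shape
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if n_samples < 5:
        raise ValueError("need at least 5 samples")
    if mtry == "all":
        max_features = 1.0
    elif mtry == "sqrt":
        max_features = "sqrt"
    else:
        max_features = mtry
    W = np.zeros((n_units, n_units))
    seeds = np.random.SeedSequence(seed).generate_state(n_units) % (2**31 - 1)
    others = np.arange(n_units)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    for i in range(n_units):
        if sd[i, 0] == 0:
            warnings.warn(
                f"constant target unit {profile.unit_ids[i]!r}: importances set to 0",
                stacklevel=2,
            )
            continue
        feats = others[others != i]
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(seeds[i]),
            n_jobs=1,
        )
        forest.fit(Z[feats].T, Z[i])
        imp = np.mean(
            [t.tree_.compute_feature_importances(normalize=False)
             for t in forest.estimators_],
            axis=0,
        )
        W[feats, i] = imp
    return WeightMatrix(list(profile.unit_ids), W, method="rf", symmetric=False)


def symmetrize(w: WeightMatrix, rule: str = "max") -> WeightMatrix:
    """Collapse a directed weight matrix to an undirected one.

    ``rule="max"`` keeps the stronger of the two directed weights for each
    pair (the default: the strongest evidence for an association);
    ``rule="mean"`` averages them.
    """
    if rule == "max":
        out = np.maximum(w.weights, w.weights.T)
    elif rule == "mean":
        out = (w.weights + w.weights.T) / 2.0
    else:
        raise ValueError(f"unknown symmetrization rule: {rule!r}")
    return WeightMatrix(list(w.unit_ids), out, method=w.method, symmetric=True)


def threshold_network(
    w: WeightMatrix, relative_threshold: float = 1.5
) -> nx.Graph:
    """Keep the ``floor(t * N)`` highest-ranked pairs as network edges.

    PCC pairs are ranked by ``|r|`` (the sign is kept as an edge
    attribute); RF pairs by the symmetrised importance.  Ties at the
    cutoff are broken by lexicographic node-pair order.  Units left
    without any surviving edge are excluded from the node set, so the
    returned graph may have fewer than N nodes.
    """
    if relative_threshold <= 0:
        raise ValueError("relative_threshold must be positive")
    if not w.symmetric:
        raise ValueError("threshold_network requires a symmetric matrix; symmetrize() first")
    n = w.n
    n_keep = min(math.floor(relative_threshold * n), n * (n - 1) // 2)
    iu, ju = np.triu_indices(n, k=1)
    vals = w.weights[iu, ju]
    score = np.abs(vals) if w.method == "pcc" else vals
    # stable ranking: descending score, ties by lexicographic node pair
    order = np.lexsort((ju, iu, -score))[:n_keep]
    g = nx.Graph()
    g.graph["method"] = w.method
    for k in order:
        a, b = w.unit_ids[iu[k]], w.unit_ids[ju[k]]
        attrs = {"weight": float(vals[k])}
        if w.method == "pcc":
            attrs["sign"] = 1 if vals[k] >= 0 else -1
        g.add_edge(a, b, **attrs)
    return g


def threshold_by_pvalue(p: PermutationPValues, alpha: float = 0.01) -> nx.Graph:
    """Network whose edges are the pairs with permutation P below ``alpha``.

    ``alpha=1`` admits every pair (P values live in (0, 1], so the cutoff
    is inclusive at the top): the complete graph over the units.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    g = nx.Graph()
    n = len(p.unit_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if p.p[i, j] < alpha or alpha == 1:
                g.add_edge(p.unit_ids[i], p.unit_ids[j], p=float(p.p[i, j]))
    return g
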