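"""Seeded synthetic metagenome fixtures with planted structure.

The generator emulates the statistical structure the downstream methods
assume: functional units whose log abundances co-vary inside planted
modules (a shared latent factor per module), a subset of marker units with
a case/control location shift, log-normal baseline variation between
units, and compositional closure (each sample's abundances sum to one).
A matching gene-level table can be emitted so the whole profiling path —
length-normalised relative abundance, unit aggregation — is exercised
end to end.  The planted truth (module membership, marker directions,
true association pairs) is returned alongside for recovery scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .profiles import AbundanceProfile, AnnotationMap, GeneTable

__all__ = [
    "ModuleSpec",
    "MarkerSpec",
    "SynthConfig",
    "PlantedTruth",
    "generate_profile",
    "generate_gene_table",
    "planted_network",
]


@dataclass
class ModuleSpec:
    """A planted co-abundance module: ``size`` units sharing a latent factor.

    ``loading`` in (0, 1] is the factor coefficient on the log scale; with
    noise sd sigma the within-module correlation is roughly
    loading^2 / (loading^2 + sigma^2).
    """

    size: int
    loading: float = 0.8
    effect: float = 0.0  # case/control shift of member units, in pooled SDs
    direction: str = "enriched"

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not (0 < self.loading <= 1):
            raise ValueError("loading must be in (0, 1]")
        if self.direction not in ("enriched", "depleted"):
            raise ValueError("direction must be 'enriched' or 'depleted'")


@dataclass
class MarkerSpec:
    """Planted differential units: ``n`` units shifted by ``effect`` pooled SDs."""

    n: int
    effect: float = 1.5
    direction: str = "enriched"  # higher in cases; "depleted": higher in controls

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("marker count must be >= 1")
        if self.direction not in ("enriched", "depleted"):
            raise ValueError("direction must be 'enriched' or 'depleted'")


@dataclass
class SynthConfig:
    n_units: int = 500
    n_case: int = 100
    n_control: int = 100
    modules: list[ModuleSpec] = field(default_factory=list)
    markers: list[MarkerSpec] = field(default_factory=list)
    baseline_mean: float = 0.0  # mean log abundance before closure
    baseline_sd: float = 1.0  # between-unit dispersion of baselines
    noise_sd: float = 0.5  # per-sample log-scale noise within a unit
    genes_per_unit: int = 3
    depth: int = 10_000_000  # target reads per sample for gene tables
    seed: int = 42

    def __post_init__(self) -> None:
        planted = sum(m.size for m in self.modules) + sum(mk.n for mk in self.markers)
        if planted > self.n_units:
            raise ValueError("planted modules + markers exceed n_units")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")

    @classmethod
    def standard(cls, seed: int = 42) -> "SynthConfig":
        """The package's standard fixture: 500 units, 100+100 samples,
        three planted modules of sizes 8/10/12 at loading 0.8, and 30
        markers (15 enriched + 15 depleted) at a 1.5-SD shift."""
        return cls(
            n_units=500,
            n_case=100,
            n_control=100,
            modules=[ModuleSpec(8), ModuleSpec(10), ModuleSpec(12)],
            markers=[
                MarkerSpec(15, 1.5, "enriched"),
                MarkerSpec(15, 1.5, "depleted"),
            ],
            seed=seed,
        )


@dataclass
class PlantedTruth:
    module_of: dict[str, int]  # unit -> module index (planted units only)
    marker_direction: dict[str, str]
    unit_ids: list[str]
    marker_effect: dict[str, float] = field(default_factory=dict)

    def module_members(self, idx: int) -> set[str]:
        return {u for u, m in self.module_of.items() if m == idx}

    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def true_pairs(self) -> set[frozenset]:
        """All within-module unit pairs (the planted associations)."""
        pairs: set[frozenset] = set()
        for idx in set(self.module_of.values()):
            for a, b in itertools.combinations(sorted(self.module_members(idx)), 2):
                pairs.add(frozenset((a, b)))
        return pairs


def _layout(cfg: SynthConfig) -> tuple[list[str], PlantedTruth]:
    width = len(str(cfg.n_units))
    unit_ids = [f"U{i:0{width}d}" for i in range(1, cfg.n_units + 1)]
    module_of: dict[str, int] = {}
    marker_direction: dict[str, str] = {}
    cursor = 0
    marker_effect: dict[str, float] = {}
    for idx, spec in enumerate(cfg.modules):
        for u in unit_ids[cursor : cursor + spec.size]:
            module_of[u] = idx
            if spec.effect != 0.0:
                marker_direction[u] = spec.direction
                marker_effect[u] = spec.effect
        cursor += spec.size
    for spec in cfg.markers:
        for u in unit_ids[cursor : cursor + spec.n]:
            marker_direction[u] = spec.direction
            marker_effect[u] = spec.effect
        cursor += spec.n
    return unit_ids, PlantedTruth(module_of, marker_direction, unit_ids, marker_effect)


def generate_profile(cfg: SynthConfig) -> tuple[AbundanceProfile, PlantedTruth]:
    """Draw a labelled unit x sample abundance profile with planted structure.

    Log abundance of unit u in sample s is
    ``baseline_u + loading * factor_{module(u), s} + shift_u * group_s
    + noise_sd * eps``, exponentiated and closed per sample (columns sum
    to one).  The marker shift is ``effect * noise_sd`` on the log scale
    (+ for case samples of enriched markers, + for control samples of
    depleted ones).  Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    unit_ids, truth = _layout(cfg)
    n_samples = cfg.n_case + cfg.n_control
    sample_ids = [f"case_{i:03d}" for i in range(1, cfg.n_case + 1)] + [
        f"ctrl_{i:03d}" for i in range(1, cfg.n_control + 1)
    ]
    is_case = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_units)
    factors = rng.standard_normal((len(cfg.modules), n_samples))
    log_b = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_units, n_samples)
    )
    for i, u in enumerate(unit_ids):
        if u in truth.module_of:
            m = truth.module_of[u]
            log_b[i] += cfg.modules[m].loading * factors[m]
        if u in truth.marker_direction:
            direction = truth.marker_direction[u]
            shift = truth.marker_effect[u] * cfg.noise_sd
            group = is_case if direction == "enriched" else 1.0 - is_case
            log_b[i] += shift * group

    b = np.exp(log_b)
    b /= b.sum(axis=0, keepdims=True)
    abundance = pd.DataFrame(b, index=unit_ids, columns=sample_ids)
    labels = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=sample_ids
    )
    profile = AbundanceProfile(abundance=abundance, level="KO", labels=labels)
    return profile, truth


def generate_gene_table(cfg: SynthConfig) -> tuple[GeneTable, AnnotationMap, PlantedTruth]:
    """Emit a gene-level count table whose aggregation recovers the profile.

    Each unit's abundance is split over ``genes_per_unit`` genes with
    random proportions; gene lengths are uniform in 300-3000 bp and
    counts are derived by inverting the length normalisation at the
    configured sequencing depth (rounded to integers), so the profiling
    path reproduces the unit profile up to quantisation error.
    """
    if cfg.genes_per_unit < 1:
        raise ValueError("genes_per_unit must be >= 1")
    profile, truth = generate_profile(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0])
    unit_ids = list(profile.unit_ids)
    gene_ids, lengths, mapping = [], [], {}
    weights = []
    for u in unit_ids:
        w = rng.dirichlet(np.full(cfg.genes_per_unit, 5.0))
        for k in range(cfg.genes_per_unit):
            gid = f"{u}_g{k + 1}"
            gene_ids.append(gid)
            lengths.append(int(rng.integers(300, 3001)))
            mapping[gid] = frozenset({u})
            weights.append(w[k])
    weights = np.array(weights)
    lengths_arr = np.array(lengths, dtype=float)

    B = profile.values()  # units x samples
    A = np.repeat(B, cfg.genes_per_unit, axis=0) * weights[:, None]  # gene rel ab
    # invert a_i = (x_i / l_i) / total: x_i proportional to a_i * l_i
    raw = A * lengths_arr[:, None]
    scale = cfg.depth / raw.sum(axis=0, keepdims=True)
    counts = np.rint(raw * scale).astype(np.int64)
    table = GeneTable(
        counts=pd.DataFrame(counts, index=gene_ids, columns=profile.sample_ids),
        lengths=pd.Series(lengths, index=gene_ids),
    )
    ann = AnnotationMap(mapping=mapping, unit_namespace="KO")
    return table, ann, truth


def planted_network(truth: PlantedTruth) -> nx.Graph:
    """The gold association graph: one clique per planted module."""
    g = nx.Graph()
    for pair in truth.true_pairs():
        a, b = sorted(pair)
        g.add_edge(a, b, weight=1.0)
    return g
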