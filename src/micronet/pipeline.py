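"""End-to-end orchestration: profile -> networks -> modules -> analyses.

The pipeline mirrors the full study workflow on one labelled abundance
profile: filter to common units, infer PCC and RF networks at the relative
threshold, intersect them, detect and filter dense modules, call
case/control markers, test marker connectivity and module enrichment,
census tetrad motifs, and cross-validate a module-feature classifier.
Every stochastic stage draws from its own named seed, and the JSON report
is byte-identical across reruns with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as mio
from .classify import crossval_logistic, module_features, roc_pr
from .inference import (
    pcc_weight_matrix,
    rf_weight_matrix,
    symmetrize,
    threshold_network,
)
from .markers import (
    call_markers,
    edge_shuffle_null,
    module_marker_enrichment,
    node_label_null,
)
from .mcode import filter_modules, mcode_find_complexes
from .motifs import TETRAD_CLASSES, subgraph_ratio_profile
from .profiles import AbundanceProfile, filter_common_units
from .topology import intersect_networks, topology_summary

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("micronet")

_STAGE_SEEDS = ("rf", "edge_null", "node_null", "motifs", "cv")


@dataclass
class PipelineConfig:
    """All thresholds, replicate counts and seeds of a pipeline run.

    Defaults are the study-scale constants (relative threshold 1.5,
    marker alpha 1e-4, module score cutoff 2.0, 10,000 permutation
    replicates, 100 motif randomizations); replicate counts are the
    knobs to scale a run down.  Every stochastic stage must have a seed:
    use :meth:`with_master_seed` to derive all of them from one integer.
    """

    relative_threshold: float = 1.5
    marker_alpha: float = 1e-4
    min_module_score: float = 2.0
    n_trees: int = 1000
    mtry: str | int | float = "sqrt"
    rf_symmetrize: str = "max"
    n_null: int = 10_000  # edge-shuffle / node-label replicates
    n_random: int = 100  # motif randomizations
    cv_folds: int = 10
    seeds: dict = field(default_factory=dict)

    @classmethod
    def with_master_seed(cls, seed: int, **kwargs) -> "PipelineConfig":
        children = np.random.SeedSequence(seed).generate_state(len(_STAGE_SEEDS))
        seeds = {
            name: int(s % (2**31 - 1))
            for name, s in zip(_STAGE_SEEDS, children)
        }
        return cls(seeds=seeds, **kwargs)

    def seed_for(self, stage: str) -> int:
        if stage not in self.seeds:
            raise ValueError(f"no seed configured for stochastic stage {stage!r}")
        return int(self.seeds[stage])


def run_pipeline(
    profile: AbundanceProfile, cfg: PipelineConfig, out_dir: str | Path
) -> dict:
    """Run the full analysis on a labelled profile; return the JSON report.

    All intermediate artifacts (profiles, networks, modules, markers) are
    written under ``out_dir`` in the package's TSV dialects, plus
    ``report.json`` with every computed statistic, threshold and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {**asdict(cfg)}}

    def stage(name):
        log.info("stage %s", name)

    stage("filter_common_units")
    common = filter_common_units(profile)
    mio.write_profile(common, out / "profile.common.tsv")
    report["profile"] = {
        "n_units_input": profile.n_units,
        "n_units_common": common.n_units,
        "n_samples": common.n_samples,
    }

    stage("pcc_network")
    w_pcc = pcc_weight_matrix(common)
    net_pcc = threshold_network(w_pcc, cfg.relative_threshold)
    mio.write_network(net_pcc, out / "network.pcc.tsv")

    stage("rf_network")
    w_rf = symmetrize(
        rf_weight_matrix(
            common, n_trees=cfg.n_trees, mtry=cfg.mtry, seed=cfg.seed_for("rf")
        ),
        rule=cfg.rf_symmetrize,
    )
    net_rf = threshold_network(w_rf, cfg.relative_threshold)
    mio.write_network(net_rf, out / "network.rf.tsv")

    stage("intersection")
    net_int = intersect_networks(net_pcc, net_rf)
    mio.write_network(net_int, out / "network.intersection.tsv")

    stage("topology")
    report["topology"] = {}
    for name, net in (("pcc", net_pcc), ("rf", net_rf), ("intersection", net_int)):
        if net.number_of_nodes() > 0:
            report["topology"][name] = topology_summary(net).as_dict()
        else:
            report["topology"][name] = None

    stage("modules")
    modules = filter_modules(
        mcode_find_complexes(net_int), min_score=cfg.min_module_score
    )
    mio.write_modules(modules, out / "modules.tsv")
    report["modules"] = [
        {"module": m.rank, "score": m.score, "n_nodes": len(m.members)}
        for m in modules
    ]

    stage("markers")
    if common.labels is not None:
        markers = call_markers(common, alpha=cfg.marker_alpha)
        mio.write_markers(markers, out / "markers.tsv")
        report["markers"] = {
            "n_enriched": len(markers.units("enriched")),
            "n_depleted": len(markers.units("depleted")),
        }

        stage("marker_connectivity")
        report["marker_tests"] = {}
        for direction in ("enriched", "depleted"):
            group = set(markers.units(direction)) & set(net_pcc.nodes())
            if len(group) < 2:
                report["marker_tests"][direction] = None
                continue
            dens = edge_shuffle_null(
                net_pcc,
                group,
                n_networks=cfg.n_null,
                seed=cfg.seed_for("edge_null"),
            )
            deg = node_label_null(
                net_pcc,
                group,
                statistic="mean_degree",
                n_draws=cfg.n_null,
                seed=cfg.seed_for("node_null"),
                side="le",
            )
            report["marker_tests"][direction] = {
                "density_observed": dens.observed,
                "density_p": dens.p_value,
                "mean_degree_observed": deg.observed,
                "low_degree_p": deg.p_value,
            }

        stage("module_enrichment")
        if len(modules) > 0:
            enr = module_marker_enrichment(modules, markers, net_int, "enriched")
            report["module_enrichment"] = enr.to_dict(orient="records")
    else:
        markers = None
        report["markers"] = None

    stage("motifs")
    report["motifs"] = {}
    for name, net in (("pcc", net_pcc), ("rf", net_rf)):
        if net.number_of_edges() < 2:
            report["motifs"][name] = None
            continue
        srp = subgraph_ratio_profile(
            net, n_random=cfg.n_random, seed=cfg.seed_for("motifs")
        )
        report["motifs"][name] = {
            "classes": list(TETRAD_CLASSES),
            "real_counts": srp.real_counts.tolist(),
            "null_means": srp.null_means.tolist(),
            "delta": srp.delta.tolist(),
            "normalized": srp.normalized.tolist(),
            "degenerate": srp.degenerate,
        }

    stage("classifier")
    if common.labels is not None and len(modules) > 0:
        fm = module_features(common, modules)
        cv = crossval_logistic(fm, k=cfg.cv_folds, seed=cfg.seed_for("cv"))
        curves = roc_pr(cv)
        mio.write_json(curves, out / "classifier.json")
        report["classifier"] = {"auc": curves["auc"], "aupr": curves["aupr"]}
    else:
        report["classifier"] = None

    mio.write_json(report, out / "report.json")
    return report
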