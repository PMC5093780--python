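"""Readers and writers for the pipeline's TSV / GraphML / JSON artifacts.

All tabular formats are tab-delimited UTF-8 with a header row:

* gene table — columns ``gene_id``, ``length``, then one column per sample;
* annotation map — ``gene_id``, ``unit_ids`` (comma-separated, may be empty);
* labels — ``sample_id``, ``label``;
* abundance profile — ``unit_id`` then one column per sample;
* network edge list — ``node_a``, ``node_b``, ``weight``[, ``sign``], each
  undirected edge stored once with endpoints in sorted order;
* weight matrix — unit ids as both row index and column header;
* markers — ``unit_id``, ``direction``, ``p_value``;
* modules — ``module_id``, ``score``, ``n_nodes``, ``members``.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .inference import WeightMatrix
from .mcode import Module, ModuleSet
from .markers import MarkerTable
from .profiles import AbundanceProfile, AnnotationMap, GeneTable

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_annotation_map",
    "write_annotation_map",
    "read_labels",
    "write_labels",
    "read_profile",
    "write_profile",
    "read_weight_matrix",
    "write_weight_matrix",
    "read_network",
    "write_network",
    "read_modules",
    "write_modules",
    "read_markers",
    "write_markers",
    "write_json",
]

_FLOAT_FMT = "%.12g"


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    return df


def read_gene_table(path) -> GeneTable:
    df = _read_tsv(path, dtype={"gene_id": str})
    for col in ("gene_id", "length"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    df = df.set_index("gene_id")
    lengths = df.pop("length")
    return GeneTable(counts=df.astype(np.int64), lengths=lengths.astype(np.int64))


def write_gene_table(table: GeneTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_map(path, unit_namespace: str = "KO") -> AnnotationMap:
    df = _read_tsv(path, dtype=str, keep_default_na=False)
    for col in ("gene_id", "unit_ids"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    mapping = {}
    for _, row in df.iterrows():
        gid = row["gene_id"]
        if gid in mapping:
            raise ValueError(f"{path}: duplicate gene_id {gid!r}")
        units = [u for u in row["unit_ids"].split(",") if u]
        mapping[gid] = frozenset(units)
    return AnnotationMap(mapping=mapping, unit_namespace=unit_namespace)


def write_annotation_map(ann: AnnotationMap, path) -> None:
    rows = [
        {"gene_id": g, "unit_ids": ",".join(sorted(us))}
        for g, us in sorted(ann.mapping.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "unit_ids"]).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> pd.Series:
    df = _read_tsv(path, dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    return df.set_index("sample_id")["label"]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample_id")


def read_profile(path, labels_path=None, level: str = "KO") -> AbundanceProfile:
    df = _read_tsv(path)
    if df.columns[0] != "unit_id":
        raise ValueError(f"{path}: first column must be 'unit_id' (header required)")
    dup = df["unit_id"][df["unit_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate unit_id {dup.iloc[0]!r}")
    df = df.set_index("unit_id")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance cell: {exc}") from exc
    labels = read_labels(labels_path) if labels_path is not None else None
    return AbundanceProfile(abundance=values, level=level, labels=labels)


def write_profile(profile: AbundanceProfile, path) -> None:
    profile.abundance.to_csv(
        path, sep="\t", index_label="unit_id", float_format=_FLOAT_FMT
    )


def read_weight_matrix(path, method: str) -> WeightMatrix:
    df = _read_tsv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column unit ids differ")
    w = df.to_numpy(dtype=float)
    symmetric = bool(np.allclose(w, w.T))
    return WeightMatrix(list(df.index), w, method=method, symmetric=symmetric)


def write_weight_matrix(w: WeightMatrix, path) -> None:
    pd.DataFrame(w.weights, index=w.unit_ids, columns=w.unit_ids).to_csv(
        path, sep="\t", index_label="unit_id", float_format=_FLOAT_FMT
    )


def read_network(path, fmt: str = "edgelist") -> nx.Graph:
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for u, v, attrs in g.edges(data=True):
            if u == v:
                raise ValueError(f"{path}: self-loop at {u!r}")
            out.add_edge(u, v, **attrs)
        return out
    if fmt != "edgelist":
        raise ValueError(f"unknown network format: {fmt!r}")
    df = _read_tsv(path, dtype={"node_a": str, "node_b": str})
    for col in ("node_a", "node_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    g = nx.Graph()
    seen = set()
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        a, b = row.node_a, row.node_b
        if a == b:
            raise ValueError(f"{path}:{ln}: self-loop at {a!r}")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"{path}:{ln}: duplicate edge {a!r}-{b!r}")
        seen.add(key)
        attrs = {}
        if hasattr(row, "weight") and not pd.isna(row.weight):
            attrs["weight"] = float(row.weight)
        if hasattr(row, "sign") and not pd.isna(row.sign):
            attrs["sign"] = int(row.sign)
        g.add_edge(a, b, **attrs)
    return g


def write_network(net: nx.Graph, path, fmt: str = "edgelist") -> None:
    if fmt == "graphml":
        nx.write_graphml(net, path)
        return
    if fmt != "edgelist":
        raise ValueError(f"unknown network format: {fmt!r}")
    rows = []
    has_sign = any("sign" in d for _, _, d in net.edges(data=True))
    for u, v, d in sorted(net.edges(data=True), key=lambda e: tuple(sorted(map(str, e[:2])))):
        a, b = sorted((str(u), str(v)))
        row = {"node_a": a, "node_b": b, "weight": d.get("weight", 1.0)}
        if has_sign:
            row["sign"] = d.get("sign", "")
        rows.append(row)
    cols = ["node_a", "node_b", "weight"] + (["sign"] if has_sign else [])
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_modules(path) -> ModuleSet:
    df = _read_tsv(path, dtype={"members": str})
    mods = [
        Module(
            members=frozenset(row.members.split(",")),
            score=float(row.score),
            rank=int(row.module_id),
        )
        for row in df.itertuples(index=False)
    ]
    mods.sort(key=lambda m: m.rank)
    return ModuleSet(modules=sorted(mods, key=lambda m: -m.score))


def write_modules(ms: ModuleSet, path) -> None:
    rows = [
        {
            "module_id": m.rank,
            "score": m.score,
            "n_nodes": len(m.members),
            "members": ",".join(sorted(map(str, m.members))),
        }
        for m in ms
    ]
    pd.DataFrame(rows, columns=["module_id", "score", "n_nodes", "members"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_markers(path) -> MarkerTable:
    df = _read_tsv(path, dtype={"unit_id": str, "direction": str})
    return MarkerTable(
        table=df[["unit_id", "direction", "p_value"]].copy(), alpha=float("nan")
    )


def write_markers(markers: MarkerTable, path) -> None:
    markers.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
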