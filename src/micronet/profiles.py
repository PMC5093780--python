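"""Gene count tables, annotation maps and functional-unit abundance profiles.

A metagenome sample is summarised as read counts over a gene catalog.  Counts
are length-normalised and closed to relative abundances per sample, then summed
over the genes annotated to each functional unit (a KEGG orthologous group, KO,
or an eggNOG orthologous group, OG).  The resulting unit x sample matrix is the
substrate for all downstream network inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneTable",
    "AnnotationMap",
    "AbundanceProfile",
    "compute_gene_relative_abundance",
    "aggregate_to_units",
    "filter_common_units",
    "split_case_control",
]


@dataclass
class GeneTable:
    """Raw read counts per gene per sample, with gene lengths in bp.

    Parameters
    ----------
    counts
        Integer DataFrame, genes as rows, samples as columns.
    lengths
        Series of gene lengths (bp), indexed like ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene_ids must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("sample_ids must be unique")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise ValueError(f"missing lengths for genes: {missing[:5]}")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise ValueError(f"gene lengths must be strictly positive: {bad[:5]}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("read counts must be nonnegative")
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError("read counts must be integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def g(self) -> int:
        """Total number of genes in the catalog."""
        return self.counts.shape[0]


@dataclass
class AnnotationMap:
    """Mapping from gene id to the functional units annotating it.

    A gene may carry zero, one or several unit annotations; the set of genes
    annotated to unit *i* defines that unit's gene set.
    """

    mapping: dict[str, frozenset[str]]
    unit_namespace: str = "KO"

    def __post_init__(self) -> None:
        self.mapping = {g: frozenset(us) for g, us in self.mapping.items()}

    def units(self) -> list[str]:
        out: set[str] = set()
        for us in self.mapping.values():
            out.update(us)
        return sorted(out)

    def gene_sets(self) -> dict[str, list[str]]:
        """Invert the map: unit -> genes annotated with it (sorted)."""
        inv: dict[str, list[str]] = {}
        for g in sorted(self.mapping):
            for u in self.mapping[g]:
                inv.setdefault(u, []).append(g)
        return inv


@dataclass
class AbundanceProfile:
    """Functional-unit (or gene) relative abundances, units x samples.

    ``labels`` optionally assigns each sample to one of two groups
    (e.g. ``"case"`` / ``"control"``).
    """

    abundance: pd.DataFrame
    level: str = "gene"
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.abundance.index.is_unique:
            raise ValueError("unit_ids must be unique")
        if not self.abundance.columns.is_unique:
            raise ValueError("sample_ids must be unique")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundance values must be nonnegative")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.abundance.columns)
            if self.labels.isna().any():
                raise ValueError("labels missing for some samples")

    @property
    def unit_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.columns

    @property
    def n_units(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)


def compute_gene_relative_abundance(table: GeneTable) -> AbundanceProfile:
    """Length-normalised relative abundance of every gene in every sample.

    For gene *i* with count ``x_i`` and length ``l_i`` the relative abundance
    is ``a_i = (x_i / l_i) / sum_j (x_j / l_j)``, so each sample's abundances
    sum to one.  Normalising by length removes gene-length bias; closing to
    the sample total removes sequencing-depth differences.
    """
    rate = table.counts.div(table.lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(
            f"sample(s) with all-zero counts: {list(zero.index)}"
        )
    rel = rate.div(totals, axis=1)
    return AbundanceProfile(abundance=rel, level="gene")


def aggregate_to_units(
    gene_profile: AbundanceProfile, ann: AnnotationMap
) -> AbundanceProfile:
    """Sum gene relative abundances over each unit's annotated gene set.

    A multi-annotated gene contributes its full abundance to every unit it
    maps to (no fractionation); genes without annotation contribute nowhere.
    Units whose gene set is empty (no annotated gene present in the profile)
    are absent from the output.  Unit-level columns are *not* re-normalised,
    so under multi-annotation they may sum to more than one.
    """
    if gene_profile.level != "gene":
        raise ValueError("aggregate_to_units expects a gene-level profile")
    if not ann.mapping:
        raise ValueError("annotation map is empty")
    gene_sets = ann.gene_sets()
    present = set(gene_profile.unit_ids)
    rows = {}
    for unit, genes in gene_sets.items():
        genes_here = [g for g in genes if g in present]
        if genes_here:
            rows[unit] = gene_profile.abundance.loc[genes_here].sum(axis=0)
    if not rows:
        raise ValueError("no annotated gene is present in the profile")
    mat = pd.DataFrame(rows).T.sort_index()
    mat.columns = gene_profile.sample_ids
    return AbundanceProfile(
        abundance=mat, level=ann.unit_namespace, labels=gene_profile.labels
    )


def filter_common_units(profile: AbundanceProfile) -> AbundanceProfile:
    """Keep only units with strictly positive abundance in every sample.

    Units absent from even one sample cannot be correlated meaningfully
    across the cohort; only the common units enter network construction.
    Row order is preserved.
    """
    mask = (profile.abundance > 0).all(axis=1)
    if not mask.any():
        raise ValueError("no unit has nonzero abundance in every sample")
    return replace(profile, abundance=profile.abundance.loc[mask])


def split_case_control(
    profile: AbundanceProfile,
) -> tuple[AbundanceProfile, AbundanceProfile]:
    """Split a labelled profile into per-group profiles.

    Returns the two group profiles in sorted label order (e.g. case before
    control for labels "case"/"control"), each independently re-filtered to
    its own common units.
    """
    if profile.labels is None:
        raise ValueError("profile has no sample labels")
    classes = sorted(profile.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    out = []
    for cls in classes:
        cols = profile.sample_ids[profile.labels == cls]
        sub = AbundanceProfile(
            abundance=profile.abundance[cols],
            level=profile.level,
            labels=profile.labels[cols],
        )
        out.append(filter_common_units(sub))
    return out[0], out[1]
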