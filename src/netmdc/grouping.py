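"""Compound-network similarity, compound grouping, aggregate networks,
and the two baseline clusterings.

Compound networks (one per chemical with enough replicate samples) are
compared pairwise by the adjusted Rand index (aRI) of their module
partitions; compounds are grouped by Ward clustering of 1 - aRI with a
dynamic hybrid tree cut (minimum group size 3). For each group an
aggregate network is inferred from the pooled samples with partial
correlation controlling for compound identity, which removes the
confounding co-variation induced by compound-specific mean shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .datatypes import CONTROL, AnnotationTable, ExpressionMatrix, SampleMetadata
from .modules import ModulePartition
from .network import NetworkAdjacency, partial_correlation_adjacency
from .treecut import cut_dissimilarity

KIND_ARI = "ARI"
KIND_EXPR_EUCLID = "EXPR_EUCLID"
KIND_PROTEIN_JACCARD = "PROTEIN_JACCARD"


@dataclass
class CompoundSimilarityMatrix:
    compound_ids: list[str]
    values: np.ndarray
    kind: str
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.compound_ids), len(self.compound_ids)):
            raise ValueError("values must be square and match compound_ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity/distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.compound_ids)

    def as_distance(self) -> np.ndarray:
        """1 - aRI for similarity kinds; distances returned unchanged."""
        if self.kind == KIND_ARI:
            d = 1.0 - self.values
            np.fill_diagonal(d, 0.0)
            return d
        return self.values.copy()


@dataclass
class CompoundGrouping:
    compound_ids: list[str]
    labels: np.ndarray  # 0 = ungrouped
    linkage_method: str = "ward"
    min_group_size: int = 3
    deep_split: int = 4

    @property
    def group_labels(self) -> list[int]:
        return [int(c) for c in np.unique(self.labels) if c > 0]

    @property
    def group_sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in self.group_labels}

    def compounds_in(self, label: int) -> list[str]:
        return [c for c, l in zip(self.compound_ids, self.labels) if l == label]

    def ungrouped(self) -> list[str]:
        return [c for c, l in zip(self.compound_ids, self.labels) if l == 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound": self.compound_ids, "group": self.labels,
             "group_label": [f"G{l}" if l else "ungrouped" for l in self.labels]}
        )


def adjusted_rand_index(
    p1: ModulePartition,
    p2: ModulePartition,
    *,
    unassigned: str = "exclude",
) -> float:
    """Chance-corrected agreement of two module partitions.

    ``unassigned="exclude"`` drops genes unassigned (label 0) in either
    partition, comparing only co-clustering structure;
    ``"singleton"`` gives each unassigned gene its own private label.
    """
    if set(p1.gene_ids) != set(p2.gene_ids):
        raise ValueError("partitions must share the same gene universe")
    lab2 = dict(zip(p2.gene_ids, p2.labels))
    a = np.asarray(p1.labels, dtype=int)
    b = np.array([lab2[g] for g in p1.gene_ids], dtype=int)
    if unassigned == "exclude":
        keep = (a > 0) & (b > 0)
        if keep.sum() < 2:
            return 0.0
        a, b = a[keep], b[keep]
    elif unassigned == "singleton":
        a = a.copy()
        b = b.copy()
        next_a = a.max() + 1
        next_b = b.max() + 1
        for i in np.where(a == 0)[0]:
            a[i] = next_a
            next_a += 1
        for i in np.where(b == 0)[0]:
            b[i] = next_b
            next_b += 1
    else:
        raise ValueError(f"unknown unassigned mode {unassigned!r}")
    return float(adjusted_rand_score(a, b))


def compounds_with_min_replicates(meta: SampleMetadata, min_replicates: int = 10) -> list[str]:
    """Compounds with at least ``min_replicates`` replicate samples
    (controls excluded); the eligibility filter for compound networks."""
    return [
        c for c in meta.compounds()
        if c != CONTROL and len(meta.samples_for(c)) >= min_replicates
    ]


def compound_similarity(
    partitions: dict[str, ModulePartition],
    *,
    unassigned: str = "exclude",
) -> CompoundSimilarityMatrix:
    """Pairwise aRI between compound-network module partitions."""
    if not partitions:
        raise ValueError("no compound partitions given")
    compounds = list(partitions)
    n = len(compounds)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ari = adjusted_rand_index(
                partitions[compounds[i]], partitions[compounds[j]], unassigned=unassigned
            )
            values[i, j] = values[j, i] = ari
    return CompoundSimilarityMatrix(compounds, values, KIND_ARI)


def cut_compound_tree(
    sim: CompoundSimilarityMatrix,
    min_group_size: int = 3,
    deep_split: int = 4,
) -> CompoundGrouping:
    """Group compounds by Ward clustering + dynamic hybrid cut of the
    compound distance matrix (1 - aRI for the network-based similarity)."""
    n = len(sim.compound_ids)
    if n < 2 * min_group_size:
        raise ValueError(
            f"need at least {2 * min_group_size} compounds to form groups, got {n}"
        )
    dist = sim.as_distance()
    labels = cut_dissimilarity(dist, min_group_size, deep_split)
    return CompoundGrouping(
        compound_ids=sim.compound_ids,
        labels=labels,
        min_group_size=min_group_size,
        deep_split=deep_split,
    )


def mean_profile_distance(x: ExpressionMatrix, meta: SampleMetadata) -> CompoundSimilarityMatrix:
    """Baseline: Euclidean distance between per-compound mean expression
    profiles (no network structure used)."""
    meta.validate_against(x)
    compounds = meta.compounds()
    if not compounds:
        raise ValueError("metadata contains no non-control compounds")
    profiles = []
    for c in compounds:
        samples = [s for s in meta.samples_for(c) if s in x.data.columns]
        if not samples:
            raise ValueError(f"compound {c!r} has no samples in the expression matrix")
        profiles.append(x.data[samples].mean(axis=1).to_numpy())
    dist = squareform(pdist(np.vstack(profiles), metric="euclidean"))
    return CompoundSimilarityMatrix(compounds, dist, KIND_EXPR_EUCLID)


def jaccard_protein_distance(ann: AnnotationTable) -> CompoundSimilarityMatrix:
    """Baseline: 1 - Jaccard index of per-compound protein (item) sets.

    Compounds with no annotations are excluded and listed in ``excluded``.
    """
    if len(ann) == 0:
        raise ValueError("annotation table is empty")
    compounds = [c for c in ann.compounds if ann.items_for(c)]
    excluded = [c for c in ann.compounds if not ann.items_for(c)]
    sets = [ann.items_for(c) for c in compounds]
    n = len(compounds)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            jac = len(sets[i] & sets[j]) / union if union else 0.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    return CompoundSimilarityMatrix(compounds, dist, KIND_PROTEIN_JACCARD, excluded=excluded)


def build_aggregate_network(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    group: list[str] | set[str],
) -> NetworkAdjacency:
    """Aggregate compound network: partial correlation over the pooled
    samples of a compound group, controlling for compound identity."""
    group = list(group)
    samples: list[str] = []
    covariate: list[str] = []
    for c in group:
        c_samples = meta.samples_for(c)
        if not c_samples:
            raise ValueError(f"compound {c!r} has no samples in the metadata")
        samples.extend(c_samples)
        covariate.extend([c] * len(c_samples))
    pooled = x.subset_samples(samples)
    return partial_correlation_adjacency(pooled, np.asarray(covariate))
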