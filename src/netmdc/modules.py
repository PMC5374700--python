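"""Gene-module detection on a network adjacency and module matching
across networks.

Modules are found by Ward hierarchical clustering of the dissimilarity
d_ij = 1 - a_ij followed by a dynamic hybrid tree cut (minimum module
size 10 and deepSplit 4 in the reference configuration). Because the
adjacency is unsigned, anticorrelated genes can co-cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import NetworkAdjacency
from .treecut import cut_dissimilarity

# Cosmetic aliases for module labels, in the WGCNA color tradition.
_MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "sienna3", "yellowgreen", "skyblue3",
    "plum1", "orangered4", "mediumpurple3", "lightsteelblue1", "lightcyan1",
    "ivory", "floralwhite", "darkorange2", "brown4", "bisque4", "darkslateblue",
    "plum2", "thistle2", "thistle1", "salmon4", "palevioletred3", "navajowhite2",
    "maroon", "lightpink4", "lavenderblush3", "honeydew1", "darkseagreen4",
    "coral1",
)


def module_color(label: int) -> str:
    """Deterministic label -> color-name alias (0 = 'grey', unassigned)."""
    if label == 0:
        return "grey"
    return _MODULE_COLORS[(label - 1) % len(_MODULE_COLORS)]


@dataclass
class ModulePartition:
    """Assignment of genes to labeled modules; label 0 = unassigned."""

    gene_ids: list[str]
    labels: np.ndarray
    source_network: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != len(self.gene_ids):
            raise ValueError("labels must match gene_ids")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")

    @property
    def module_labels(self) -> list[int]:
        return [int(c) for c in np.unique(self.labels) if c > 0]

    @property
    def module_sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in self.module_labels}

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def genes_in(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def module_gene_sets(self) -> dict[int, frozenset[str]]:
        return {c: frozenset(self.genes_in(c)) for c in self.module_labels}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "module_label": self.labels,
                "module_color": [module_color(l) for l in self.labels],
            }
        )


def cluster_modules(
    adj: NetworkAdjacency,
    min_cluster_size: int = 10,
    deep_split: int = 4,
    *,
    method: str = "hybrid",
) -> ModulePartition:
    """Detect gene modules in a network adjacency.

    Dissimilarity is 1 - a_ij; clustering is Ward linkage with a dynamic
    hybrid cut. Genes failing assignment get label 0.
    """
    if adj.n_genes < 2 * min_cluster_size:
        raise ValueError(
            f"need at least {2 * min_cluster_size} genes to cluster, got {adj.n_genes}"
        )
    dissim = 1.0 - adj.weights
    np.fill_diagonal(dissim, 0.0)
    labels = cut_dissimilarity(dissim, min_cluster_size, deep_split, method=method)
    return ModulePartition(gene_ids=adj.gene_ids, labels=labels, source_network=adj.flavor)


@dataclass
class ModuleMatch:
    module_a: int
    module_b: int
    overlap: int
    fisher_p: float
    matched: bool


def overlap_fisher_p(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for the overlap of two gene
    sets of sizes ``size_a`` and ``size_b`` in a universe of ``universe``
    genes; equals the upper hypergeometric tail."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either set size")
    return float(hypergeom.sf(overlap - 1, universe, size_a, size_b))


def match_modules(
    p1: ModulePartition,
    p2: ModulePartition,
    alpha: float = 0.01,
) -> list[ModuleMatch]:
    """For each module of ``p1``, the best-overlapping module of ``p2``.

    Significance is a one-sided Fisher exact test on the 2x2 membership
    table over the shared gene universe; ``matched`` iff p < alpha.
    """
    if set(p1.gene_ids) != set(p2.gene_ids):
        raise ValueError("partitions must share the same gene universe")
    universe = len(p1.gene_ids)
    lab2 = dict(zip(p2.gene_ids, p2.labels))
    sizes2 = p2.module_sizes
    results = []
    for a in p1.module_labels:
        genes_a = p1.genes_in(a)
        counts: dict[int, int] = {}
        for g in genes_a:
            lb = lab2[g]
            if lb > 0:
                counts[lb] = counts.get(lb, 0) + 1
        if not counts:
            results.append(ModuleMatch(a, 0, 0, 1.0, False))
            continue
        best_b, overlap = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        p = overlap_fisher_p(overlap, len(genes_a), sizes2[best_b], universe)
        results.append(ModuleMatch(a, int(best_b), int(overlap), p, p < alpha))
    return results
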