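"""Dynamic hybrid cutting of a hierarchical clustering dendrogram.

Static tree cuts at a fixed height cannot adapt to dendrograms where
clusters merge at very different scales. The hybrid procedure implemented
here detects branches adaptively and then assigns left-over objects in a
PAM-like second stage:

1. The dendrogram (Ward linkage on a precomputed dissimilarity) is walked
   top-down. A node is split into its two children when both children are
   large enough (>= ``min_cluster_size``) and the merge sits clearly above
   the heights at which the children's members typically merge — the
   normalized *gap* between the node's height and a high quantile of each
   child's internal merge heights exceeds a threshold — and each child
   is internally tight (mean normalized merge height, the *core scatter*,
   below a ceiling). Using a quantile rather than the child's single top
   merge lets the walk descend through stacked high-level joins (a branch
   holding several well-separated clusters merges high itself). A small
   side branch hanging off a clear gap is trimmed to "unassigned" while
   descent continues into the main branch.
2. Objects left unassigned are attached to the cluster with the smallest
   mean dissimilarity, provided they are closer to that cluster than to
   the remaining objects; otherwise they keep label 0.

``deep_split`` in {0..4} controls sensitivity: higher values lower the
gap requirement and relax the core-scatter ceiling, producing more and
smaller clusters. Labels are positive integers ordered by decreasing
cluster size (label 1 = largest); 0 marks unassigned objects. The
procedure is fully deterministic.

This is a reimplementation in the spirit of the hybrid variant of the
dynamic tree cut algorithm of Langfelder, Zhang & Horvath; it does not
promise numerical agreement with the R reference, only recovery of
well-separated structure.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

# deep_split -> (core-scatter ceiling, minimum normalized gap)
_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)

#: quantile of a subtree's internal merge heights used as its "typical"
#: merge level when evaluating the split gap
_TOP_QUANTILE = 0.9


def _split_params(deep_split: int) -> tuple[float, float]:
    if deep_split not in range(5):
        raise ValueError(f"deep_split must be in 0..4, got {deep_split}")
    mcs = _CORE_SCATTER[deep_split]
    return mcs, (1.0 - mcs) * 3.0 / 4.0


def cut_tree_hybrid(
    Z: np.ndarray,
    dissim: np.ndarray,
    min_cluster_size: int,
    deep_split: int = 4,
) -> np.ndarray:
    """Cut a scipy linkage matrix into clusters; returns labels (0 = none)."""
    n = Z.shape[0] + 1
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    max_scatter, min_gap = _split_params(deep_split)

    heights = Z[:, 2]
    ref = float(np.quantile(heights, 0.05))
    hmax = float(heights.max())
    span = hmax - ref
    if span <= 0:  # flat dendrogram: one degenerate cluster
        return np.ones(n, dtype=int) if n >= min_cluster_size else np.zeros(n, dtype=int)

    def norm(h: float) -> float:
        return max(0.0, (h - ref) / span)

    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)

    # bottom-up subtree statistics, node ids: 0..n-1 leaves, n+i for Z row i
    count = np.ones(2 * n - 1, dtype=int)
    h_sum = np.zeros(2 * n - 1)
    h_cnt = np.zeros(2 * n - 1, dtype=int)
    node_h = np.zeros(2 * n - 1)
    q_top = np.zeros(2 * n - 1)  # high quantile of subtree merge heights
    subtree_heights: dict[int, list[float]] = {}
    for i in range(n - 1):
        node = n + i
        count[node] = count[left[i]] + count[right[i]]
        node_h[node] = norm(heights[i])
        h_sum[node] = h_sum[left[i]] + h_sum[right[i]] + node_h[node]
        h_cnt[node] = h_cnt[left[i]] + h_cnt[right[i]] + 1
        # smaller-into-larger list merging keeps this O(n log n) overall
        big = subtree_heights.pop(left[i], [])
        small = subtree_heights.pop(right[i], [])
        if len(small) > len(big):
            big, small = small, big
        big.extend(small)
        big.append(node_h[node])
        subtree_heights[node] = big
        q_top[node] = float(np.quantile(big, _TOP_QUANTILE))
    subtree_heights.clear()

    def scatter(node: int) -> float:
        return h_sum[node] / h_cnt[node] if h_cnt[node] else 0.0

    def leaves(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((left[v - n], right[v - n]))
        return out

    clusters: list[list[int]] = []
    unassigned: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if count[node] < min_cluster_size:
            unassigned.extend(leaves(node))
            continue
        if node < n:  # single leaf cluster only possible when min size is 1
            clusters.append([node])
            continue
        c1, c2 = left[node - n], right[node - n]
        if count[c2] > count[c1]:
            c1, c2 = c2, c1
        gap = node_h[node] - max(q_top[c1], q_top[c2])
        both_ok = (
            count[c1] >= min_cluster_size
            and count[c2] >= min_cluster_size
            and gap >= min_gap
            and scatter(c1) <= max_scatter
            and scatter(c2) <= max_scatter
        )
        if both_ok:
            stack.extend((c1, c2))
        elif (
            count[c2] < min_cluster_size
            and count[c1] >= min_cluster_size
            and node_h[node] - q_top[c1] >= min_gap
        ):
            # clear outlying twig: trim it, keep descending the main branch
            unassigned.extend(leaves(c2))
            stack.append(c1)
        else:
            clusters.append(leaves(node))

    labels = np.zeros(n, dtype=int)
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab

    if unassigned and clusters:
        labels = _assign_leftovers(labels, np.asarray(unassigned, dtype=int), dissim)

    return canonicalize_labels(labels)


def _assign_leftovers(labels: np.ndarray, pool: np.ndarray, dissim: np.ndarray) -> np.ndarray:
    """PAM-like stage: attach unassigned objects to the nearest cluster if
    they are closer to it than to the rest of the objects."""
    labels = labels.copy()
    cluster_ids = np.unique(labels[labels > 0])
    if cluster_ids.size == 0:
        return labels
    members = {c: np.where(labels == c)[0] for c in cluster_ids}
    for i in pool:
        means = np.array([dissim[i, members[c]].mean() for c in cluster_ids])
        best = int(np.argmin(means))
        c = cluster_ids[best]
        others = np.setdiff1d(np.arange(labels.size), np.append(members[c], i))
        if others.size == 0 or means[best] < dissim[i, others].mean():
            labels[i] = c
    return labels


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K by decreasing size (ties: first occurrence)."""
    labels = np.asarray(labels, dtype=int)
    ids = [c for c in np.unique(labels) if c > 0]
    if not ids:
        return labels.copy()
    sizes = {c: int((labels == c).sum()) for c in ids}
    first = {c: int(np.argmax(labels == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-sizes[c], first[c]))
    mapping = {c: i for i, c in enumerate(order, start=1)}
    out = np.zeros_like(labels)
    for c, new in mapping.items():
        out[labels == c] = new
    return out


def ward_linkage(dissim: np.ndarray) -> np.ndarray:
    """Ward linkage on a precomputed symmetric dissimilarity matrix."""
    d = np.asarray(dissim, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="ward")


def cut_dissimilarity(
    dissim: np.ndarray,
    min_cluster_size: int,
    deep_split: int = 4,
    *,
    method: str = "hybrid",
) -> np.ndarray:
    """Ward linkage + dynamic cut of a dissimilarity matrix.

    ``method="tree"`` is a simplified debugging fallback: a static cut at
    the 99th percentile merge height with small clusters dissolved.
    """
    Z = ward_linkage(dissim)
    if method == "hybrid":
        return cut_tree_hybrid(Z, dissim, min_cluster_size, deep_split)
    if method == "tree":
        from scipy.cluster.hierarchy import fcluster

        h = float(np.quantile(Z[:, 2], 0.99))
        raw = fcluster(Z, t=h, criterion="distance")
        labels = np.zeros_like(raw)
        for c in np.unique(raw):
            mask = raw == c
            if mask.sum() >= min_cluster_size:
                labels[mask] = c
        return canonicalize_labels(labels)
    raise ValueError(f"unknown cut method {method!r}")
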