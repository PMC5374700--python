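"""Adjacency-matrix inference: correlation networks (CN), scale-free
thresholded networks with topological overlap (SFN), and the
covariate-adjusted partial-correlation networks used for aggregates.

The default adjacency is unsigned, a_ij = |r_ij|, so connectivity measures
magnitude of co-expression irrespective of sign; the signed correlations
are retained alongside for diagnostics. The diagonal is defined as 0 and
excluded from every connectivity average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix

FLAVOR_CN = "CN"
FLAVOR_SFN_TOM = "SFN_TOM"
FLAVOR_PARTIAL = "PARTIAL_CN"


@dataclass
class NetworkAdjacency:
    """Symmetric gene-by-gene weight matrix with its raw correlations."""

    gene_ids: list[str]
    weights: np.ndarray
    flavor: str
    signed_source: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape[0] != w.shape[1] or w.shape[0] != len(self.gene_ids):
            raise ValueError("weights must be square and match gene_ids")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        s = np.asarray(self.signed_source, dtype=float).copy()
        np.fill_diagonal(s, 0.0)
        self.signed_source = s

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from adjacency: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)


def _correlation(values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    sd = values.std(axis=1)
    constant = [g for g, s in zip(gene_ids, sd) if s == 0]
    if constant:
        raise ValueError(f"constant genes cannot be correlated: {constant[:10]}")
    r = np.corrcoef(values)
    return np.clip(r, -1.0, 1.0)


def pearson_adjacency(x: ExpressionMatrix, *, signed: bool = False) -> NetworkAdjacency:
    """Correlation network: a_ij = |pearson(x_i, x_j)| (signed mode keeps r).

    Requires at least 3 samples and no constant gene.
    """
    if x.n_samples < 3:
        raise ValueError(f"need >=3 samples for correlation, got {x.n_samples}")
    r = _correlation(x.values, x.gene_ids)
    weights = r if signed else np.abs(r)
    return NetworkAdjacency(
        gene_ids=x.gene_ids,
        weights=weights.copy(),
        flavor=FLAVOR_CN,
        signed_source=r,
        n_samples=x.n_samples,
    )


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit across candidate hard thresholds.

    For each candidate tau, edges are kept where a_ij >= tau, degrees are
    binned (equal-occupancy log bins) and log10 p(k) is regressed on
    log10 k. The chosen threshold is the smallest one reaching
    ``r2_min`` with a negative slope, else the best-fitting one.
    """

    candidate_thresholds: np.ndarray
    r_squared: np.ndarray  # NaN where the fit was unusable
    chosen_threshold: float
    fit_criterion: float
    usable: bool
    warnings: list[str] = field(default_factory=list)


def _power_law_r2(degrees: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) ~ log10 k over equal-occupancy bins; NaN if the
    degree distribution is degenerate or the slope is non-negative."""
    k = degrees[degrees > 0]
    if k.size < 10 or np.unique(k).size < 3:
        return np.nan
    n_bins = min(n_bins, np.unique(k).size)
    quantiles = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    if edges.size < 3:
        return np.nan
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return np.nan
    slope, intercept = np.polyfit(xs, ys, 1)
    if slope >= 0:
        return np.nan
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - pred) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def select_scale_free_threshold(
    adj: NetworkAdjacency,
    candidates=None,
    r2_min: float = 0.85,
) -> ScaleFreeFit:
    """Pick the hard threshold whose degree distribution best fits a
    power law (scale-free topology)."""
    if candidates is None:
        candidates = np.arange(0.1, 1.0, 0.05)
    candidates = np.asarray(candidates, dtype=float)
    if ((candidates <= 0) | (candidates >= 1)).any():
        raise ValueError("candidate thresholds must lie in (0, 1)")
    r2 = np.full(candidates.shape, np.nan)
    warns: list[str] = []
    for i, tau in enumerate(candidates):
        edges = adj.weights >= tau
        np.fill_diagonal(edges, False)
        degrees = edges.sum(axis=1)
        if degrees.sum() == 0:
            warns.append(f"threshold {tau:.2f}: no edges, skipped")
            continue
        r2[i] = _power_law_r2(degrees)
    usable = bool(np.isfinite(r2).any())
    if not usable:
        warns.append("no candidate threshold produced a usable scale-free fit")
        return ScaleFreeFit(candidates, r2, float(candidates[0]), np.nan, False, warns)
    passing = np.where(np.nan_to_num(r2, nan=-np.inf) >= r2_min)[0]
    best = int(passing[0]) if passing.size else int(np.nanargmax(r2))
    return ScaleFreeFit(candidates, r2, float(candidates[best]), float(r2[best]), True, warns)


def tom_transform(adj: NetworkAdjacency, threshold: float) -> NetworkAdjacency:
    """Topological overlap of the hard-thresholded adjacency.

    With â_ij = a_ij * 1[a_ij >= tau], l_ij = sum_u â_iu â_uj and
    k_i = sum_u â_iu:

        TOM_ij = (l_ij + â_ij) / (min(k_i, k_j) + 1 - â_ij)
    """
    a = adj.weights.copy()
    a[a < threshold] = 0.0
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return NetworkAdjacency(
        gene_ids=adj.gene_ids,
        weights=tom,
        flavor=FLAVOR_SFN_TOM,
        signed_source=adj.signed_source,
        n_samples=adj.n_samples,
    )


def residualize_by_level(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Subtract per-level sample means from each gene (columns grouped by
    the categorical covariate)."""
    out = values.astype(float).copy()
    for level in np.unique(covariate):
        cols = covariate == level
        out[:, cols] -= out[:, cols].mean(axis=1, keepdims=True)
    return out


def partial_correlation_adjacency(x: ExpressionMatrix, covariate) -> NetworkAdjacency:
    """Partial-correlation network controlling for a categorical covariate.

    Expression is residualized on the covariate (per-level mean removal,
    equivalent to partialling out level indicator variables) and the
    adjacency is |pearson| of the residuals. Used for aggregate compound
    networks, where the covariate is compound identity and would otherwise
    confound correlations through compound-specific mean shifts.
    """
    covariate = np.asarray(covariate)
    if covariate.shape[0] != x.n_samples:
        raise ValueError("covariate length must equal the number of samples")
    levels, counts = np.unique(covariate, return_counts=True)
    small = levels[counts < 2]
    if small.size:
        raise ValueError(f"covariate levels with <2 samples: {small.tolist()}")
    if x.n_samples - levels.size < 3:
        raise ValueError(
            f"too few residual degrees of freedom: {x.n_samples} samples, "
            f"{levels.size} covariate levels"
        )
    resid = residualize_by_level(x.values, covariate)
    r = _correlation(resid, x.gene_ids)
    return NetworkAdjacency(
        gene_ids=x.gene_ids,
        weights=np.abs(r),
        flavor=FLAVOR_PARTIAL,
        signed_source=r,
        n_samples=x.n_samples,
    )
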