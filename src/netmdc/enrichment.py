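"""Gene-set enrichment of modules and annotation-based similarity of
compound groups.

Module annotation uses the one-sided hypergeometric (Fisher) test of the
overlap between a module and each gene set, restricted to the filtered
gene universe, with Benjamini-Hochberg correction across sets (FDR <=
0.25 reported by default). Compound-group coherence is scored by the
median pairwise Fisher p-value of annotation overlap between member
compounds, with significance from random equally sized compound groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import false_discovery_control, hypergeom

from .datatypes import AnnotationTable, GeneSetCollection


@dataclass
class EnrichmentResult:
    module_label: object
    set_name: str
    overlap: int
    module_size: int
    set_size: int
    universe_size: int
    p_value: float
    fdr_q: float

    @property
    def significant(self) -> bool:
        return self.fdr_q <= 0.25


def hypergeom_upper_tail(overlap: int, universe: int, module_size: int, set_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_size, module_size)."""
    return float(hypergeom.sf(overlap - 1, universe, set_size, module_size))


def hypergeometric_enrichment(
    module,
    sets: GeneSetCollection,
    universe,
    fdr_max: float = 0.25,
    *,
    module_label=None,
) -> list[EnrichmentResult]:
    """Test a module for enrichment of each gene set.

    Sets are intersected with the universe before testing; q-values are
    BH across all sets. Returns rows with fdr_q <= ``fdr_max`` (pass
    ``fdr_max=1`` for the full table), sorted by p-value.
    """
    module = frozenset(module)
    universe = frozenset(universe)
    module_in = module & universe
    if not module_in:
        raise ValueError("module is disjoint from the gene universe")
    n_univ = len(universe)
    rows = []
    for name in sets.names:
        members = sets[name] & universe
        if not members:
            continue
        overlap = len(module_in & members)
        p = hypergeom_upper_tail(overlap, n_univ, len(module_in), len(members))
        rows.append((name, overlap, len(members), p))
    if not rows:
        return []
    p_values = np.array([r[3] for r in rows])
    q_values = false_discovery_control(p_values, method="bh")
    results = [
        EnrichmentResult(
            module_label=module_label,
            set_name=name,
            overlap=overlap,
            module_size=len(module_in),
            set_size=set_size,
            universe_size=n_univ,
            p_value=float(p),
            fdr_q=float(q),
        )
        for (name, overlap, set_size, p), q in zip(rows, q_values)
    ]
    results = [r for r in results if r.fdr_q <= fdr_max]
    return sorted(results, key=lambda r: r.p_value)


def perturbational_overlap(module, signature, universe, *, module_label=None) -> EnrichmentResult:
    """Single-set hypergeometric test (e.g. against a differential-
    expression signature such as a perturbational transcriptome list)."""
    collection = GeneSetCollection({"signature": frozenset(signature)})
    res = hypergeometric_enrichment(
        module, collection, universe, fdr_max=1.0, module_label=module_label
    )
    return res[0]


def _overlap_fisher_p(set_a: frozenset, set_b: frozenset, universe_size: int) -> float:
    overlap = len(set_a & set_b)
    return hypergeom_upper_tail(overlap, universe_size, len(set_a), len(set_b))


def internal_similarity(group, ann: AnnotationTable, universe=None) -> float:
    """Median pairwise annotation-overlap Fisher p within a compound group.

    Compounds without annotations are skipped; with fewer than 2 annotated
    compounds the similarity is undefined and NaN is returned (the "no
    annotations" NA case).
    """
    if universe is None:
        universe = ann.items
    universe = frozenset(universe)
    annotated = [c for c in group if ann.items_for(c)]
    if len(annotated) < 2:
        return float("nan")
    sets = [ann.items_for(c) & universe for c in annotated]
    ps = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            ps.append(_overlap_fisher_p(sets[i], sets[j], len(universe)))
    return float(np.median(ps))


@dataclass
class GroupSimilarityResult:
    group_label: object
    median_pairwise_p: float
    permutation_p: float
    n_permutations: int
    best_possible: bool  # no permutation achieved a lower score
    annotation_source: str = ""


def permutation_group_significance(
    group_size: int,
    ann: AnnotationTable,
    observed: float,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    group_label=None,
) -> GroupSimilarityResult:
    """Significance of an observed internal-similarity score.

    Random equally sized compound groups are drawn (without replacement
    within each draw) from the annotated compounds;
    permutation_p = (1 + #{score_perm <= observed}) / (1 + n_perm), since
    smaller median p means higher similarity. ``best_possible`` flags the
    case where no permutation beats the observed score.
    """
    compounds = [c for c in ann.compounds if ann.items_for(c)]
    if group_size > len(compounds):
        raise ValueError(
            f"group_size {group_size} exceeds {len(compounds)} annotated compounds"
        )
    if not np.isfinite(observed):
        return GroupSimilarityResult(group_label, observed, float("nan"), n_perm, False)
    rng = np.random.default_rng(seed)
    compounds = np.asarray(compounds)
    universe = ann.items
    count = 0
    best = np.inf
    for _ in range(n_perm):
        sel = rng.choice(compounds, size=group_size, replace=False)
        score = internal_similarity(sel, ann, universe)
        if np.isnan(score):
            score = 1.0
        count += score <= observed
        best = min(best, score)
    p = (1 + count) / (1 + n_perm)
    return GroupSimilarityResult(
        group_label=group_label,
        median_pairwise_p=observed,
        permutation_p=float(p),
        n_permutations=n_perm,
        best_possible=bool(best >= observed),
    )
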