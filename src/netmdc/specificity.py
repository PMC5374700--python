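"""Perturbation specificity of module connectivity changes, and the
high-/low-frequency classification of aggregate-network modules.

For a module m and compound groups g_1..g_K, the specificity of m to a
focal group g_i is

    Sp(m)_{g_i} = sum_{k != i} | log MDC_m(g_i, c) - log MDC_m(g_k, c) |

i.e. how much the focal group's connectivity change stands apart from
every other group's. Per compound group, (module, group) pairs whose
score strictly exceeds the top 5th percentile of the pooled specificity
distribution are selected for enrichment analysis. For high-frequency
aggregate modules the score is additionally divided by the total number
of compound groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modules import ModulePartition, match_modules


def mdc_delta(log_mdc_i: float, log_mdc_j: float) -> float:
    """Absolute difference of two log MDC scores."""
    if not (np.isfinite(log_mdc_i) and np.isfinite(log_mdc_j)):
        raise ValueError("log MDC values must be finite")
    return abs(log_mdc_i - log_mdc_j)


def specificity_score(
    log_mdc_by_group: dict,
    focal,
    *,
    normalize: bool = False,
) -> float:
    """Sp of a module to the focal group; ``normalize`` divides by the
    total number of groups (the high-frequency module convention)."""
    if focal not in log_mdc_by_group:
        raise KeyError(f"focal group {focal!r} not in table")
    if len(log_mdc_by_group) < 2:
        raise ValueError("specificity needs at least 2 compound groups")
    f = log_mdc_by_group[focal]
    sp = sum(mdc_delta(f, v) for g, v in log_mdc_by_group.items() if g != focal)
    if normalize:
        sp /= len(log_mdc_by_group)
    return sp


def build_specificity_table(
    log_mdc: pd.DataFrame,
    *,
    normalize: bool = False,
) -> pd.DataFrame:
    """Long-format specificity table from a modules x groups log-MDC matrix.

    Columns: module_label, group, log_mdc, mdc, specificity.
    """
    if log_mdc.shape[1] < 2:
        raise ValueError("need at least 2 compound groups")
    rows = []
    for m, row in log_mdc.iterrows():
        by_group = row.to_dict()
        for g in log_mdc.columns:
            rows.append(
                {
                    "module_label": m,
                    "group": g,
                    "log_mdc": row[g],
                    "mdc": float(np.exp(row[g])),
                    "specificity": specificity_score(by_group, g, normalize=normalize),
                }
            )
    return pd.DataFrame(rows)


def select_specific_modules(table: pd.DataFrame, percentile: float = 5.0) -> pd.DataFrame:
    """Flag (module, group) pairs in the top ``percentile`` of the pooled
    specificity distribution (strictly exceeding the cut point).

    Adds columns ``percentile_rank`` and ``selected``. Selection iterates
    compound groups, but the threshold is computed on the global pooled
    distribution over all (module, group) pairs.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if table.empty:
        raise ValueError("specificity table is empty")
    scores = table["specificity"].to_numpy(dtype=float)
    cut = float(np.percentile(scores, 100.0 - percentile))
    out = table.copy()
    out["percentile_rank"] = pd.Series(scores).rank(pct=True).to_numpy() * 100.0
    selected = np.zeros(len(out), dtype=bool)
    for g in out["group"].unique():
        mask = (out["group"] == g).to_numpy()
        selected[mask] = scores[mask] > cut
    out["selected"] = selected
    return out


@dataclass
class FrequencyClass:
    module_label: int
    source_network: str
    genes: frozenset
    n_networks_observed: int
    n_networks_total: int
    frequency_class: str  # "HIGH" or "LOW"


def classify_frequency(
    partitions: dict[str, ModulePartition],
    alpha: float = 0.01,
) -> list[FrequencyClass]:
    """Classify each aggregate-network module as high/low frequency.

    A module of network A is observed in network B when some module of B
    overlaps it significantly (one-sided Fisher test p < ``alpha``). A
    module observed in strictly more than half of the aggregate networks
    (its own included) is HIGH frequency, otherwise LOW. Low-frequency
    modules are carried into downstream selection only if their own MDC
    significance passes (p < 0.01), which is applied by the caller.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 aggregate networks")
    names = list(partitions)
    total = len(names)
    matched: dict[tuple[str, int], int] = {}
    for a in names:
        for m in partitions[a].module_labels:
            matched[(a, m)] = 1  # observed in its own network
    for a in names:
        for b in names:
            if a == b:
                continue
            for match in match_modules(partitions[a], partitions[b], alpha=alpha):
                if match.matched:
                    matched[(a, match.module_a)] += 1
    results = []
    for (a, m), count in matched.items():
        cls = "HIGH" if count / total > 0.5 else "LOW"
        results.append(
            FrequencyClass(
                module_label=m,
                source_network=a,
                genes=frozenset(partitions[a].genes_in(m)),
                n_networks_observed=count,
                n_networks_total=total,
                frequency_class=cls,
            )
        )
    return results
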