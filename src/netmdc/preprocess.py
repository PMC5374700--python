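"""Variation filtering of probes prior to network inference.

Probes are ranked by the median absolute deviation (MAD) of their
expression across all samples and the top ``k`` are retained (7000 in the
reference configuration). The MAD is unscaled — no 1.4826 consistency
constant — since ranking is invariant to it. Ties at the cutoff are broken
by stable input order, so the filter is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    mad_values: pd.Series  # indexed by gene id, input order
    retained_ids: list[str]  # sorted by MAD descending (stable)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.retained_ids,
                "mad": self.mad_values.loc[self.retained_ids].to_numpy(),
                "rank": np.arange(1, self.n_retained + 1),
            }
        )


def mad_filter(x: ExpressionMatrix, k: int) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain the ``k`` genes with the largest MAD.

    Returns the filtered matrix (rows ordered by MAD descending, ties in
    input order) and a report with the per-gene MAD values. If fewer than
    ``k`` genes are available, all are retained and a warning is recorded.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if x.n_genes < 1:
        raise ValueError("expression matrix has no genes")
    values = x.values
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1)
    mad_series = pd.Series(mad, index=x.gene_ids)
    order = np.argsort(-mad, kind="stable")
    warnings = []
    if x.n_genes < k:
        warnings.append(f"requested k={k} but only {x.n_genes} genes available; all retained")
        n_keep = x.n_genes
    else:
        n_keep = k
    retained_idx = order[:n_keep]
    retained_ids = [x.gene_ids[i] for i in retained_idx]
    filtered = ExpressionMatrix(x.data.iloc[retained_idx])
    report = FilterReport(
        n_input=x.n_genes,
        n_retained=n_keep,
        mad_values=mad_series,
        retained_ids=retained_ids,
        warnings=warnings,
    )
    return filtered, report
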