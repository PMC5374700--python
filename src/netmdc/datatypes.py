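"""Core in-memory containers shared across the pipeline.

All containers are thin, validated wrappers around pandas/numpy objects.
Gene and sample identifiers are opaque strings: no symbol mapping is
attempted, and duplicated identifiers are a hard error everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Reserved compound label for unexposed (vehicle/control) samples.
CONTROL = "CONTROL"


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no", ""):
            return False
        raise ValueError(f"cannot interpret {value!r} as a boolean")
    return bool(value)


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


class ExpressionMatrix:
    """Normalized log-scale expression, genes (rows) by samples (columns).

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns. Values must
        be finite; missing values are rejected unless ``impute_missing`` is
        set, in which case they are replaced by the per-gene mean.
    impute_missing
        Replace NaNs by the row (gene) mean instead of raising. Genes that
        are entirely missing still raise.
    """

    def __init__(self, data: pd.DataFrame, *, impute_missing: bool = False):
        data = data.copy()
        gene_dups = _find_duplicates(data.index.astype(str))
        if gene_dups:
            raise ValueError(f"duplicate gene ids: {gene_dups}")
        sample_dups = _find_duplicates(data.columns.astype(str))
        if sample_dups:
            raise ValueError(f"duplicate sample ids: {sample_dups}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            if impute_missing:
                row_mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)
                if not np.isfinite(row_mean).all():
                    bad = data.index[~np.isfinite(row_mean)].tolist()
                    raise ValueError(f"genes with no finite values cannot be imputed: {bad}")
                idx = np.where(~np.isfinite(values))
                values[idx] = row_mean[idx[0]]
                data = pd.DataFrame(values, index=data.index, columns=data.columns)
            else:
                n_bad = int((~np.isfinite(values)).sum())
                raise ValueError(
                    f"expression matrix contains {n_bad} non-finite values; "
                    "pass impute_missing=True to impute by the gene mean"
                )
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        self.data = data

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[gene_ids])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data[sample_ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


class SampleMetadata:
    """Per-sample annotations: compound, dose, time, control status.

    Control samples carry the reserved compound label ``CONTROL`` and
    ``is_control == True``; the two encodings must agree.
    """

    REQUIRED = ("sample_id", "compound")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if "dose" not in table.columns:
            table["dose"] = ""
        if "time" not in table.columns:
            table["time"] = ""
        table["sample_id"] = table["sample_id"].astype(str)
        table["compound"] = table["compound"].astype(str)
        if "is_control" not in table.columns:
            table["is_control"] = table["compound"] == CONTROL
        else:
            table["is_control"] = table["is_control"].map(_parse_bool)
        dups = _find_duplicates(table["sample_id"])
        if dups:
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        mism = table[(table["compound"] == CONTROL) != table["is_control"]]
        if len(mism):
            raise ValueError(
                "is_control flag disagrees with CONTROL compound label for samples: "
                f"{mism['sample_id'].tolist()}"
            )
        self.table = table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def compounds(self, *, include_control: bool = False) -> list[str]:
        vals = self.table["compound"].unique().tolist()
        if not include_control:
            vals = [v for v in vals if v != CONTROL]
        return vals

    def samples_for(self, compound: str) -> list[str]:
        return self.table.loc[self.table["compound"] == compound, "sample_id"].tolist()

    def control_samples(self) -> list[str]:
        return self.table.loc[self.table["is_control"], "sample_id"].tolist()

    def compound_of(self) -> Mapping[str, str]:
        return dict(zip(self.table["sample_id"], self.table["compound"]))

    def validate_against(self, x: ExpressionMatrix) -> None:
        """Every expression sample must have exactly one metadata row."""
        meta_ids = set(self.sample_ids)
        missing = [s for s in x.sample_ids if s not in meta_ids]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        a = self.table.sort_values("sample_id").reset_index(drop=True)
        b = other.table.sort_values("sample_id").reset_index(drop=True)
        return a.equals(b)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB hallmark collection read from GMT)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


class AnnotationTable:
    """Compound-to-item edge list (interacting proteins or side effects).

    Rows are deduplicated on (compound, item). The per-compound item set is
    the unit consumed by the similarity tests; a compound absent from the
    table simply has an empty set (the "no annotations" case).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        for col in ("compound", "item"):
            if col not in table.columns:
                raise ValueError(f"annotation table missing required column {col!r}")
        if "evidence" not in table.columns:
            table["evidence"] = ""
        table["compound"] = table["compound"].astype(str)
        table["item"] = table["item"].astype(str)
        table = table.drop_duplicates(subset=["compound", "item"]).reset_index(drop=True)
        self.table = table

    @property
    def compounds(self) -> list[str]:
        return self.table["compound"].unique().tolist()

    @property
    def items(self) -> frozenset[str]:
        return frozenset(self.table["item"])

    def items_for(self, compound: str) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["compound"] == compound, "item"])

    def filter_evidence(self, evidence: str) -> "AnnotationTable":
        return AnnotationTable(self.table[self.table["evidence"] == evidence])

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        key = ["compound", "item", "evidence"]
        a = self.table[key].sort_values(key).reset_index(drop=True)
        b = other.table[key].sort_values(key).reset_index(drop=True)
        return a.equals(b)
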