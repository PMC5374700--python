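"""Readers and writers for the external formats: TSV, GCT v1.2, GMT.

All tables are UTF-8 tab-separated with a header row. GCT support is
limited to version 1.2 (two header lines, Name/Description columns);
v1.3 files are rejected with an explicit message.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AnnotationTable, ExpressionMatrix, GeneSetCollection, SampleMetadata


def _check_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return out


def read_expression(path, format: str | None = None, *, impute_missing: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT v1.2.

    The format is inferred from the extension when not given. Row and
    column order are preserved from the file.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(
                    f"{path}: unsupported GCT version {version!r}; only #1.2 is supported"
                )
            dims = fh.readline().split()
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["Name", "Description"]:
            raise ValueError(f"{path}: GCT header must start with Name<TAB>Description")
        df = df.set_index("Name").drop(columns="Description")
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"{path}: GCT dimension line says {n_genes}x{n_samples}, found {df.shape}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    df = _check_numeric(df, path)
    return ExpressionMatrix(df, impute_missing=impute_missing)


def write_expression(x: ExpressionMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        x.data.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{x.n_genes}\t{x.n_samples}\n")
            out = x.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(
        pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    )


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members per line).

    Duplicate members within a line are dropped; a duplicated set name or
    a set with no members is an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *sorted(members)]) + "\n")


def read_annotations(path, *, evidence: str | None = None) -> AnnotationTable:
    """Read a compound-item annotation TSV (CTD/STITCH/SIDER-style extract).

    ``evidence`` keeps only rows with that evidence label (e.g.
    ``"experimental"`` for STITCH experimental-evidence associations).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ann = AnnotationTable(table)
    if evidence is not None:
        ann = ann.filter_evidence(evidence)
    return ann


def write_annotations(ann: AnnotationTable, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def write_edge_list(adjacency, path, *, min_weight: float = 0.0) -> None:
    """Export a network as a long-format edge list TSV.

    Columns: gene_i, gene_j, weight, raw_r (signed correlation). Only the
    upper triangle is written; edges below ``min_weight`` are dropped.
    """
    genes = adjacency.gene_ids
    w = adjacency.weights
    r = adjacency.signed_source
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = w[iu, ju] >= min_weight
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_i", "gene_j", "weight", "raw_r"])
        for i, j in zip(iu[keep], ju[keep]):
            writer.writerow([genes[i], genes[j], f"{w[i, j]:.6g}", f"{r[i, j]:.6g}"])
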