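"""End-to-end orchestration of the differential-connectivity pipeline.

Stages: MAD filter -> control network -> per-compound networks -> aRI
grouping -> aggregate networks -> module detection -> MDC + bootstrap
significance (control-centered and aggregate-centered) -> specificity ->
optional gene-set enrichment. Every intermediate result is persisted as
TSV in the run directory together with the resolved configuration, so a
run is fully reproducible from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .datatypes import ExpressionMatrix, SampleMetadata
from .enrichment import hypergeometric_enrichment
from .grouping import (
    build_aggregate_network,
    compound_similarity,
    compounds_with_min_replicates,
    cut_compound_tree,
)
from .mdc import bootstrap_mdc, compute_gdc, compute_mdc
from .modules import cluster_modules, module_color
from .network import pearson_adjacency
from .preprocess import mad_filter
from .specificity import build_specificity_table, classify_frequency, select_specific_modules

log = logging.getLogger("netmdc")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their reference defaults."""

    expression: str = ""
    metadata: str = ""
    gene_sets: str = ""  # optional GMT
    out_dir: str = "netmdc_run"
    mad_k: int = 7000
    min_replicates: int = 10
    min_module_size: int = 10
    deep_split: int = 4
    min_group_size: int = 3
    group_deep_split: int = 4
    n_boot: int = 1000
    n_perm: int = 1000
    specificity_percentile: float = 5.0
    fdr_max: float = 0.25
    hf_threshold: float = 0.5
    lf_p_max: float = 0.01
    match_alpha: float = 0.01
    seed: int = 17

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (stable
    across processes: stage names are hashed with crc32)."""
    h = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: PipelineConfig,
    *,
    x: ExpressionMatrix | None = None,
    meta: SampleMetadata | None = None,
) -> Path:
    """Execute the full pipeline; returns the run directory.

    Expression and metadata can be passed in-memory (e.g. from the
    synthetic generator) or read from the paths in the config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")

    stage = "load inputs"
    try:
        if x is None:
            x = nio.read_expression(config.expression)
        if meta is None:
            meta = nio.read_metadata(config.metadata)
        meta.validate_against(x)
        gene_sets = nio.read_gmt(config.gene_sets) if config.gene_sets else None

        stage = "mad filter"
        x_filt, report = mad_filter(x, min(config.mad_k, x.n_genes))
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        nio.write_expression(x_filt, out / "expression.filtered.tsv")

        stage = "control network"
        controls = meta.control_samples()
        if len(controls) < 3:
            raise ValueError("need >=3 control samples")
        control_adj = pearson_adjacency(x_filt.subset_samples(controls))
        control_modules = cluster_modules(
            control_adj, config.min_module_size, config.deep_split
        )
        control_modules.to_frame().to_csv(out / "modules.control.tsv", sep="\t", index=False)
        log.info("control network: %d genes, %d modules",
                 control_adj.n_genes, control_modules.n_modules)

        stage = "compound networks"
        eligible = compounds_with_min_replicates(meta, config.min_replicates)
        if len(eligible) < 2:
            raise ValueError(
                f"fewer than 2 compounds have >= {config.min_replicates} replicates"
            )
        partitions = {}
        for c in eligible:
            adj = pearson_adjacency(x_filt.subset_samples(meta.samples_for(c)))
            partitions[c] = cluster_modules(adj, config.min_module_size, config.deep_split)
        log.info("inferred %d compound networks", len(partitions))

        stage = "compound grouping"
        sim = compound_similarity(partitions)
        sim.to_frame().to_csv(out / "compound_similarity.tsv", sep="\t")
        grouping = cut_compound_tree(sim, config.min_group_size, config.group_deep_split)
        grouping.to_frame().to_csv(out / "compound_groups.tsv", sep="\t", index=False)
        if grouping.ungrouped():
            log.info("ungrouped compounds excluded from aggregates: %s",
                     grouping.ungrouped())

        stage = "aggregate networks"
        aggregates = {}
        for g in grouping.group_labels:
            aggregates[f"G{g}"] = build_aggregate_network(
                x_filt, meta, grouping.compounds_in(g)
            )

        stage = "control-centered MDC"
        x_control = x_filt.subset_samples(controls)
        boot_seed = stage_seed(config.seed, "bootstrap-control")
        mdc_rows = []
        log_mdc = pd.DataFrame(
            index=control_modules.module_labels, columns=list(aggregates), dtype=float
        )
        for gname, agg in aggregates.items():
            observed = {
                m: compute_mdc(agg, control_adj, control_modules.genes_in(m))
                for m in control_modules.module_labels
            }
            results = bootstrap_mdc(
                x_control, control_modules, observed,
                n_target=agg.n_samples, n_boot=config.n_boot,
                seed=stage_seed(boot_seed, gname),
            )
            for r in results:
                log_mdc.loc[r.module_label, gname] = r.log_mdc
                mdc_rows.append({
                    "group": gname, "module_label": r.module_label,
                    "module_color": module_color(r.module_label),
                    "mdc": r.mdc, "log_mdc": r.log_mdc,
                    "p_value": r.p_value, "q_value": r.q_value,
                })
            gdc = compute_gdc(agg, control_adj)
            mdc_rows.append({"group": gname, "module_label": 0,
                             "module_color": "GDC", "mdc": gdc,
                             "log_mdc": float(np.log(gdc)),
                             "p_value": np.nan, "q_value": np.nan})
        pd.DataFrame(mdc_rows).to_csv(out / "mdc.control_centered.tsv", sep="\t", index=False)
        np.exp(log_mdc).to_csv(out / "mdc_matrix.tsv", sep="\t", index_label="module_label")

        stage = "control-centered specificity"
        if log_mdc.shape[1] >= 2:
            spec_table = build_specificity_table(log_mdc)
            spec_table = select_specific_modules(spec_table, config.specificity_percentile)
            spec_table.to_csv(out / "specificity.control_centered.tsv", sep="\t", index=False)
        else:
            spec_table = None
            log.info("single compound group: specificity skipped")

        stage = "aggregate-centered MDC"
        agg_partitions = {
            g: cluster_modules(adj, config.min_module_size, config.deep_split)
            for g, adj in aggregates.items()
        }
        perturbed = [s for c in eligible for s in meta.samples_for(c)]
        x_perturbed = x_filt.subset_samples(perturbed)
        agg_rows = []
        for g, part in agg_partitions.items():
            observed = {
                m: compute_mdc(aggregates[g], control_adj, part.genes_in(m))
                for m in part.module_labels
            }
            results = bootstrap_mdc(
                x_perturbed, part, observed,
                n_target=aggregates[g].n_samples, n_boot=config.n_boot,
                seed=stage_seed(config.seed, f"bootstrap-agg-{g}"),
            )
            for r in results:
                agg_rows.append({
                    "network": g, "module_label": r.module_label,
                    "mdc": r.mdc, "log_mdc": r.log_mdc,
                    "p_value": r.p_value, "q_value": r.q_value,
                })
        agg_mdc = pd.DataFrame(agg_rows)
        if len(agg_partitions) >= 2:
            freq = classify_frequency(agg_partitions, alpha=config.match_alpha)
            freq_df = pd.DataFrame([
                {"network": f.source_network, "module_label": f.module_label,
                 "n_observed": f.n_networks_observed, "n_total": f.n_networks_total,
                 "class": f.frequency_class}
                for f in freq
            ])
            agg_mdc = agg_mdc.merge(freq_df, on=["network", "module_label"], how="left")
            keep_lf = (agg_mdc["class"] == "HIGH") | (
                (agg_mdc["class"] == "LOW") & (agg_mdc["p_value"] < config.lf_p_max)
            )
            agg_mdc["selected_by_frequency"] = keep_lf
        agg_mdc.to_csv(out / "mdc.aggregate_centered.tsv", sep="\t", index=False)

        stage = "enrichment"
        if gene_sets is not None and spec_table is not None:
            universe = frozenset(x_filt.gene_ids)
            enr_rows = []
            for _, row in spec_table[spec_table["selected"]].iterrows():
                module_genes = control_modules.genes_in(int(row["module_label"]))
                for res in hypergeometric_enrichment(
                    module_genes, gene_sets, universe, config.fdr_max,
                    module_label=int(row["module_label"]),
                ):
                    enr_rows.append({
                        "group": row["group"], "module_label": res.module_label,
                        "set_name": res.set_name, "overlap": res.overlap,
                        "module_size": res.module_size, "set_size": res.set_size,
                        "p_value": res.p_value, "fdr_q": res.fdr_q,
                    })
            pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

        manifest = {
            "n_genes_input": x.n_genes,
            "n_genes_filtered": x_filt.n_genes,
            "n_control_samples": len(controls),
            "n_compound_networks": len(partitions),
            "n_groups": len(aggregates),
            "n_control_modules": control_modules.n_modules,
            "seed": config.seed,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r} (run dir: {out})") from exc
    return out
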