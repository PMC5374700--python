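import numpy as np
import pandas as pd
import pytest

from netmdc.datatypes import ExpressionMatrix, SampleMetadata
from netmdc.synthetic import CompoundDesign, SimulationDesign, generate_cohort


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with simple integer-ish values."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 4.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_tsv(tmp_path, small_expr):
    path = tmp_path / "expr.tsv"
    small_expr.data.to_csv(path, sep="\t", index_label="gene_id")
    return path


@pytest.fixture
def blocks_cohort():
    """150 genes in three 50-gene blocks (rho 0.8), 100 control samples."""
    design = SimulationDesign(
        n_genes=150,
        module_sizes=[50, 50, 50],
        control_rho=[0.8, 0.8, 0.8],
        n_control_samples=100,
        seed=3,
    )
    return generate_cohort(design)


def two_family_design(seed: int, n_samples: int = 25) -> SimulationDesign:
    """Two compound families with disjoint strong co-expression blocks."""
    comps = [
        CompoundDesign(f"A{i}", "F1", n_samples, rho_by_module=[0.8, 0.8, 0.0, 0.0])
        for i in range(4)
    ] + [
        CompoundDesign(f"B{i}", "F2", n_samples, rho_by_module=[0.0, 0.0, 0.8, 0.8])
        for i in range(4)
    ]
    return SimulationDesign(
        n_genes=200,
        module_sizes=[35, 35, 35, 35],
        control_rho=[0.5, 0.5, 0.5, 0.5],
        n_control_samples=30,
        compounds=comps,
        seed=seed,
    )


@pytest.fixture
def family_cohort():
    return generate_cohort(two_family_design(0))


@pytest.fixture
def meta_two_compounds():
    rows = [
        {"sample_id": f"c{i}", "compound": "CONTROL", "is_control": True} for i in range(4)
    ] + [
        {"sample_id": f"a{i}", "compound": "drugA", "is_control": False} for i in range(3)
    ] + [
        {"sample_id": f"b{i}", "compound": "drugB", "is_control": False} for i in range(2)
    ]
    return SampleMetadata(pd.DataFrame(rows))
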