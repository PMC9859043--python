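from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncscape.expression import ExpressionDataset
from lncscape.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def sim_small():
    """A small planted simulation shared across tests (zero leakage)."""
    return generate(SimulationConfig.small(seed=7))


@pytest.fixture(scope="session")
def sim_leak():
    """Same scale with one leakage cell per planted gene and lineage-only
    specificity, so rule-variant behaviour is clean-cut."""
    return generate(
        SimulationConfig.small(
            seed=11, leakage_cells=1, frac_stage_specific=0.0, frac_lineage_specific=0.5
        )
    )


def build_dataset(tpm: np.ndarray, gene_class=None, lineages=None, stages=None) -> ExpressionDataset:
    """Construct a minimal valid ExpressionDataset from a raw matrix."""
    n_genes, n_cells = tpm.shape
    genes = [f"G{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    if gene_class is None:
        gene_class = ["lncRNA"] * n_genes
    if lineages is None:
        lineages = ["fGC"] * (n_cells // 2) + ["fSOMA"] * (n_cells - n_cells // 2)
    if stages is None:
        stages = ["mitotic"] * n_cells
    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "sex": ["female" if l.startswith("f") else "male" for l in lineages],
            "lineage": lineages,
            "stage": stages,
            "week": [10] * n_cells,
        }
    )
    return ExpressionDataset(
        pd.DataFrame(tpm, index=genes, columns=cells),
        pd.Series(gene_class, index=genes),
        meta,
    )


@pytest.fixture()
def make_dataset():
    return build_dataset
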