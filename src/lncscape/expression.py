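"""TPM expression matrices with cell metadata, and expressed-gene calling.

Two named expressed-gene filters are provided, reflecting the two definitions
in circulation for this kind of single-cell germ-cell atlas:

* ``landscape`` — a gene is expressed when its TPM exceeds 1 in at least two
  cells of the subset.
* ``methods`` — a gene is expressed when it is detected (per-cell TPM >= 1,
  inclusive by default) in more than two cells *and* its maximum TPM over the
  subset exceeds 3.  This is the stricter, formal definition and the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LINEAGES = ("fGC", "mGC", "fSOMA", "mSOMA")
FEMALE_LINEAGES = {"fGC", "fSOMA"}
REQUIRED_CELL_COLUMNS = ("cell_id", "sex", "lineage", "stage", "week")

FILTERS = ("landscape", "methods")


@dataclass(frozen=True)
class ExpressedSet:
    """Result of an expressed-gene filter: which genes, under which rule."""

    filter_name: str
    gene_ids: frozenset[str]
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)


class ExpressionDataset:
    """A genes x cells TPM matrix joined to per-cell metadata.

    ``tpm`` is a DataFrame indexed by gene_id with cell_id columns;
    ``gene_class`` maps each gene to ``coding`` or ``lncRNA``; ``cells`` is a
    DataFrame indexed by cell_id with columns sex, lineage, stage, week.
    NaN TPM entries are rejected at construction (never coerced to 0), as are
    negative values, duplicate ids and dimension mismatches.
    """

    def __init__(
        self,
        tpm: pd.DataFrame,
        gene_class: Mapping[str, str] | pd.Series,
        cells: pd.DataFrame,
        week_range: tuple[int, int] = (4, 26),
    ) -> None:
        tpm = tpm.astype(float)
        if tpm.isna().any().any():
            raise ValueError("TPM matrix contains NaN entries; refuse to treat as 0")
        if (tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        if tpm.index.duplicated().any():
            raise ValueError("duplicate gene_ids in matrix")
        if tpm.columns.duplicated().any():
            raise ValueError("duplicate cell_ids in matrix")
        cells = cells.copy()
        if "cell_id" in cells.columns:
            cells = cells.set_index("cell_id")
        missing = [c for c in REQUIRED_CELL_COLUMNS[1:] if c not in cells.columns]
        if missing:
            raise ValueError(f"cell metadata missing columns: {missing}")
        if cells.index.duplicated().any():
            raise ValueError("duplicate cell_ids in metadata")
        if set(tpm.columns) != set(cells.index):
            raise ValueError("matrix cell_ids and metadata cell_ids disagree")
        cells = cells.loc[tpm.columns]
        bad_sex = cells[(cells.lineage.isin(FEMALE_LINEAGES)) & (cells.sex != "female")]
        bad_sex2 = cells[(~cells.lineage.isin(FEMALE_LINEAGES)) & (cells.sex != "male")]
        if len(bad_sex) or len(bad_sex2):
            raise ValueError("lineage/sex inconsistency in cell metadata")
        lo, hi = week_range
        weeks = cells.week.astype(int)
        if ((weeks < lo) | (weeks > hi)).any():
            raise ValueError(f"gestational weeks outside configured range {week_range}")
        gene_class = pd.Series(gene_class)
        if not set(tpm.index) <= set(gene_class.index):
            raise ValueError("every matrix gene needs a gene_class")
        self.tpm = tpm
        self.gene_class = gene_class.loc[tpm.index]
        self.cells = cells

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def genes_of_class(self, gene_class: str) -> list[str]:
        return list(self.gene_class[self.gene_class == gene_class].index)

    def select_cells(self, selector=None, lineage=None, stage=None, sex=None) -> list[str]:
        """Resolve a cell subset: an explicit list, a boolean mask over the
        metadata, or lineage/stage/sex equality filters (combined with AND)."""
        if selector is not None:
            if callable(selector):
                mask = self.cells.apply(selector, axis=1)
                return list(self.cells.index[mask])
            return [c for c in selector]
        mask = pd.Series(True, index=self.cells.index)
        if lineage is not None:
            mask &= self.cells.lineage == lineage
        if stage is not None:
            mask &= self.cells.stage == stage
        if sex is not None:
            mask &= self.cells.sex == sex
        return list(self.cells.index[mask])

    def manifest(self) -> dict:
        """Accounting summary: totals per lineage/class and their consistency.

        ``germ + soma == total`` is checked here so metadata bookkeeping
        errors surface at load time rather than downstream.
        """
        by_lineage = self.cells.lineage.value_counts().to_dict()
        n_germ = sum(v for k, v in by_lineage.items() if k.endswith("GC"))
        n_soma = sum(v for k, v in by_lineage.items() if k.endswith("SOMA"))
        total = len(self.cells)
        if n_germ + n_soma != total:
            raise ValueError(
                f"cell partition does not sum: germ {n_germ} + soma {n_soma} != total {total}"
            )
        return {
            "n_cells": total,
            "n_germ": n_germ,
            "n_soma": n_soma,
            "cells_by_lineage": by_lineage,
            "n_genes": len(self.tpm),
            "n_coding": int((self.gene_class == "coding").sum()),
            "n_lncRNA": int((self.gene_class == "lncRNA").sum()),
        }

    def to_anndata(self):
        """Export as an AnnData (cells x genes) for external clustering tools."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.tpm.to_numpy().T,
            obs=self.cells.copy(),
            var=pd.DataFrame({"gene_class": self.gene_class}),
        )
        adata.var_names = self.tpm.index
        adata.obs_names = self.tpm.columns
        return adata


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def load_dataset(
    matrix_path: str | Path,
    meta_path: str | Path,
    gene_class: Mapping[str, str] | None = None,
    class_column: str = "gene_class",
) -> ExpressionDataset:
    """Load a TSV (genes x cells) or MatrixMarket matrix plus metadata TSV.

    MTX input expects sibling index files ``<stem>.genes.tsv`` and
    ``<stem>.cells.tsv``.  Gene classes come either from ``gene_class`` or
    from a ``gene_class`` column in the gene index / first matrix column.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(matrix_path).todense())
        genes = pd.read_csv(matrix_path.with_suffix(".genes.tsv"), sep="\t")
        cells_idx = pd.read_csv(matrix_path.with_suffix(".cells.tsv"), sep="\t", header=None)[0]
        tpm = pd.DataFrame(mat, index=genes["gene_id"], columns=cells_idx)
        if gene_class is None and class_column in genes.columns:
            gene_class = pd.Series(genes[class_column].to_numpy(), index=genes["gene_id"])
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if gene_class is None and class_column in df.columns:
            gene_class = df.pop(class_column)
        tpm = df
    if gene_class is None:
        raise ValueError("gene classes not provided and not present in matrix input")
    meta = pd.read_csv(meta_path, sep="\t")
    return ExpressionDataset(tpm, gene_class, meta)


def tpm_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell scaling of raw counts to TPM-style values: c * 1e6 / colsum."""
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("cannot TPM-normalise a cell with zero total counts")
    return counts * 1e6 / colsum


# ---------------------------------------------------------------------------
# expressed-gene filters
# ---------------------------------------------------------------------------


def call_expressed(
    ds: ExpressionDataset,
    cells_subset: Sequence[str] | None = None,
    filter_name: str = "methods",
    gene_class: str | None = None,
    inclusive: bool = True,
) -> ExpressedSet:
    """Apply one of the named expressed-gene filters over a cell subset.

    ``inclusive`` controls whether per-cell detection in the ``methods``
    filter is TPM >= 1 (default) or strictly > 1.
    """
    if filter_name not in FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    cells = list(ds.tpm.columns) if cells_subset is None else list(cells_subset)
    if not cells:
        raise ValueError("empty cell subset")
    sub = ds.tpm[cells]
    if gene_class is not None:
        sub = sub.loc[ds.gene_class == gene_class]
    if filter_name == "landscape":
        keep = (sub > 1).sum(axis=1) >= 2
        params = {"min_tpm": 1.0, "strict": True, "min_cells": 2}
    else:
        detected = sub >= 1 if inclusive else sub > 1
        keep = (detected.sum(axis=1) > 2) & (sub.max(axis=1) > 3)
        params = {"min_tpm": 1.0, "inclusive": inclusive, "min_cells_exclusive": 2, "max_tpm_gt": 3.0}
    return ExpressedSet(filter_name, frozenset(sub.index[keep]), params)


def per_cell_expressed_counts(ds: ExpressionDataset, min_tpm: float = 1.0) -> pd.DataFrame:
    """Number of detected genes per cell, split by gene class.

    Returns a DataFrame indexed by cell_id with columns ``lncRNA``, ``coding``
    and ``total`` plus the cell metadata, ready for grouping by week, lineage
    or stage.
    """
    detected = ds.tpm >= min_tpm
    out = pd.DataFrame(index=ds.tpm.columns)
    for cls in GENE_CLASSES_ORDER:
        out[cls] = detected.loc[ds.gene_class == cls].sum(axis=0)
    out["total"] = detected.sum(axis=0)
    return out.join(ds.cells)


GENE_CLASSES_ORDER = ("lncRNA", "coding")


def compare_groups(
    counts: pd.DataFrame,
    group_column: str,
    group_a: str,
    group_b: str,
    value_column: str = "lncRNA",
) -> dict:
    """Two-sample location test (Student's t) between per-cell count groups."""
    a = counts.loc[counts[group_column] == group_a, value_column]
    b = counts.loc[counts[group_column] == group_b, value_column]
    t, p = stats.ttest_ind(a, b)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": float(t),
        "p_value": float(p),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
    }


@dataclass(frozen=True)
class LncCodingRatio:
    n_lnc: int
    n_coding: int

    @property
    def ratio(self) -> float:
        return self.n_lnc / self.n_coding


def lnc_coding_ratio(expressed_lnc: ExpressedSet, expressed_coding: ExpressedSet) -> LncCodingRatio:
    """Ratio of expressed lncRNAs to expressed coding genes, with counts."""
    if len(expressed_coding) == 0:
        raise ValueError("no expressed coding genes; ratio undefined")
    return LncCodingRatio(len(expressed_lnc), len(expressed_coding))
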