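"""Cell-type- and stage-specific gene calling by the exclusion rule.

A gene is specific to a group when it is detected (TPM >= 1) in at least two
cells of that group while being essentially absent outside it.  Two variants
of "essentially absent" are in circulation for this atlas style and both are
first-class here:

* ``results`` — zero cells outside the group with TPM >= 1 (strict exclusion).
* ``methods`` — at most one cell outside the group with TPM >= 1 (the default;
  tolerates a single stray cell).

``results``-specific implies ``methods``-specific, and under ``results`` the
specific sets of distinct groups are provably disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .expression import ExpressionDataset

RULES = ("results", "methods")


@dataclass(frozen=True)
class SpecificitySet:
    target_group: str
    gene_ids: frozenset[str]
    evidence: pd.DataFrame  # per called gene: n_cells_in, n_cells_out (+ per-group counts)
    rule_variant: str

    def __len__(self) -> int:
        return len(self.gene_ids)


def _resolve_grouping(
    ds: ExpressionDataset,
    grouping: str | Mapping[str, str] | pd.Series,
    cell_index: Sequence[str],
) -> pd.Series:
    if isinstance(grouping, str):
        if grouping not in ds.cells.columns:
            raise ValueError(f"no metadata column {grouping!r} to group by")
        return ds.cells.loc[cell_index, grouping]
    groups = pd.Series(grouping)
    if not set(cell_index) <= set(groups.index):
        raise ValueError("grouping must cover every cell in the partition")
    return groups.loc[cell_index]


def call_specific(
    ds: ExpressionDataset,
    grouping: str | Mapping[str, str] | pd.Series = "lineage",
    rule_variant: str = "methods",
    min_tpm: float = 1.0,
    min_cells: int = 2,
    gene_class: str | None = "lncRNA",
    cells_subset: Sequence[str] | None = None,
) -> dict[str, SpecificitySet]:
    """Call group-specific genes for every group of a cell partition.

    ``grouping`` is a metadata column name (e.g. ``lineage`` or ``stage``) or
    an explicit cell -> group mapping partitioning all cells.  Groups with
    fewer than two cells are skipped with a warning.  Returns one
    SpecificitySet per retained group.
    """
    if rule_variant not in RULES:
        raise ValueError(f"unknown rule {rule_variant!r}; choose from {RULES}")
    cell_index = list(ds.tpm.columns) if cells_subset is None else list(cells_subset)
    groups = _resolve_grouping(ds, grouping, cell_index)
    tpm = ds.tpm[cell_index]
    if gene_class is not None:
        tpm = tpm.loc[ds.gene_class == gene_class]
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("specificity needs at least two groups; got a single-group partition")
    detected = tpm >= min_tpm
    per_group = detected.T.groupby(groups).sum().T  # genes x groups
    total = detected.sum(axis=1)
    max_out = 0 if rule_variant == "results" else 1
    out: dict[str, SpecificitySet] = {}
    for g in sorted(map(str, labels)):
        n_cells_in_group = int((groups == g).sum())
        if n_cells_in_group < 2:
            warnings.warn(f"group {g!r} has {n_cells_in_group} cell(s); skipped", stacklevel=2)
            continue
        n_in = per_group[g]
        n_out = total - n_in
        called = (n_in >= min_cells) & (n_out <= max_out)
        evidence = per_group.loc[called].copy()
        evidence.insert(0, "n_cells_in", n_in[called])
        evidence.insert(1, "n_cells_out", n_out[called])
        out[g] = SpecificitySet(g, frozenset(tpm.index[called]), evidence, rule_variant)
    return out


def stage_specific(
    ds: ExpressionDataset,
    lineage: str,
    rule_variant: str = "methods",
    min_tpm: float = 1.0,
    min_cells: int = 2,
    gene_class: str | None = "lncRNA",
    background: str = "lineage",
) -> dict[str, SpecificitySet]:
    """Stage-specific calling within one lineage.

    With ``background="lineage"`` (default) only cells of that lineage form
    the universe — the exclusion clause counts stray cells among the other
    stages of the *same* lineage.  ``background="all"`` keeps every other cell
    in the background instead.
    """
    if background not in ("lineage", "all"):
        raise ValueError("background must be 'lineage' or 'all'")
    in_lineage = ds.cells.lineage == lineage
    if not in_lineage.any():
        raise ValueError(f"no cells of lineage {lineage!r}")
    if background == "lineage":
        cells = list(ds.cells.index[in_lineage])
        grouping = ds.cells.loc[cells, "stage"]
        return call_specific(
            ds, grouping, rule_variant, min_tpm, min_cells, gene_class, cells_subset=cells
        )
    # all-cell background: other lineages become one pooled background group
    grouping = ds.cells.stage.where(in_lineage, other="__background__")
    result = call_specific(ds, grouping, rule_variant, min_tpm, min_cells, gene_class)
    result.pop("__background__", None)
    return result


def specificity_table(sets: Mapping[str, SpecificitySet]) -> pd.DataFrame:
    """Flatten specificity calls to a tidy gene/group table for export."""
    rows = []
    for g, s in sets.items():
        for gene in sorted(s.gene_ids):
            rows.append(
                {
                    "gene_id": gene,
                    "group": g,
                    "n_cells_in": int(s.evidence.loc[gene, "n_cells_in"]),
                    "n_cells_out": int(s.evidence.loc[gene, "n_cells_out"]),
                    "rule": s.rule_variant,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "group", "n_cells_in", "n_cells_out", "rule"])
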