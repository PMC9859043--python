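"""Expression correlation of lncRNA-mRNA pairs with random-pair nulls.

Pearson r is computed over the cells that express the pair's lncRNA (TPM >= 1
by default — the cell-selection rule for these pairs), or over an explicit
cell subset.  Observed pair correlations are compared against two nulls:
random lncRNA-coding pairs drawn from the *same* chromosome, and pairs whose
members sit on *different* chromosomes.  The comparison uses a rank-based
two-sample test (Mann-Whitney U), since the shape of the r distributions is
not known a priori.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .biotype import LocusPair
from .expression import ExpressionDataset

CELL_RULES = ("expressing", "all")


@dataclass(frozen=True)
class PairCorrelation:
    lnc_id: str
    coding_id: str
    r: float | None  # None = undefined (too few cells or zero variance), never 0
    n_cells: int
    cell_rule: str


@dataclass(frozen=True)
class NullComparison:
    observed: np.ndarray
    null_same_chrom: np.ndarray
    null_cross_chrom: np.ndarray
    n_missing: dict[str, int]
    summary: pd.DataFrame
    p_same: float
    p_cross: float
    seed: int
    n_draws: int


def pair_correlation(
    ds: ExpressionDataset,
    pair: LocusPair | tuple[str, str],
    cell_rule: str = "expressing",
    cells_subset: Sequence[str] | None = None,
    min_tpm: float = 1.0,
    min_cells: int = 3,
    log1p: bool = False,
) -> PairCorrelation:
    """Pearson correlation of one lncRNA-coding pair.

    ``cell_rule="expressing"`` restricts to cells with lncRNA TPM >=
    ``min_tpm``; ``"all"`` uses every cell of ``cells_subset`` (or all cells).
    r is reported missing (None) — never imputed as 0 — when fewer than
    ``min_cells`` cells remain or either vector has zero variance.
    """
    if cell_rule not in CELL_RULES:
        raise ValueError(f"unknown cell_rule {cell_rule!r}")
    lnc_id, coding_id = (pair.lnc_id, pair.coding_id) if isinstance(pair, LocusPair) else pair
    for g in (lnc_id, coding_id):
        if g not in ds.tpm.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    cols = list(ds.tpm.columns) if cells_subset is None else list(cells_subset)
    x = ds.tpm.loc[lnc_id, cols].to_numpy(dtype=float)
    y = ds.tpm.loc[coding_id, cols].to_numpy(dtype=float)
    if cell_rule == "expressing":
        mask = x >= min_tpm
        x, y = x[mask], y[mask]
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    n = len(x)
    if n < min_cells or np.ptp(x) == 0 or np.ptp(y) == 0:
        return PairCorrelation(lnc_id, coding_id, None, n, cell_rule)
    # product-moment formula
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return PairCorrelation(lnc_id, coding_id, min(1.0, max(-1.0, r)), n, cell_rule)


def _r_values(
    ds: ExpressionDataset,
    pairs: Iterable[tuple[str, str]],
    cell_rule: str,
    min_tpm: float,
    min_cells: int,
    log1p: bool,
) -> tuple[np.ndarray, int]:
    rs, missing = [], 0
    for lnc_id, coding_id in pairs:
        pc = pair_correlation(
            ds, (lnc_id, coding_id), cell_rule, None, min_tpm, min_cells, log1p
        )
        if pc.r is None:
            missing += 1
        else:
            rs.append(pc.r)
    return np.asarray(rs, dtype=float), missing


def null_comparison(
    ds: ExpressionDataset,
    genes: Sequence[GeneModel] | Mapping[str, str],
    true_pairs: Sequence[LocusPair | tuple[str, str]],
    n_draws: int = 200,
    seed: int = 0,
    cell_rule: str = "expressing",
    min_tpm: float = 1.0,
    min_cells: int = 3,
    log1p: bool = False,
) -> NullComparison:
    """Observed pair correlations vs same-chromosome and cross-chromosome nulls.

    ``genes`` supplies chromosome and class information (GeneModels, or a
    gene_id -> "chrom:class" is not supported — pass models).  Null pairs are
    drawn uniformly without replacement among lncRNA-coding combinations not
    in the true set; when fewer candidates exist than ``n_draws`` the draw
    count is reduced with a warning.  Undefined r values are counted, never
    imputed.
    """
    rng = np.random.default_rng(seed)
    chrom = {g.gene_id: g.chrom for g in genes}
    klass = {g.gene_id: g.gene_class for g in genes}
    in_matrix = set(ds.tpm.index)
    lncs = sorted(g for g, k in klass.items() if k == "lncRNA" and g in in_matrix)
    codings = sorted(g for g, k in klass.items() if k == "coding" and g in in_matrix)
    true = [
        (p.lnc_id, p.coding_id) if isinstance(p, LocusPair) else tuple(p) for p in true_pairs
    ]
    true_set = set(true)

    same = [
        (l, c)
        for l in lncs
        for c in codings
        if chrom[l] == chrom[c] and (l, c) not in true_set
    ]
    cross = [(l, c) for l in lncs for c in codings if chrom[l] != chrom[c]]

    def draw(candidates: list[tuple[str, str]], label: str) -> list[tuple[str, str]]:
        k = n_draws
        if len(candidates) < k:
            warnings.warn(
                f"only {len(candidates)} candidate {label} pairs; reducing draws from {k}",
                stacklevel=2,
            )
            k = len(candidates)
        idx = rng.choice(len(candidates), size=k, replace=False)
        return [candidates[i] for i in idx]

    obs_r, obs_miss = _r_values(ds, true, cell_rule, min_tpm, min_cells, log1p)
    same_r, same_miss = _r_values(ds, draw(same, "same-chromosome"), cell_rule, min_tpm, min_cells, log1p)
    cross_r, cross_miss = _r_values(ds, draw(cross, "cross-chromosome"), cell_rule, min_tpm, min_cells, log1p)

    def mwu(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) == 0 or len(b) == 0:
            return float("nan")
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    summary = pd.DataFrame(
        {
            "group": ["observed", "null_same_chrom", "null_cross_chrom"],
            "n": [len(obs_r), len(same_r), len(cross_r)],
            "mean_r": [np.mean(g) if len(g) else float("nan") for g in (obs_r, same_r, cross_r)],
            "median_r": [np.median(g) if len(g) else float("nan") for g in (obs_r, same_r, cross_r)],
        }
    )
    return NullComparison(
        observed=obs_r,
        null_same_chrom=same_r,
        null_cross_chrom=cross_r,
        n_missing={"observed": obs_miss, "null_same_chrom": same_miss, "null_cross_chrom": cross_miss},
        summary=summary,
        p_same=mwu(obs_r, same_r),
        p_cross=mwu(obs_r, cross_r),
        seed=seed,
        n_draws=n_draws,
    )
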