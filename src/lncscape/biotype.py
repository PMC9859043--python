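"""Six-way locus-biotype classification of lncRNA-coding gene pairs.

Each lncRNA is paired with its nearest protein-coding gene on the same
chromosome (edge-to-edge gap, ties broken by TSS distance then gene id) and
the pair geometry is labelled:

* ``XH`` — head-to-head / divergent antisense: TSS ends proximal, transcribed
  away from each other,
* ``XT`` — tail-to-tail / convergent antisense: transcription ends proximal,
* ``SU`` / ``SD`` — same-strand lncRNA upstream / downstream of the coding
  gene (relative to the coding gene's strand),
* ``XI`` — antisense lncRNA contained within the coding gene,
* ``XO`` — antisense lncRNA encompassing the coding gene,
* ``unpaired`` — no coding gene within the pairing distance.

Partial antisense overlaps that are neither containment are resolved by which
ends are proximal (TSS-proximal -> XH, TES-proximal -> XT; an exact tie takes
the lncRNA's strand as a flip-symmetric convention); identical intervals on
opposite strands are XO by convention.  Same-strand pairs compare locus
midpoints in the coding gene's orientation, which reduces to the usual
upstream/downstream reading for non-overlapping genes and stays well defined
for overlapping ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel
from .specificity import SpecificitySet

BIOTYPES = ("XH", "XT", "SD", "SU", "XI", "XO")
UNPAIRED = "unpaired"


@dataclass(frozen=True)
class LocusPair:
    lnc_id: str
    coding_id: str | None
    biotype: str
    tss_distance: int | None  # bp between the two TSS positions
    gene_gap: int | None  # bp between closest edges, 0 if overlapping

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES + (UNPAIRED,):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.tss_distance is not None and self.tss_distance < 0:
            raise ValueError("tss_distance must be non-negative")


def nearest_coding(
    lnc: GeneModel,
    coding: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> GeneModel | None:
    """Nearest same-chromosome coding gene by edge-to-edge gap.

    Overlap counts as gap 0.  Ties break by smaller TSS distance, then by
    lexicographic gene_id, so the choice is deterministic.  Returns None when
    the smallest gap exceeds ``max_distance`` (or no candidate shares the
    chromosome).
    """
    best: tuple[int, int, str] | None = None
    best_gene: GeneModel | None = None
    for cg in coding:
        if cg.chrom != lnc.chrom:
            continue
        key = (lnc.locus.gap_to(cg.locus), abs(lnc.tss - cg.tss), cg.gene_id)
        if best is None or key < best:
            best, best_gene = key, cg
    if best is None or best[0] > max_distance:
        return None
    return best_gene


def classify_pair(lnc: GeneModel, coding: GeneModel) -> str:
    """Label the locus geometry of one lncRNA-coding pair (see module doc)."""
    if lnc.chrom != coding.chrom:
        raise ValueError("pair members must share a chromosome")
    li, ci = lnc.locus, coding.locus
    if lnc.strand != coding.strand:
        if (li.start, li.end) == (ci.start, ci.end):
            return "XO"  # identical antisense spans: encompassing by convention
        if ci.contains(li):
            return "XI"
        if li.contains(ci):
            return "XO"
        d_tss = abs(lnc.tss - coding.tss)
        d_tes = abs(lnc.tes - coding.tes)
        if d_tss != d_tes:
            return "XH" if d_tss < d_tes else "XT"
        # exactly tied proximal ends (only possible for partial overlaps):
        # break by the lncRNA's strand, which keeps the label symmetric under
        # flipping both strands
        return "XH" if lnc.strand == "+" else "XT"
    # same strand: upstream/downstream relative to the coding gene's strand,
    # judged by locus midpoints (equivalent to the TSS/TES rule for disjoint
    # genes, and the comparison stays meaningful — and strand-flip symmetric —
    # for overlapping same-strand geometries)
    mid_l = li.start + li.end  # 2x midpoint, exact in integers
    mid_c = ci.start + ci.end
    if mid_l != mid_c:
        upstream = mid_l < mid_c if coding.strand == "+" else mid_l > mid_c
        return "SU" if upstream else "SD"
    return "SU" if lnc.strand == "+" else "SD"  # tied midpoints: flip-symmetric convention


def pair_lnc(
    lnc: GeneModel,
    coding: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> LocusPair:
    partner = nearest_coding(lnc, coding, max_distance)
    if partner is None:
        return LocusPair(lnc.gene_id, None, UNPAIRED, None, None)
    return LocusPair(
        lnc.gene_id,
        partner.gene_id,
        classify_pair(lnc, partner),
        abs(lnc.tss - partner.tss),
        lnc.locus.gap_to(partner.locus),
    )


def pair_all(
    lncs: Iterable[GeneModel],
    coding: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> list[LocusPair]:
    """Pair and classify every lncRNA; one partner and one label per lncRNA."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for cg in coding:
        by_chrom.setdefault(cg.chrom, []).append(cg)
    return [pair_lnc(l, by_chrom.get(l.chrom, ()), max_distance) for l in lncs]


def biotype_proportions(
    pairs: Iterable[LocusPair],
    stage_sets: Mapping[str, SpecificitySet] | Mapping[str, Iterable[str]],
    min_pairs: int = 20,
) -> pd.DataFrame:
    """Per-stage biotype percentage table over paired stage-specific lncRNAs.

    Stages whose paired-lncRNA count falls below ``min_pairs`` are kept in the
    table but flagged ``reported=False`` (their percentages are still
    computed).  Percentages are over assigned (non-unpaired) pairs and sum to
    100 per reported stage.
    """
    by_lnc = {p.lnc_id: p for p in pairs}
    rows = []
    for stage, s in stage_sets.items():
        gene_ids = s.gene_ids if isinstance(s, SpecificitySet) else set(s)
        stage_pairs = [by_lnc[g] for g in sorted(gene_ids) if g in by_lnc]
        assigned = [p for p in stage_pairs if p.biotype != UNPAIRED]
        row: dict = {"stage": stage, "n_pairs": len(assigned), "n_unpaired": len(stage_pairs) - len(assigned)}
        for bt in BIOTYPES:
            n = sum(1 for p in assigned if p.biotype == bt)
            row[f"n_{bt}"] = n
            row[f"pct_{bt}"] = 100.0 * n / len(assigned) if assigned else float("nan")
        row["reported"] = len(assigned) >= min_pairs
        rows.append(row)
    return pd.DataFrame(rows)


def pairs_table(pairs: Iterable[LocusPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "coding_id": p.coding_id or "",
                "biotype": p.biotype,
                "tss_distance": p.tss_distance if p.tss_distance is not None else "",
                "gap": p.gene_gap if p.gene_gap is not None else "",
            }
            for p in pairs
        ],
        columns=["lnc_id", "coding_id", "biotype", "tss_distance", "gap"],
    )
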