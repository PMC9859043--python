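"""Promoter extraction, PWM motif scanning and per-TF promoter coverage.

The screen asks, for each candidate transcription factor: in what fraction of
the stage-specific lncRNA promoters does its binding motif occur?  Promoters
are strand-aware windows around the TSS (default -2000/+100); scanning slides
a log-odds position weight matrix over the window and its reverse complement,
calling a hit when the score reaches a configurable fraction of the maximum
achievable score.  A TF passes the expression filter when its own gene is
expressed in the germ-cell group under study; candidates are TFs that pass
both the coverage floor and the expression filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneModel
from .expression import ExpressionDataset, call_expressed
from .specificity import SpecificitySet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)} | {"N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PROB_FLOOR = 1e-3  # pseudo-probability floor keeping log-odds finite


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position weight matrix in probability form (rows A, C, G, T)."""

    tf_name: str
    matrix: np.ndarray  # (4, L) column-stochastic
    background: np.ndarray = None  # (4,)
    score_threshold: float = 0.8  # fraction of the maximum log-odds score

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("probability PWM columns must sum to 1")
        object.__setattr__(self, "matrix", m)
        bg = np.full(4, 0.25) if self.background is None else np.asarray(self.background, float)
        object.__setattr__(self, "background", bg / bg.sum())
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds; row 4 (N) scores 0, i.e. as background."""
        p = np.maximum(self.matrix, PROB_FLOOR)
        lo = np.log2(p / self.background[:, None])
        return np.vstack([lo, np.zeros(self.length)])

    @property
    def max_score(self) -> float:
        return float(self.log_odds()[:4].max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


def load_jaspar(path: str | Path, score_threshold: float = 0.8) -> list[PWM]:
    """Parse a JASPAR plain-text PWM file via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            colsum = counts.sum(axis=0)
            if (colsum == 0).any():
                raise ValueError(f"motif {m.name}: zero-count column")
            out.append(PWM(m.name or m.matrix_id, counts / colsum, score_threshold=score_threshold))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write probability PWMs as JASPAR count matrices (probabilities x scale)."""
    lines = []
    for p in pwms:
        lines.append(f">{p.tf_name} {p.tf_name}")
        for bi, b in enumerate(BASES):
            vals = " ".join(str(int(round(v * scale))) for v in p.matrix[bi])
            lines.append(f"{b} [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------


def promoter_window(
    gene: GeneModel,
    genome: Mapping[str, str],
    upstream: int = 2000,
    downstream: int = 100,
) -> str:
    """Strand-aware promoter sequence around the TSS, 5'->3' for the gene.

    Plus strand: ``[tss - upstream, tss + downstream)``.  Minus strand: the
    mirror window on the other side, reverse-complemented.  Windows are
    clipped at chromosome ends.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} absent from genome")
    chrom_seq = str(genome[gene.chrom])
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream + 1, tss + upstream + 1
    lo, hi = max(0, lo), min(len(chrom_seq), hi)
    seq = chrom_seq[lo:hi].upper()
    return revcomp(seq) if gene.strand == "-" else seq


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq.upper()), dtype=np.int64, count=len(seq))


def _strand_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    L = lo.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[codes[j : j + n], j]
    return scores


def scan_sequence(seq: str, pwm: PWM) -> tuple[int, float]:
    """Slide the PWM over both strands; return (hit count, best score).

    A hit is a window scoring >= ``score_threshold * max_score``.  Sequences
    shorter than the motif yield 0 hits; N bases score as background (0).
    """
    codes = _encode(seq)
    lo = pwm.log_odds()
    fwd = _strand_scores(codes, lo)
    rev = _strand_scores(_encode(revcomp(seq)), lo)
    all_scores = np.concatenate([fwd, rev])
    if len(all_scores) == 0:
        return 0, float("-inf")
    cutoff = pwm.score_threshold * pwm.max_score
    return int((all_scores >= cutoff).sum()), float(all_scores.max())


@dataclass(frozen=True)
class CoverageReport:
    tf_name: str
    stage: str
    n_promoters: int
    n_hit: int
    expression_pass: bool | None  # None = TF gene absent from the matrix

    @property
    def fraction(self) -> float:
        return self.n_hit / self.n_promoters if self.n_promoters else float("nan")

    def is_candidate(self, min_fraction: float = 0.2) -> bool:
        return bool(self.expression_pass) and self.fraction >= min_fraction


def coverage_fraction(
    stage_set: SpecificitySet | Sequence[str],
    pwms: Sequence[PWM],
    ds: ExpressionDataset | None,
    germ_cells: Sequence[str] | None,
    genome: Mapping[str, str],
    genes: Mapping[str, GeneModel],
    upstream: int = 2000,
    downstream: int = 100,
    expressed_filter: str = "methods",
    stage_label: str | None = None,
) -> list[CoverageReport]:
    """Per-TF fraction of stage-specific lncRNA promoters carrying the motif.

    ``genes`` maps gene ids to models for promoter extraction; the TF's own
    expression is judged by ``call_expressed`` over ``germ_cells`` (matched by
    gene id or display name; absent TFs report ``expression_pass=None``).
    """
    gene_ids = sorted(stage_set.gene_ids if isinstance(stage_set, SpecificitySet) else stage_set)
    stage = stage_label or (stage_set.target_group if isinstance(stage_set, SpecificitySet) else "")
    promoters = [
        promoter_window(genes[g], genome, upstream, downstream) for g in gene_ids
    ]
    expressed = None
    name_to_id: dict[str, str] = {}
    if ds is not None and germ_cells:
        expressed = call_expressed(ds, germ_cells, expressed_filter, gene_class=None).gene_ids
        for g in genes.values():
            name_to_id.setdefault(g.name, g.gene_id)
    reports = []
    for pwm in pwms:
        n_hit = sum(1 for seq in promoters if scan_sequence(seq, pwm)[0] > 0)
        if expressed is None:
            epass: bool | None = None
        else:
            tf_id = pwm.tf_name if pwm.tf_name in ds.tpm.index else name_to_id.get(pwm.tf_name)
            epass = (tf_id in expressed) if tf_id is not None and tf_id in ds.tpm.index else None
        reports.append(CoverageReport(pwm.tf_name, stage, len(promoters), n_hit, epass))
    return reports
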