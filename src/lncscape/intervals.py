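"""Strand-aware genomic intervals.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Printed 1-based inclusive spans (GTF, genome-browser style) are converted on
input and restored on output.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, stranded genomic span.

    Invariants: ``start < end`` (length >= 1) and ``strand`` in ``{+, -}``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end} (start must be < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """Whole-interval containment on the same chromosome (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int, chrom: str | None = None) -> bool:
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start <= pos < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance; 0 when the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap length divided by the *longer* interval.

    This is the symmetric ("reciprocal") criterion: a fraction f here implies
    the overlap covers >= f of both intervals.
    """
    ov = a.overlap_len(b)
    if ov == 0:
        return 0.0
    return ov / max(a.length, b.length)
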