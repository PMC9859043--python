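"""Binned coverage tracks and input-normalised ChIP enrichment.

Aligned fragments are binned into fixed-width genomic bins (100 bp for browse
tracks, 10 bp for enrichment, both configurable), each fragment contributing
to every bin it overlaps in proportion to the overlapped fraction of its
length (so a fully in-bounds fragment contributes total mass 1).  Bin values
are normalised to RPKM — count / (bin kb x library size in millions) — which
makes tracks invariant to library duplication.  Enrichment over input is the
per-bin log2 ratio of ChIP RPKM to Input RPKM with a pseudocount keeping it
finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

Fragment = tuple[str, int, int]  # chrom, start, end (0-based half-open)


@dataclass
class BinnedTrack:
    chrom_sizes: dict[str, int]
    bin_width: int
    raw: dict[str, np.ndarray]  # weighted fragment counts per bin
    total_fragments: int

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            expected = math.ceil(size / self.bin_width)
            if len(self.raw[chrom]) != expected:
                raise ValueError(f"{chrom}: expected {expected} bins")

    @property
    def values(self) -> dict[str, np.ndarray]:
        """RPKM per bin: raw / (bin_width/1000 * total_fragments/1e6)."""
        if self.total_fragments == 0:
            return {c: np.zeros_like(v) for c, v in self.raw.items()}
        denom = (self.bin_width / 1000.0) * (self.total_fragments / 1e6)
        return {c: v / denom for c, v in self.raw.items()}

    def same_binning(self, other: "BinnedTrack") -> bool:
        return self.bin_width == other.bin_width and self.chrom_sizes == other.chrom_sizes


@dataclass
class EnrichmentTrack:
    chrom_sizes: dict[str, int]
    bin_width: int
    log2_ratio: dict[str, np.ndarray]
    pseudocount: float


def _as_fragment(f) -> Fragment:
    if isinstance(f, tuple):
        return f
    return (f.chrom, f.start, f.end)  # GenomicInterval-like


def dedupe_fragments(fragments: Iterable[Fragment]) -> list[Fragment]:
    """Drop exact-duplicate fragments (convenience; PCR-duplicate removal is
    normally done upstream on the alignments)."""
    seen: set[Fragment] = set()
    out = []
    for f in map(_as_fragment, fragments):
        if f not in seen:
            seen.add(f)
            out.append(f)
    return out


def bin_coverage(
    fragments: Iterable[Fragment],
    chrom_sizes: Mapping[str, int],
    bin_width: int = 100,
    mode: str = "weighted",
) -> BinnedTrack:
    """Bin fragments into fixed-width bins.

    ``mode="weighted"`` (default) spreads each fragment over the bins it
    overlaps by overlapped-length fraction; ``"midpoint"`` assigns the whole
    fragment to the bin containing its midpoint.  Out-of-bounds fragments are
    clipped with a warning; fragments on unknown chromosomes are dropped with
    a warning.  An empty library yields an all-zero track with
    ``total_fragments == 0``.
    """
    if mode not in ("weighted", "midpoint"):
        raise ValueError("mode must be 'weighted' or 'midpoint'")
    raw = {c: np.zeros(math.ceil(size / bin_width)) for c, size in chrom_sizes.items()}
    total = 0
    n_clipped = n_unknown = 0
    for chrom, start, end in map(_as_fragment, fragments):
        if chrom not in raw:
            n_unknown += 1
            continue
        if end <= start:
            continue
        total += 1
        size = chrom_sizes[chrom]
        cstart, cend = max(0, start), min(size, end)
        if (cstart, cend) != (start, end):
            n_clipped += 1
            if cend <= cstart:
                continue
        frag_len = end - start  # weight fraction uses the *original* length
        if mode == "midpoint":
            mid = (cstart + cend) // 2
            raw[chrom][mid // bin_width] += 1.0
            continue
        b0, b1 = cstart // bin_width, (cend - 1) // bin_width
        for b in range(b0, b1 + 1):
            lo, hi = b * bin_width, (b + 1) * bin_width
            ov = min(cend, hi) - max(cstart, lo)
            raw[chrom][b] += ov / frag_len
    if n_clipped:
        warnings.warn(f"{n_clipped} fragment(s) clipped at chromosome bounds", stacklevel=2)
    if n_unknown:
        warnings.warn(f"{n_unknown} fragment(s) on unknown chromosomes dropped", stacklevel=2)
    if total == 0:
        warnings.warn("zero usable fragments: all-zero track", stacklevel=2)
    return BinnedTrack(dict(chrom_sizes), bin_width, raw, total)


def log2_enrichment(
    chip: BinnedTrack, input_track: BinnedTrack, pseudocount: float = 0.5
) -> EnrichmentTrack:
    """Per-bin log2((ChIP RPKM + p) / (Input RPKM + p)); requires identical bins."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive to keep ratios finite")
    if not chip.same_binning(input_track):
        raise ValueError("ChIP and Input tracks must share bin width and chromosome sizes")
    cv, iv = chip.values, input_track.values
    ratio = {c: np.log2((cv[c] + pseudocount) / (iv[c] + pseudocount)) for c in cv}
    return EnrichmentTrack(dict(chip.chrom_sizes), chip.bin_width, ratio, pseudocount)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_fragments_bed(path: str | Path) -> list[Fragment]:
    """Read fragments from BED (first three columns used)."""
    out: list[Fragment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bedgraph(
    track: BinnedTrack | EnrichmentTrack, path: str | Path, precision: int = 4
) -> None:
    """Write per-bin values as bedGraph (consecutive equal bins not merged)."""
    values = track.log2_ratio if isinstance(track, EnrichmentTrack) else track.values
    with open(path, "w") as fh:
        for chrom in sorted(values):
            size = track.chrom_sizes[chrom]
            v = values[chrom]
            for b, val in enumerate(v):
                start = b * track.bin_width
                end = min(size, start + track.bin_width)
                fh.write(f"{chrom}\t{start}\t{end}\t{val:.{precision}f}\n")
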