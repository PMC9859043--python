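"""Gene models from GTF/BED annotation, annotated/unannotated status, and
genomic-region assignment of lncRNA loci.

Two annotation sources (one for protein-coding genes, one for lncRNAs — in the
human germ-cell setting these emulate a GENCODE coding annotation merged with a
NONCODE lncRNA catalog) are ingested into a single strand-aware gene model.
A lncRNA is *annotated* when it matches a record in both reference catalogs
(configurable to "either"), and *unannotated* otherwise.  Region categories
for lncRNA loci are assigned by a fixed priority list evaluated at the lncRNA
TSS against coding-gene features.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, reciprocal_overlap

GENE_CLASSES = ("coding", "lncRNA")

REGION_PRIORITY = (
    "TSS",
    "promoter",
    "5'UTR",
    "exon",
    "intron",
    "3'UTR",
    "TTS",
    "other-ncRNA-overlap",
    "intergenic",
)


class AnnotationParseError(ValueError):
    """Malformed annotation input; message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: locus, class, and (for lncRNAs) annotation status.

    ``tss`` is the transcription start site in 0-based coordinates:
    ``locus.start`` on the plus strand and ``locus.end - 1`` on the minus
    strand, so it always lies inside the locus.  ``tes`` is the opposite end.
    """

    gene_id: str
    name: str
    locus: GenomicInterval
    gene_class: str
    annotation_status: str | None = None
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"gene_class must be one of {GENE_CLASSES}")
        if self.annotation_status not in (None, "annotated", "unannotated"):
            raise ValueError(f"bad annotation_status {self.annotation_status!r}")

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def tss(self) -> int:
        return self.locus.start if self.strand == "+" else self.locus.end - 1

    @property
    def tes(self) -> int:
        return self.locus.end - 1 if self.strand == "+" else self.locus.start


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def _read_gtf_genes(path: str | Path, gene_class: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    sub: dict[str, dict[str, list[GenomicInterval]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if end1 < start1:
                raise AnnotationParseError(f"{path}:{lineno}: end < start")
            attributes = _parse_gtf_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if feature in ("gene", "exon", "five_prime_utr", "three_prime_utr", "UTR") and not gene_id:
                raise AnnotationParseError(f"{path}:{lineno}: missing gene_id attribute")
            if strand not in ("+", "-"):
                if feature == "gene":
                    warnings.warn(
                        f"{path}:{lineno}: gene {gene_id!r} has no strand; excluded",
                        stacklevel=2,
                    )
                continue
            # GTF is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if feature == "gene":
                name = attributes.get("gene_name", gene_id)
                genes.append(GeneModel(gene_id, name, iv, gene_class))
            elif feature == "exon":
                sub.setdefault(gene_id, {}).setdefault("exons", []).append(iv)
            elif feature == "five_prime_utr":
                sub.setdefault(gene_id, {}).setdefault("utr5", []).append(iv)
            elif feature == "three_prime_utr":
                sub.setdefault(gene_id, {}).setdefault("utr3", []).append(iv)
    out = []
    for g in genes:
        s = sub.get(g.gene_id)
        if s:
            g = replace(
                g,
                exons=tuple(sorted(s.get("exons", ()))),
                utr5=tuple(sorted(s.get("utr5", ()))),
                utr3=tuple(sorted(s.get("utr3", ()))),
            )
        out.append(g)
    return out


def _read_bed_genes(path: str | Path, gene_class: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-"):
                warnings.warn(
                    f"{path}:{lineno}: record {name!r} has no strand; excluded",
                    stacklevel=2,
                )
                continue
            genes.append(
                GeneModel(name, name, GenomicInterval(chrom, start, end, strand), gene_class)
            )
    return genes


def _read_genes(path: str | Path, gene_class: str) -> list[GeneModel]:
    suffix = Path(path).suffix.lower()
    if suffix in (".bed", ".bed6"):
        return _read_bed_genes(path, gene_class)
    return _read_gtf_genes(path, gene_class)


def load_annotation(
    coding_path: str | Path | None,
    lnc_path: str | Path | None,
) -> list[GeneModel]:
    """Load coding and lncRNA annotation sources into one gene model list.

    Either path may be None (or point at an empty file) to load only one
    class.  A gene_id that occurs in both sources keeps the coding record's id
    and the lncRNA copy is disambiguated with the suffix ``__lnc``; duplicate
    ids *within* one source are rejected.
    """
    coding = _read_genes(coding_path, "coding") if coding_path else []
    lnc = _read_genes(lnc_path, "lncRNA") if lnc_path else []
    for src_name, src in (("coding", coding), ("lncRNA", lnc)):
        ids = [g.gene_id for g in src]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationParseError(f"duplicate gene_ids within {src_name} source: {dup}")
    coding_ids = {g.gene_id for g in coding}
    merged = list(coding)
    for g in lnc:
        if g.gene_id in coding_ids:
            g = replace(g, gene_id=g.gene_id + "__lnc")
        merged.append(g)
    return merged


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene (and exon/UTR) records as ensembl-dialect GTF.

    Internal half-open coordinates are restored to 1-based inclusive, so a
    load/write cycle preserves the printed coordinates exactly.
    """
    rows = []
    for g in genes:
        attrs = (
            f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
            f'gene_type "{"protein_coding" if g.gene_class == "coding" else "lncRNA"}";'
        )
        rows.append(
            f"{g.chrom}\tlncscape\tgene\t{g.locus.start + 1}\t{g.locus.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for feat, ivs in (("exon", g.exons), ("five_prime_utr", g.utr5), ("three_prime_utr", g.utr3)):
            for iv in ivs:
                rows.append(
                    f"{iv.chrom}\tlncscape\t{feat}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# annotated / unannotated status
# ---------------------------------------------------------------------------

Catalog = Sequence[GenomicInterval] | Iterable[str]


def _matches_catalog(
    gene: GeneModel,
    catalog_ids: set[str],
    catalog_intervals: list[GenomicInterval],
    min_overlap: float,
) -> bool:
    if gene.gene_id in catalog_ids or gene.name in catalog_ids:
        return True
    for iv in catalog_intervals:
        if iv.strand == gene.strand and reciprocal_overlap(gene.locus, iv) >= min_overlap:
            return True
    return False


def _split_catalog(catalog: Catalog) -> tuple[set[str], list[GenomicInterval]]:
    ids: set[str] = set()
    ivs: list[GenomicInterval] = []
    for entry in catalog:
        if isinstance(entry, GenomicInterval):
            ivs.append(entry)
        elif isinstance(entry, GeneModel):
            ids.add(entry.gene_id)
            ivs.append(entry.locus)
        else:
            ids.add(str(entry))
    return ids, ivs


def classify_annotation_status(
    lncs: Iterable[GeneModel],
    catalog_a: Catalog,
    catalog_b: Catalog,
    min_overlap: float = 0.5,
    require: str = "both",
) -> list[GeneModel]:
    """Tag each lncRNA as annotated or unannotated against two catalogs.

    A lncRNA matches a catalog when its id is listed or when some catalog
    interval on the same strand overlaps it reciprocally by >= ``min_overlap``.
    With ``require="both"`` (default) it is annotated only when it matches both
    catalogs; ``require="any"`` accepts either.
    """
    if require not in ("both", "any"):
        raise ValueError("require must be 'both' or 'any'")
    ids_a, ivs_a = _split_catalog(catalog_a)
    ids_b, ivs_b = _split_catalog(catalog_b)
    if not (ids_a or ivs_a) or not (ids_b or ivs_b):
        raise ValueError("reference catalogs must be non-empty")
    out = []
    for g in lncs:
        in_a = _matches_catalog(g, ids_a, ivs_a, min_overlap)
        in_b = _matches_catalog(g, ids_b, ivs_b, min_overlap)
        hit = (in_a and in_b) if require == "both" else (in_a or in_b)
        out.append(replace(g, annotation_status="annotated" if hit else "unannotated"))
    return out


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionAssignment:
    gene_id: str
    category: str
    overlap_basis: str | None = None  # coding gene (or ncRNA) whose feature matched

    def __post_init__(self) -> None:
        if self.category not in REGION_PRIORITY:
            raise ValueError(f"unknown region category {self.category!r}")


def assign_region(
    lnc: GeneModel,
    coding: Sequence[GeneModel],
    promoter_window: int = 1000,
    tss_window: int = 100,
    tts_window: int = 1000,
    other_ncrna: Sequence[GeneModel] = (),
) -> RegionAssignment:
    """Assign one genomic-region category to a lncRNA locus.

    The lncRNA TSS is tested against coding-gene features in the fixed
    priority order TSS > promoter > 5'UTR > exon > intron > 3'UTR > TTS
    (> other-ncRNA-overlap) > intergenic.  "Promoter" means within
    ``promoter_window`` bp upstream of a coding TSS (strand-aware); "TTS"
    means within ``tts_window`` bp downstream of a coding TES.  Coding genes
    without exon sub-features fall back to whole-gene = exon.
    """
    pos = lnc.tss
    hits: dict[str, str] = {}

    def record(cat: str, gid: str) -> None:
        hits.setdefault(cat, gid)

    for cg in coding:
        if cg.chrom != lnc.chrom:
            continue
        if abs(pos - cg.tss) <= tss_window:
            record("TSS", cg.gene_id)
        if cg.strand == "+":
            if cg.tss - promoter_window <= pos < cg.tss:
                record("promoter", cg.gene_id)
            if cg.tes < pos <= cg.tes + tts_window:
                record("TTS", cg.gene_id)
        else:
            if cg.tss < pos <= cg.tss + promoter_window:
                record("promoter", cg.gene_id)
            if cg.tes - tts_window <= pos < cg.tes:
                record("TTS", cg.gene_id)
        if cg.locus.contains_point(pos, lnc.chrom):
            in_utr = False
            if any(iv.contains_point(pos, lnc.chrom) for iv in cg.utr5):
                record("5'UTR", cg.gene_id)
                in_utr = True
            if any(iv.contains_point(pos, lnc.chrom) for iv in cg.utr3):
                record("3'UTR", cg.gene_id)
                in_utr = True
            if cg.exons:
                if any(iv.contains_point(pos, lnc.chrom) for iv in cg.exons):
                    record("exon", cg.gene_id)
                elif not in_utr:  # UTR positions are not introns
                    record("intron", cg.gene_id)
            else:
                record("exon", cg.gene_id)  # whole-gene fallback
    for ng in other_ncrna:
        if ng.gene_id != lnc.gene_id and ng.locus.contains_point(pos, lnc.chrom):
            record("other-ncRNA-overlap", ng.gene_id)
    for cat in REGION_PRIORITY:
        if cat in hits:
            return RegionAssignment(lnc.gene_id, cat, hits[cat])
    return RegionAssignment(lnc.gene_id, "intergenic", None)


def genes_to_table(genes: Iterable[GeneModel], regions: Mapping[str, RegionAssignment] | None = None):
    """Flatten gene models (plus optional region assignments) to a DataFrame."""
    import pandas as pd

    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "name": g.name,
                "chrom": g.chrom,
                "start": g.locus.start,
                "end": g.locus.end,
                "strand": g.strand,
                "gene_class": g.gene_class,
                "annotation_status": g.annotation_status or "",
                "region": regions[g.gene_id].category if regions and g.gene_id in regions else "",
            }
        )
    return pd.DataFrame(rows)
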