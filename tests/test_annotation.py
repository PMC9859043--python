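import warnings

import pytest
from hypothesis import given, settings, strategies as st

from lncscape.annotation import (
    AnnotationParseError,
    GeneModel,
    assign_region,
    classify_annotation_status,
    load_annotation,
    write_gtf,
)
from lncscape.intervals import GenomicInterval, reciprocal_overlap
from lncscape.simulate import generate_region_fixture

GTF_LINE = (
    '{chrom}\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\t'
    'gene_id "{gid}"; gene_name "{gid}"; gene_type "{gtype}";\n'
)


def write_lines(path, lines):
    path.write_text("".join(lines))
    return str(path)


def test_gtf_one_based_inclusive_converts_to_half_open(tmp_path):
    """A 1-based inclusive span [75122518, 75123927] becomes the half-open
    interval [75122517, 75123927) of length 1410."""
    coding = write_lines(tmp_path / "c.gtf", [])
    lnc = write_lines(
        tmp_path / "l.gtf",
        [GTF_LINE.format(chrom="chr1", start=75122518, end=75123927, strand="-", gid="LNC1845", gtype="lncRNA")],
    )
    genes = load_annotation(coding, lnc)
    (g,) = genes
    assert (g.locus.start, g.locus.end) == (75122517, 75123927)
    assert g.locus.length == 1410
    assert g.gene_class == "lncRNA"
    assert g.tss == 75123926  # minus strand: 5' end at the interval's right edge


def test_gtf_round_trip_preserves_printed_coordinates(tmp_path):
    genes = [
        GeneModel("A", "A", GenomicInterval("chr1", 99, 500, "+"), "coding"),
        GeneModel("B", "B", GenomicInterval("chr2", 0, 10, "-"), "coding"),
        GeneModel("C", "C", GenomicInterval("chr1", 1234, 6789, "-"), "coding"),
    ]
    p = tmp_path / "rt.gtf"
    write_gtf(genes, p)
    # printed 1-based starts are internal start + 1
    fields = [l.split("\t") for l in p.read_text().splitlines()]
    assert [(f[3], f[4]) for f in fields] == [("100", "500"), ("1", "10"), ("1235", "6789")]
    reloaded = load_annotation(p, None)
    assert [(g.gene_id, g.locus, g.strand) for g in reloaded] == [
        (g.gene_id, g.locus, g.strand) for g in genes
    ]


def test_empty_lnc_source_gives_coding_only(tmp_path):
    coding = write_lines(
        tmp_path / "c.gtf",
        [GTF_LINE.format(chrom="chr1", start=1, end=100, strand="+", gid="P1", gtype="protein_coding")],
    )
    lnc = write_lines(tmp_path / "l.gtf", [])
    genes = load_annotation(coding, lnc)
    assert [g.gene_class for g in genes] == ["coding"]


def test_strandless_gene_excluded_with_warning(tmp_path):
    lnc = write_lines(
        tmp_path / "l.gtf",
        [
            GTF_LINE.format(chrom="chr1", start=1, end=100, strand=".", gid="NOSTRAND", gtype="lncRNA"),
            GTF_LINE.format(chrom="chr1", start=200, end=300, strand="+", gid="OK", gtype="lncRNA"),
        ],
    )
    with pytest.warns(UserWarning, match="NOSTRAND"):
        genes = load_annotation(None, lnc)
    assert [g.gene_id for g in genes] == ["OK"]


def test_malformed_line_error_names_line_number(tmp_path):
    lnc = write_lines(
        tmp_path / "l.gtf",
        [
            GTF_LINE.format(chrom="chr1", start=1, end=100, strand="+", gid="OK", gtype="lncRNA"),
            "chr1\tbroken line without tabs\n",
        ],
    )
    with pytest.raises(AnnotationParseError, match=":2:"):
        load_annotation(None, lnc)


def test_duplicate_ids(tmp_path):
    line = GTF_LINE.format(chrom="chr1", start=1, end=100, strand="+", gid="DUP", gtype="x")
    dup_within = write_lines(tmp_path / "dup.gtf", [line, line])
    with pytest.raises(AnnotationParseError, match="DUP"):
        load_annotation(dup_within, None)
    # across sources: lncRNA copy gets a documented suffix
    coding = write_lines(tmp_path / "c.gtf", [line])
    lnc = write_lines(tmp_path / "l.gtf", [line])
    ids = [g.gene_id for g in load_annotation(coding, lnc)]
    assert ids == ["DUP", "DUP__lnc"]


def test_bed6_source(tmp_path):
    bed = tmp_path / "cat.bed"
    bed.write_text("chr1\t100\t500\tL1\t0\t+\nchr1\t600\t900\tL2\t0\t-\n")
    genes = load_annotation(None, bed)
    assert [(g.gene_id, g.locus.start, g.locus.end, g.strand) for g in genes] == [
        ("L1", 100, 500, "+"),
        ("L2", 600, 900, "-"),
    ]


# ---------------------------------------------------------------------------
# annotation status
# ---------------------------------------------------------------------------


def _lnc(i, start, chrom="chr1", strand="+", length=400):
    return GeneModel(f"L{i}", f"L{i}", GenomicInterval(chrom, start, start + length, strand), "lncRNA")


def test_planted_catalog_membership_recovered():
    """100 lncRNAs, 40 planted in both catalogs -> exactly those 40 annotated."""
    lncs = [_lnc(i, 1000 * i) for i in range(100)]
    in_both = {g.gene_id for g in lncs[:40]}
    catalog_a = [g for g in lncs if g.gene_id in in_both]
    catalog_b = list(lncs)  # all recorded in the NONCODE-like catalog
    tagged = classify_annotation_status(lncs, catalog_a, catalog_b)
    annotated = {g.gene_id for g in tagged if g.annotation_status == "annotated"}
    assert annotated == in_both
    assert all(g.annotation_status == "unannotated" for g in tagged if g.gene_id not in in_both)


def test_only_one_catalog_is_unannotated_by_default_but_any_switch_flips():
    lnc = [_lnc(0, 100)]
    only_b = classify_annotation_status(lnc, [_lnc(99, 900_000)], lnc)
    assert only_b[0].annotation_status == "unannotated"
    any_mode = classify_annotation_status(lnc, [_lnc(99, 900_000)], lnc, require="any")
    assert any_mode[0].annotation_status == "annotated"


def test_overlap_match_requires_same_strand_and_fraction():
    g = _lnc(0, 1000, strand="+", length=1000)
    half = GenomicInterval("chr1", 1000, 1500, "+")  # 50% reciprocal overlap
    assert reciprocal_overlap(g.locus, half) == 0.5
    tagged = classify_annotation_status([g], [half], [half], min_overlap=0.5)
    assert tagged[0].annotation_status == "annotated"
    opposite = GenomicInterval("chr1", 1000, 2000, "-")
    tagged = classify_annotation_status([g], [opposite], [opposite])
    assert tagged[0].annotation_status == "unannotated"


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_enlarging_a_catalog_never_unannotates(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    lncs = [_lnc(i, int(rng.integers(0, 50_000))) for i in range(20)]
    pick = lambda: [g for g in lncs if rng.random() < 0.5] or [lncs[0]]
    cat_a, cat_b, extra = pick(), pick(), pick()
    before = classify_annotation_status(lncs, cat_a, cat_b)
    after = classify_annotation_status(lncs, cat_a + extra, cat_b)
    for b, a in zip(before, after):
        if b.annotation_status == "annotated":
            assert a.annotation_status == "annotated"


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------


def test_planted_region_categories_recovered_exactly():
    coding, placed = generate_region_fixture(n_per_category=4, seed=3)
    for lnc, intended in placed:
        got = assign_region(lnc, coding)
        assert got.category == intended, (lnc.gene_id, intended, got)


def test_region_priority_tss_inside_exon_and_promoter_window():
    cg = GeneModel("C", "C", GenomicInterval("chr1", 10_000, 20_000, "+"), "coding")
    inside = GeneModel("L1", "L1", GenomicInterval("chr1", 15_000, 15_400, "+"), "lncRNA")
    assert assign_region(inside, [cg]).category == "exon"  # whole-gene fallback
    upstream = GeneModel("L2", "L2", GenomicInterval("chr1", 9_500, 9_900, "+"), "lncRNA")
    assert assign_region(upstream, [cg], promoter_window=1000).category == "promoter"
    nothing_near = GeneModel("L3", "L3", GenomicInterval("chr1", 90_000, 90_400, "+"), "lncRNA")
    assert assign_region(nothing_near, [cg]).category == "intergenic"


def test_region_assignment_translation_invariant():
    coding, placed = generate_region_fixture(n_per_category=2, seed=5)
    shift = 12_345

    def shifted_gene(g):
        return GeneModel(
            g.gene_id, g.name, g.locus.shift(shift), g.gene_class,
            exons=tuple(iv.shift(shift) for iv in g.exons),
            utr5=tuple(iv.shift(shift) for iv in g.utr5),
            utr3=tuple(iv.shift(shift) for iv in g.utr3),
        )

    coding_s = [shifted_gene(g) for g in coding]
    for lnc, _ in placed:
        before = assign_region(lnc, coding).category
        after = assign_region(shifted_gene(lnc), coding_s).category
        assert before == after
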