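# Methods

## Coordinates and gene models

All internal coordinates are 0-based half-open `[start, end)`. GTF input
(1-based inclusive) is converted on load and restored on write, so a
load/write cycle preserves printed coordinates exactly. Printed
genome-browser-style spans are interpreted as half-open; this choice makes the
span `chr1:75,122,517–75,123,927` of the single-isoform divergent lncRNA
measure 1410 nt, equal to its reported transcript length, which is the
consistency the convention is anchored to. The TSS of a gene is `start` on
the plus strand and `end − 1` on the minus strand, so it always lies inside
the locus. Strandless records are excluded at load time (with a warning)
rather than defaulted, because every downstream biotype call depends on
strand. Duplicate gene ids within one source are an error; a collision across
the coding and lncRNA sources renames the lncRNA copy with the suffix
`__lnc`.

## Annotation status

A lncRNA is *annotated* when it matches a record in both reference catalogs
and *unannotated* otherwise. A match is an id match or a reciprocal interval
overlap on the same strand of at least `min_overlap` (default 0.5, defined
against the longer interval so the criterion is symmetric). The texts this
analysis style derives from alternate between "included in both databases"
and "unannotated in both" readings; the `require={both,any}` switch exposes
the choice, with `both` the default. Enlarging a catalog can only move genes
toward `annotated` (monotonicity, property-tested).

## Region categories

Each lncRNA TSS is assigned one category by a fixed priority list:
TSS > promoter > 5′UTR > exon > intron > 3′UTR > TTS > other-ncRNA-overlap >
intergenic. "TSS" means within ±100 bp of a coding TSS, "promoter" within
1000 bp upstream of a coding TSS (strand-aware), "TTS" within 1000 bp
downstream of a coding TES; all three windows are parameters. Coding genes
without exon sub-features fall back to whole-gene = exon; positions inside a
UTR are never counted as intronic. This is a deliberately simple, documented
priority scheme, not a re-implementation of any particular annotation tool's
internals — published analyses of this kind report only category proportions,
which do not constrain the tool's tie-breaking.

## Expressed-gene filters

Two named presets reflect the two definitions that circulate for germ-cell
atlases: `landscape` keeps a gene with TPM > 1 in at least two cells of the
subset; `methods` (default, the stricter formal definition) requires
detection (TPM ≥ 1; a flag switches to strict >) in more than two cells *and*
a maximum TPM above 3. The methods set is provably contained in the
landscape set, which is asserted on random matrices. NaN TPM values are
rejected at load time, never coerced to zero. TPM is taken as input; a
counts-to-TPM helper (`counts × 10⁶ / column sum`) covers the case where only
counts are at hand.

## Specificity

A gene is specific to a group when detected (TPM ≥ 1) in ≥ 2 of its cells and
in at most *k* cells outside: k = 0 (`results`) or k = 1 (`methods`,
default). `results`-specific implies `methods`-specific, and under `results`
the specific sets of different groups are disjoint. Stage-specificity is
called within one lineage; by default only same-lineage cells form the
background (the stages of a lineage are clustered within it), with
`background="all"` as the alternative. Partitions with fewer than two groups
are refused; groups with fewer than two cells are skipped with a warning.

## Locus biotypes

Each lncRNA is paired with its nearest same-chromosome coding gene by
edge-to-edge gap (overlap = 0), with ties broken by TSS distance and then by
gene id so runs are reproducible; pairs farther than `max_distance` (default
10 kb — no cutoff is stated in the scheme this follows, and XH fractions
depend on it, so it is echoed in output headers) are `unpaired`. The label
logic, in order:

1. identical antisense spans → XO (convention);
2. antisense containment: lncRNA inside the coding gene → XI, encompassing it
   → XO;
3. other antisense geometries → XH when the TSS ends are the proximal pair,
   XT when the transcription ends are; an exact tie (possible only for
   partial overlaps) takes the lncRNA's strand (+ → XH), a convention chosen
   because it is equivariant under flipping both strands;
4. same-strand pairs → SU/SD by comparing locus midpoints in the coding
   gene's orientation. For disjoint genes this is exactly the usual
   "upstream of the coding TSS / downstream of the coding TES" reading; for
   overlapping same-strand genes (which the upstream/downstream wording does
   not address) the midpoint comparison remains well defined and keeps the
   SU↔SD strand-flip symmetry that TSS-based comparisons violate.

The classifier is checked against an independently written brute-force
decision table over an exhaustive geometry sweep, and satisfies
translation invariance and the double-strand-flip symmetry
(XH↔XT, SU↔SD, XI/XO fixed). Per-stage biotype percentage tables are
computed over each stage's paired specific lncRNAs; stages with fewer than
`min_pairs` (default 20) assigned pairs are flagged unreported.

## Pair correlation and nulls

Pearson r is computed from the product-moment formula on TPM (a `log1p`
option exists) over the cells that express the pair's lncRNA at TPM ≥ 1 —
the cell-selection rule for these pairs — or over an explicit subset. r is
reported *missing*, never zero, when fewer than 3 cells remain or either
vector is constant; the 3-cell floor is this package's choice where the
source texts are silent. Null pairs are drawn uniformly without replacement:
same-chromosome lncRNA–coding pairs excluding the true pairs, and
cross-chromosome pairs. Observed-vs-null location is compared with a
two-sided Mann–Whitney U test (the r distributions' shapes are unknown, so a
rank test is safer than a t-test), and both mean and median are reported.
All draws are governed by an explicit seed.

## Promoter motif coverage

Promoters are strand-aware windows around the TSS, default −2000/+100
(no window is published for the prediction service this step abstracts, so
the default is a common promoter convention and is logged with every output).
PWMs are read from JASPAR text via Bio.motifs; probabilities are floored at
10⁻³ before log₂-odds against the background so scores stay finite. A window
position is a hit when its score reaches `score_threshold ×` the maximum
achievable score; both the sequence and its reverse complement are scanned,
so hit counts are double-strand symmetric, and `N` scores as background (0).
Per TF, the coverage fraction is the share of stage-specific lncRNA promoters
with ≥ 1 hit (presence/absence, matching the "promoters containing the
motif" framing); coverage is non-increasing in the threshold. A TF is a
candidate when its own gene passes the expressed filter in the germ-cell
group and its coverage exceeds a floor. The eight TFs bundled with the
simulator (CEBPA, HNF1A, GATA1, TFAP2A, FOXA1, PAX5, STAT4, FOXP3) are an
example configuration with synthetic consensus matrices, not measured binding
models.

## ChIP enrichment

Fragments are binned at fixed width (100 bp for browse tracks, 10 bp for
enrichment; both configurable). Each fragment contributes to every bin it
overlaps, weighted by the overlapped fraction of its length, so a fully
in-bounds fragment deposits total mass 1 (conservation is property-tested);
a midpoint-assignment mode is available. Bin values are RPKM
(`count / (bin_kb × library_millions)`), invariant under library duplication.
Enrichment is `log2((ChIP_RPKM + p) / (Input_RPKM + p))` with pseudocount
p = 0.5 RPKM by default (the sources are silent; the value is recorded in
track metadata), requiring identical binning of the two tracks. No smoothing
or read extension is applied. Exact-duplicate removal is offered as a
convenience only; PCR-duplicate handling belongs upstream.

## Synthetic data

The generator emulates the structure of a fetal-gonad single-cell atlas:
600 cells by default in a 3:1 germ:soma split (fGC 225, mGC 225, fSOMA 75,
mSOMA 75 — the published atlas proportions scaled down), stage taxonomies
fGC = {mitotic, RA responsive, meiotic, oogenesis}, mGC = {migrating,
mitotic, mitotic arrest}, granulosa/Leydig subtypes for the somatic lineages,
and gestational weeks 5–26 (female) / 4–25 (male). Genes live in 20 kb slots
interleaved round-robin across chromosomes; each paired lncRNA's geometry is
constructed to realize its intended biotype and verified at generation time
against the classifier and the nearest-gene rule, failing loudly rather than
emitting inconsistent truth.

Expression is log-normal TPM on "on" cells (per-gene ln-mean uniform on
[1, 3], σ = 0.8) with per-lineage Bernoulli dropout (germ 0.25, soma 0.45 —
chosen so germ cells express visibly more lncRNAs, as in the real atlas);
planted specific genes are "on" only in their target group plus exactly
`leakage_cells` planted stray cells, and the generator verifies that the
matching rule recovers every planted label exactly before returning. Planted
pair correlations use a Gaussian copula whose latent correlation is
moment-adjusted (the standard Nataf transform for log-normal marginals,
`ρ_z = ln(1 + ρ(e^{σ²} − 1))/σ²`) so the Pearson correlation of the TPM
values hits the configured target in expectation; pair genes skip dropout
inside the target group so the expressing-cell selection keeps the whole
group. Half of the XH lncRNAs are pinned to the two germ lineages so planted
correlations can be measured over ≥ 100 expressing cells at default scale.

Motif instances are the TF consensus sequences written at recorded,
non-overlapping promoter offsets in `round(rate × n)` of the meiotic-stage
promoters; accidental exact-consensus occurrences elsewhere in those windows
are mutated away, so at threshold 1.0 the measured coverage equals the
planted fraction exactly. ChIP and Input fragments (10⁵ each, 150 bp) are
drawn over a 1 Mb region, with ChIP start positions up-weighted 8-fold where
the fragment would overlap the planted 500 bp peak, giving an expected peak
log2 ratio of `log2(8 × Z_in/Z_chip) ≈ 2.99`.

What the generator does **not** emulate: per-cell library-size variation and
TPM compositionality (values are drawn per gene and not renormalised to sum
to 10⁶ — renormalisation would induce small negative correlations that
contaminate the planted-correlation truth), batch effects, doublets, UMI
noise, realistic promoter/motif sequence composition, and fragment-length
variation. Passing tests therefore demonstrate that the *rules and
estimators* are implemented correctly and recover planted parameters, not
that they are robust to every artefact of real single-cell data.

## Scales and numerical choices

The default synthetic scale (≈ 2,000 genes × 600 cells, 30 Mb genome,
2 × 10⁵ ChIP fragments) runs the full pipeline in a few seconds on one CPU;
the test suite uses a smaller preset (96 genes × 112 cells) for unit-level
checks and the full scale for end-to-end validation. Pearson r values are
clamped to [−1, 1] against floating-point drift. Largest-remainder rounding
allocates integer counts to fractions (biotype mix, stage sizes)
deterministically. All randomness flows from a single `numpy` Generator per
run, making every output byte-reproducible for a fixed seed and
configuration.

## Known limitations

* Biotypes are gene-level; transcript isoforms and multi-partner pairings are
  out of scope.
* The region-category scheme is a priority heuristic; proportions are not
  comparable to any specific annotation tool's output.
* The motif screen is presence/absence at a fraction-of-max threshold; it
  does not model binding affinity or positional preference within the
  promoter.
* No peak calling or differential-binding statistics; enrichment tracks are
  for inspection and downstream tools.
* The headline counts of the real atlas (tens of thousands of expressed
  lncRNAs) depend on the full GEO dataset and specific aligner/annotation
  versions, and are out of desk-scale scope; the acceptance script recovers
  in-text arithmetic and planted parameters instead.
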