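# lncscape

Landscape analysis of long non-coding RNA (lncRNA) expression in single-cell
transcriptomes of developing gonads — the kind of atlas in which female and
male germ cells (fGC, mGC) and their somatic neighbours (fSOMA, mSOMA) are
profiled by single-cell RNA-seq across gestational weeks, and in which most
expressed lncRNAs are absent from the standard annotation.

The package is aimed at computational biologists who have a TPM matrix over a
mixed coding + lncRNA annotation and want to reproduce, on their own data, the
standard chain of lncRNA landscape analyses:

1. **Expressed-gene calling** with two named filters: `landscape`
   (TPM > 1 in ≥ 2 cells) and `methods` (detected at TPM ≥ 1 in > 2 cells and
   max TPM > 3), plus per-cell expressed-gene counts and lncRNA:coding ratios.
2. **Annotation status** — a lncRNA is *annotated* iff it matches a record in
   both reference catalogs (e.g. a GENCODE lncRNA GTF and a NONCODE BED), by
   id or by reciprocal interval overlap ≥ 0.5 on the same strand.
3. **Cell-type / stage specificity** by the exclusion rule: detected in ≥ 2
   cells of the target group and in at most *k* cells outside it, with
   k = 0 (`results` variant) or k = 1 (`methods` variant, default).
4. **Locus biotypes** — each lncRNA is paired with its nearest protein-coding
   gene (edge gap, then TSS distance, then id) and labelled
   XH (head-to-head/divergent), XT (tail-to-tail), SU/SD (same-strand
   upstream/downstream), XI (antisense within) or XO (antisense encompassing),
   with per-stage biotype percentage tables.
5. **Pair correlation** — Pearson *r* over the cells expressing the pair's
   lncRNA, compared against random same-chromosome and cross-chromosome
   lncRNA–mRNA pairs with a rank-based two-sample test.
6. **Promoter motif coverage** — strand-aware promoter windows (default
   −2000/+100 around the TSS), log-odds PWM scanning on both strands, and the
   per-TF fraction of stage-specific lncRNA promoters carrying the motif,
   filtered by whether the TF itself is expressed in the germ-cell group.
7. **ChIP enrichment tracks** — fixed-width binned coverage (RPKM) of
   ChIP and Input fragment sets and per-bin log2(ChIP/Input) bedGraph tracks.

A fully seeded synthetic-data generator (`lncscape.simulate`) produces every
input the pipeline consumes — annotation with planted pair geometries,
catalogs with planted membership, a TPM matrix with planted lineage/stage
structure and planted pair correlations, a genome with motifs planted in
promoters, and ChIP/Input fragments with planted peaks — together with a
`ground_truth.json` so every module can be validated end to end without any
download.

## Worked example

```python
from lncscape import (SimulationConfig, generate, call_specific, pair_all,
                      biotype_proportions, null_comparison)
from lncscape.specificity import stage_specific

res = generate(SimulationConfig(seed=0))          # ~2,000 genes x 600 cells
ds = res.dataset

specific = call_specific(ds, "lineage", rule_variant="methods")
print({lin: len(s) for lin, s in specific.items()})

pairs = pair_all(res.lncs, res.coding, max_distance=10_000)
stages = stage_specific(ds, "fGC", rule_variant="methods")
table = biotype_proportions(pairs, stages, min_pairs=10)
print(table[["stage", "n_pairs", "pct_XH", "pct_XT", "reported"]].round(1))

gt = res.ground_truth
true_pairs = [(l, gt.biotype[l]["partner"]) for l in gt.pair_rho]
nc = null_comparison(ds, res.coding + res.lncs, true_pairs, n_draws=200, seed=0)
print(nc.summary.round(3))
```

prints

```
{'fGC': 177, 'fSOMA': 35, 'mGC': 153, 'mSOMA': 35}
        stage  n_pairs  pct_XH  pct_XT  reported
RA responsive       23    17.4    21.7      True
      meiotic       23    13.0    26.1      True
      mitotic       23    17.4    43.5      True
    oogenesis       23     8.7    26.1      True
           group   n  mean_r  median_r
        observed 200   0.514     0.505
 null_same_chrom 163  -0.005    -0.004
null_cross_chrom 167   0.002    -0.001
```

Reading: 177 lncRNAs are fGC-specific under the tolerant exclusion rule
(germ lineages carry far more specific lncRNAs than somatic ones, as planted);
each fGC stage has 23 paired stage-specific lncRNAs whose biotype percentages
sum to 100; and the divergent (XH) pairs planted at Pearson ρ = 0.5 show a
mean observed r of 0.514 while both random-pair null groups sit at ≈ 0.

The same stages run from the shell:

```bash
lncscape simulate --seed 0 --out sim/
lncscape annotate --coding-gtf sim/genes_coding.gtf --lnc-gtf sim/genes_lnc.gtf \
    --catalog-a sim/catalog_a.bed --catalog-b sim/catalog_b.bed --out genes.tsv
lncscape specific --matrix sim/matrix.tsv --meta sim/cells.tsv \
    --group-by lineage --rule methods --out specific.tsv
lncscape chip --chip sim/chip_fragments.bed --input sim/input_fragments.bed \
    --bin 10 --pseudo 0.5 --out track.bedGraph
lncscape run --config run.yaml     # full pipeline with a manifest.json
```

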