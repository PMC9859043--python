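"""End-to-end orchestration of the landscape analysis.

``run_landscape`` executes annotation -> expression -> specificity -> biotype
-> correlation (-> motifs, -> chip when configured) on one configuration and
writes per-stage tables plus a machine-readable ``manifest.json`` whose
header echoes every threshold, so a run is reproducible from its outputs.
Any stage failure aborts with the failing stage named.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from .biotype import pair_all, pairs_table, biotype_proportions
from .correlation import null_comparison
from .expression import call_expressed, lnc_coding_ratio, load_dataset, per_cell_expressed_counts
from .motifs import coverage_fraction, load_jaspar
from .chip import bin_coverage, log2_enrichment, read_fragments_bed, write_bedgraph
from .specificity import call_specific, specificity_table, stage_specific

log = logging.getLogger("lncscape")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    # inputs
    coding_gtf: str = ""
    lnc_gtf: str = ""
    catalog_a: str = ""
    catalog_b: str = ""
    matrix: str = ""
    cells: str = ""
    genome: str = ""
    pwms: str = ""
    chip: str = ""
    input: str = ""
    # rule variants and thresholds
    expressed_filter: str = "methods"
    specificity_rule: str = "methods"
    min_tpm: float = 1.0
    max_distance: int = 10_000
    catalog_overlap: float = 0.5
    catalog_require: str = "both"
    promoter_upstream: int = 2000
    promoter_downstream: int = 100
    motif_stage: str = "meiotic"
    motif_lineage: str = "fGC"
    chip_bin: int = 10
    pseudocount: float = 0.5
    min_biotype_pairs: int = 20
    nulls: int = 200
    seed: int = 0
    export_combined: bool = False
    outdir: str = "lncscape_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> dict:
        skip = {"coding_gtf", "lnc_gtf", "catalog_a", "catalog_b", "matrix", "cells",
                "genome", "pwms", "chip", "input", "outdir"}
        return {k: v for k, v in asdict(self).items() if k not in skip}


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def run_landscape(config: RunConfig) -> dict:
    """Run the configured stages in order; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"thresholds": config.thresholds(), "stages": {}, "outputs": {}}

    # --- annotation --------------------------------------------------------
    @_stage("annotation")
    def do_annotation():
        genes = ann.load_annotation(config.coding_gtf or None, config.lnc_gtf or None)
        coding = [g for g in genes if g.gene_class == "coding"]
        lncs = [g for g in genes if g.gene_class == "lncRNA"]
        if lncs and config.catalog_a and config.catalog_b:
            cat_a = ann._read_bed_genes(config.catalog_a, "lncRNA")
            cat_b = ann._read_bed_genes(config.catalog_b, "lncRNA")
            lncs = ann.classify_annotation_status(
                lncs, cat_a, cat_b,
                min_overlap=config.catalog_overlap, require=config.catalog_require,
            )
        regions = {l.gene_id: ann.assign_region(l, coding) for l in lncs}
        table = ann.genes_to_table(coding + lncs, regions)
        table.to_csv(out / "genes.tsv", sep="\t", index=False)
        return coding, lncs

    coding, lncs = do_annotation()
    manifest["stages"]["annotation"] = {
        "n_coding": len(coding),
        "n_lncRNA": len(lncs),
        "n_annotated": sum(1 for g in lncs if g.annotation_status == "annotated"),
        "n_unannotated": sum(1 for g in lncs if g.annotation_status == "unannotated"),
    }
    manifest["outputs"]["genes"] = "genes.tsv"

    # --- expression --------------------------------------------------------
    @_stage("expression")
    def do_expression():
        ds = load_dataset(config.matrix, config.cells)
        counts = per_cell_expressed_counts(ds, config.min_tpm)
        counts.to_csv(out / "per_cell_counts.tsv", sep="\t", index_label="cell_id")
        expressed = {}
        ratios = {}
        for lineage in sorted(ds.cells.lineage.unique()):
            sel = ds.select_cells(lineage=lineage)
            e_lnc = call_expressed(ds, sel, config.expressed_filter, gene_class="lncRNA")
            e_cod = call_expressed(ds, sel, config.expressed_filter, gene_class="coding")
            expressed[lineage] = {"lncRNA": sorted(e_lnc.gene_ids), "coding": sorted(e_cod.gene_ids)}
            if len(e_cod):
                rr = lnc_coding_ratio(e_lnc, e_cod)
                ratios[lineage] = {"n_lnc": rr.n_lnc, "n_coding": rr.n_coding, "ratio": rr.ratio}
        pd.DataFrame(
            [
                {"lineage": lin, "gene_class": cls, "gene_id": g}
                for lin, d in expressed.items()
                for cls, gs in d.items()
                for g in gs
            ]
        ).to_csv(out / "expressed.tsv", sep="\t", index=False)
        return ds, expressed, ratios

    ds, expressed, ratios = do_expression()
    manifest["stages"]["expression"] = {
        "manifest": ds.manifest(),
        "filter": config.expressed_filter,
        "n_expressed_lnc": {k: len(v["lncRNA"]) for k, v in expressed.items()},
        "n_expressed_coding": {k: len(v["coding"]) for k, v in expressed.items()},
        "lnc_coding_ratio": ratios,
    }
    manifest["outputs"]["expressed"] = "expressed.tsv"
    manifest["outputs"]["per_cell_counts"] = "per_cell_counts.tsv"

    # --- specificity -------------------------------------------------------
    @_stage("specificity")
    def do_specificity():
        lineage_sets = call_specific(ds, "lineage", rule_variant=config.specificity_rule,
                                     min_tpm=config.min_tpm)
        stage_sets = {}
        for lineage in ("fGC", "mGC"):
            if (ds.cells.lineage == lineage).any():
                stage_sets[lineage] = stage_specific(
                    ds, lineage, rule_variant=config.specificity_rule, min_tpm=config.min_tpm
                )
        specificity_table(lineage_sets).to_csv(out / "specific_lineage.tsv", sep="\t", index=False)
        flat = {f"{lin}:{st}": s for lin, d in stage_sets.items() for st, s in d.items()}
        specificity_table(flat).to_csv(out / "specific_stage.tsv", sep="\t", index=False)
        return lineage_sets, stage_sets

    lineage_sets, stage_sets = do_specificity()
    manifest["stages"]["specificity"] = {
        "rule": config.specificity_rule,
        "n_lineage_specific": {k: len(v) for k, v in lineage_sets.items()},
        "n_stage_specific": {
            lin: {st: len(s) for st, s in d.items()} for lin, d in stage_sets.items()
        },
    }
    manifest["outputs"]["specific_lineage"] = "specific_lineage.tsv"
    manifest["outputs"]["specific_stage"] = "specific_stage.tsv"

    # --- biotype -----------------------------------------------------------
    @_stage("biotype")
    def do_biotype():
        pairs = pair_all(lncs, coding, config.max_distance)
        pairs_table(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
        props = {}
        for lineage, d in stage_sets.items():
            props[lineage] = biotype_proportions(pairs, d, config.min_biotype_pairs)
            props[lineage].to_csv(out / f"biotype_{lineage}.tsv", sep="\t", index=False)
        return pairs, props

    pairs, props = do_biotype()
    manifest["stages"]["biotype"] = {
        "max_distance": config.max_distance,
        "n_paired": sum(1 for p in pairs if p.biotype != "unpaired"),
        "n_unpaired": sum(1 for p in pairs if p.biotype == "unpaired"),
        "proportions": {
            lin: df.to_dict(orient="records") for lin, df in props.items()
        },
    }
    manifest["outputs"]["pairs"] = "pairs.tsv"

    # --- correlation -------------------------------------------------------
    @_stage("correlation")
    def do_correlation():
        germ_specific = set()
        for lin in ("fGC", "mGC"):
            if lin in lineage_sets:
                germ_specific |= lineage_sets[lin].gene_ids
        true_pairs = [p for p in pairs if p.biotype == "XH" and p.lnc_id in germ_specific]
        if not true_pairs:
            return None, None
        nc = null_comparison(
            ds, coding + lncs, true_pairs, n_draws=config.nulls, seed=config.seed
        )
        nc.summary.to_csv(out / "correlation_summary.tsv", sep="\t", index=False)
        rows = [
            {"group": grp, "r": float(v)}
            for grp, arr in (
                ("observed", nc.observed),
                ("null_same_chrom", nc.null_same_chrom),
                ("null_cross_chrom", nc.null_cross_chrom),
            )
            for v in arr
        ]
        pd.DataFrame(rows).to_csv(out / "correlation_r.tsv", sep="\t", index=False)
        return true_pairs, nc

    true_pairs, nc = do_correlation()
    if nc is not None:
        manifest["stages"]["correlation"] = {
            "n_true_pairs": len(true_pairs),
            "summary": nc.summary.to_dict(orient="records"),
            "p_vs_same_chrom": nc.p_same,
            "p_vs_cross_chrom": nc.p_cross,
            "n_missing": nc.n_missing,
            "seed": nc.seed,
        }
        manifest["outputs"]["correlation"] = "correlation_summary.tsv"
    else:
        manifest["stages"]["correlation"] = {"skipped": True, "reason": "no XH pairs"}

    # --- motifs (optional) -------------------------------------------------
    if config.genome and config.pwms:
        @_stage("motifs")
        def do_motifs():
            from Bio import SeqIO

            genome = {r.id: str(r.seq) for r in SeqIO.parse(config.genome, "fasta")}
            pwms = load_jaspar(config.pwms, score_threshold=1.0)
            lin, stg = config.motif_lineage, config.motif_stage
            stage_set = stage_sets.get(lin, {}).get(stg)
            if stage_set is None or not stage_set.gene_ids:
                return []
            gene_map = {g.gene_id: g for g in lncs}
            germ = ds.select_cells(lineage=lin)
            reports = coverage_fraction(
                stage_set, pwms, ds, germ, genome, gene_map,
                config.promoter_upstream, config.promoter_downstream,
                config.expressed_filter,
            )
            pd.DataFrame(
                [
                    {
                        "tf": r.tf_name, "stage": r.stage, "n_promoters": r.n_promoters,
                        "n_hit": r.n_hit, "fraction": r.fraction,
                        "expression_pass": r.expression_pass,
                    }
                    for r in reports
                ]
            ).to_csv(out / "motif_coverage.tsv", sep="\t", index=False)
            return reports

        reports = do_motifs()
        manifest["stages"]["motifs"] = {
            "stage": f"{config.motif_lineage}:{config.motif_stage}",
            "window": [config.promoter_upstream, config.promoter_downstream],
            "coverage": {
                r.tf_name: {"fraction": r.fraction, "expression_pass": r.expression_pass}
                for r in reports
            },
        }
        manifest["outputs"]["motif_coverage"] = "motif_coverage.tsv"
    else:
        manifest["stages"]["motifs"] = {"skipped": True}

    # --- chip (optional) ---------------------------------------------------
    if config.chip and config.input:
        @_stage("chip")
        def do_chip():
            chip_frags = read_fragments_bed(config.chip)
            input_frags = read_fragments_bed(config.input)
            hi = {}
            for c, s, e in chip_frags + input_frags:
                hi[c] = max(hi.get(c, 0), e)
            sizes = {c: int(v) for c, v in hi.items()}
            chip_track = bin_coverage(chip_frags, sizes, config.chip_bin)
            input_track = bin_coverage(input_frags, sizes, config.chip_bin)
            enr = log2_enrichment(chip_track, input_track, config.pseudocount)
            write_bedgraph(enr, out / "enrichment.bedGraph")
            stats = {
                c: {"mean": float(v.mean()), "max": float(v.max())}
                for c, v in enr.log2_ratio.items()
            }
            return stats

        manifest["stages"]["chip"] = {
            "bin": config.chip_bin,
            "pseudocount": config.pseudocount,
            "summary": do_chip(),
        }
        manifest["outputs"]["enrichment"] = "enrichment.bedGraph"
    else:
        manifest["stages"]["chip"] = {"skipped": True}

    if config.export_combined:
        combined = ds.tpm.copy()
        combined.insert(0, "gene_class", ds.gene_class)
        combined.to_csv(out / "combined_matrix.tsv", sep="\t", index_label="gene_id")
        manifest["outputs"]["combined_matrix"] = "combined_matrix.tsv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
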