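"""Synthetic-data generator with planted ground truth.

Generates every input the pipeline consumes — annotation with planted
locus-biotype geometries and catalog membership, a single-cell TPM matrix
with planted lineage/stage structure and specific lncRNAs, correlated
divergent (XH) pairs, a genome with motif instances planted in promoters, and
ChIP/Input fragment sets with planted peaks — from explicit parameters and a
seed.  The planted truth is serialized alongside the outputs so that every
module's output can be checked against what was put in.

The emulated study design is a human fetal-gonad single-cell atlas: four
lineages (female/male germ cells fGC/mGC and somatic cells fSOMA/mSOMA) with
named developmental stages (fGC: mitotic, RA responsive, meiotic, oogenesis;
mGC: migrating, mitotic, mitotic arrest; granulosa and Leydig sub-types for
the somatic lineages), a germ:soma cell ratio of roughly 3:1, and a mixed
coding + lncRNA gene annotation.  Expression is modelled as log-normal TPM on
"on" cells with per-lineage Bernoulli dropout; planted pair correlations use
a Gaussian copula whose latent correlation is moment-adjusted (Nataf) so the
Pearson correlation of the log-normal marginals hits the configured target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gtf
from .biotype import BIOTYPES, UNPAIRED, classify_pair, nearest_coding
from .expression import ExpressionDataset
from .intervals import GenomicInterval
from .motifs import PWM, revcomp, write_jaspar

SLOT_WIDTH = 20_000
SLOT_OFFSET = 3_000  # first slot starts here so promoter windows never clip
_CODING_OFFSET = 8_000  # coding gene start within its slot

STAGES = {
    "fGC": ("mitotic", "RA responsive", "meiotic", "oogenesis"),
    "mGC": ("migrating", "mitotic", "mitotic arrest"),
    "fSOMA": ("early granulosa", "mural granulosa", "late granulosa"),
    "mSOMA": ("Leydig precursor", "differentiated Leydig"),
}
WEEK_RANGES = {"female": (5, 26), "male": (4, 25)}

TF_CONSENSUS = {
    "CEBPA": "TTGCGCAAT",
    "HNF1A": "GGTTAATGA",
    "GATA1": "CTATCTCAG",
    "TFAP2A": "GCCCTAGGG",
    "FOXA1": "TGTTTACTT",
    "PAX5": "GGCACTGAG",
    "STAT4": "TTCCAGGAA",
    "FOXP3": "TGTTTGCTT",
}
DEFAULT_PLANT_RATES = {
    "CEBPA": 0.21,
    "HNF1A": 0.30,
    "GATA1": 0.40,
    "TFAP2A": 0.50,
    "FOXA1": 0.60,
    "PAX5": 0.70,
    "STAT4": 0.80,
    "FOXP3": 0.89,
}
# which of the example TFs are themselves expressed in female germ cells
DEFAULT_TF_IN_FGC = {
    "CEBPA": False,
    "HNF1A": False,
    "GATA1": True,
    "TFAP2A": True,
    "FOXA1": True,
    "PAX5": False,
    "STAT4": False,
    "FOXP3": True,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 5_000_000 for i in range(1, 7)}
    )
    n_coding: int = 1200
    n_lnc: int = 800
    biotype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "XH": 0.25, "XT": 0.15, "SD": 0.12, "SU": 0.12,
            "XI": 0.08, "XO": 0.08, UNPAIRED: 0.20,
        }
    )
    max_pair_distance: int = 10_000
    annotated_fraction: float = 0.33  # roughly a third of real-gonad lncRNAs are annotated
    lineage_sizes: dict[str, int] = field(
        default_factory=lambda: {"fGC": 225, "mGC": 225, "fSOMA": 75, "mSOMA": 75}
    )
    stage_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "fGC": {"mitotic": 0.30, "RA responsive": 0.15, "meiotic": 0.35, "oogenesis": 0.20},
            "mGC": {"migrating": 0.20, "mitotic": 0.40, "mitotic arrest": 0.40},
            "fSOMA": {"early granulosa": 0.40, "mural granulosa": 0.40, "late granulosa": 0.20},
            "mSOMA": {"Leydig precursor": 0.50, "differentiated Leydig": 0.50},
        }
    )
    # expression model
    log_mu_range: tuple[float, float] = (1.0, 3.0)  # per-gene ln-TPM mean
    log_sigma: float = 0.8
    dropout: dict[str, float] = field(
        default_factory=lambda: {"fGC": 0.25, "mGC": 0.25, "fSOMA": 0.45, "mSOMA": 0.45}
    )
    # lncRNA specificity plan (fractions of n_lnc)
    frac_lineage_specific: float = 0.30
    frac_stage_specific: float = 0.20
    frac_broad: float = 0.35
    leakage_cells: int = 0  # stray expressing cells outside the target group
    # planted Pearson correlation for true XH pairs
    pair_rho: float = 0.5
    # motifs
    plant_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PLANT_RATES))
    tf_in_fgc: dict[str, bool] = field(default_factory=lambda: dict(DEFAULT_TF_IN_FGC))
    promoter_upstream: int = 2000
    promoter_downstream: int = 100
    # chip
    chip_region_length: int = 1_000_000
    chip_n_fragments: int = 100_000
    chip_fragment_length: int = 150
    chip_peaks: list[dict] = field(
        default_factory=lambda: [{"start": 500_000, "width": 500, "fold": 8.0}]
    )

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """A scaled-down configuration for fast tests."""
        defaults = dict(
            seed=seed,
            chrom_lengths={"chr1": 1_200_000, "chr2": 1_200_000},
            n_coding=48,
            n_lnc=48,
            lineage_sizes={"fGC": 40, "mGC": 40, "fSOMA": 16, "mSOMA": 16},
            chip_region_length=200_000,
            chip_n_fragments=20_000,
            chip_peaks=[{"start": 100_000, "width": 500, "fold": 8.0}],
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """The planted parameters, in the shapes the pipeline is expected to recover."""

    biotype: dict[str, dict]  # lnc_id -> {biotype, partner, tss_distance}
    catalog_membership: dict[str, dict]  # lnc_id -> {in_a, in_b, status}
    specificity_label: dict[str, str | None]  # lnc_id -> lineage:X / stage:L:S / broad / silent
    lineage_specific: dict[str, list[str]]
    stage_specific: dict[str, dict[str, list[str]]]
    leakage_cells: int
    pair_rho: dict[str, float]  # lnc_id -> planted Pearson target
    motif_plants: dict[str, dict]  # tf -> {rate, planted, fraction, consensus, expressed_in_fgc}
    chip_peaks: list[dict]
    chip_region: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulationResult:
    config: SimulationConfig
    coding: list[GeneModel]
    lncs: list[GeneModel]
    catalog_a: list[GeneModel]  # GENCODE-like lncRNA catalog (subset)
    catalog_b: list[GeneModel]  # NONCODE-like catalog (all lncRNAs)
    dataset: ExpressionDataset
    genome: dict[str, str]
    pwms: list[PWM]
    chip_fragments: list[tuple[str, int, int]]
    input_fragments: list[tuple[str, int, int]]
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize every output as plain-text files; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {k: out / v for k, v in {
            "coding_gtf": "genes_coding.gtf", "lnc_gtf": "genes_lnc.gtf",
            "catalog_a": "catalog_a.bed", "catalog_b": "catalog_b.bed",
            "matrix": "matrix.tsv", "cells": "cells.tsv", "genome": "genome.fa",
            "pwms": "pwms.jaspar", "chip": "chip_fragments.bed",
            "input": "input_fragments.bed", "ground_truth": "ground_truth.json",
        }.items()}
        write_gtf(self.coding, paths["coding_gtf"])
        write_gtf(self.lncs, paths["lnc_gtf"])
        for key, cat in (("catalog_a", self.catalog_a), ("catalog_b", self.catalog_b)):
            with open(paths[key], "w") as fh:
                for g in cat:
                    fh.write(f"{g.chrom}\t{g.locus.start}\t{g.locus.end}\t{g.gene_id}\t0\t{g.strand}\n")
        matrix = self.dataset.tpm.copy()
        matrix.insert(0, "gene_class", self.dataset.gene_class)
        matrix.to_csv(paths["matrix"], sep="\t", float_format="%.4f", index_label="gene_id")
        self.dataset.cells.to_csv(paths["cells"], sep="\t", index_label="cell_id")
        with open(paths["genome"], "w") as fh:
            for chrom in self.genome:
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_jaspar(self.pwms, paths["pwms"])
        for key, frags in (("chip", self.chip_fragments), ("input", self.input_fragments)):
            with open(paths[key], "w") as fh:
                for chrom, s, e in frags:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        paths["ground_truth"].write_text(self.ground_truth.to_json() + "\n")
        return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _largest_remainder(fracs: Sequence[float], total: int) -> list[int]:
    """Integer allocation of `total` by fractions, exact and deterministic."""
    raw = [f * total for f in fracs]
    counts = [int(math.floor(r)) for r in raw]
    rem = total - sum(counts)
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _place_pair(rng: np.random.Generator, chrom: str, base: int, bt: str):
    """Place one coding gene and its partner lncRNA in a slot (coding '+')."""
    cs = base + _CODING_OFFSET
    if bt == "XI":
        clen = 5000
    elif bt == "XO":
        clen = int(rng.integers(1000, 1601))
    else:
        clen = int(rng.integers(2000, 5001))
    ce = cs + clen
    L = int(rng.integers(500, 2001))
    g = int(rng.integers(200, 4501))
    if bt == "XH":
        lnc = (cs - g - L, cs - g, "-")
    elif bt == "XT":
        lnc = (ce + g, ce + g + L, "-")
    elif bt == "SU":
        lnc = (cs - g - L, cs - g, "+")
    elif bt == "SD":
        lnc = (ce + g, ce + g + L, "+")
    elif bt == "XI":
        L = int(rng.integers(500, 1501))
        off = int(rng.integers(200, clen - L - 199))
        lnc = (cs + off, cs + off + L, "-")
    elif bt == "XO":
        m1, m2 = int(rng.integers(300, 1501)), int(rng.integers(300, 1501))
        lnc = (cs - m1, ce + m2, "-")
    else:
        raise ValueError(bt)
    cstrand = "+" if rng.random() < 0.5 else "-"
    if cstrand == "-":
        # mirror the slot and flip both strands; reflection + double strand
        # flip preserves every biotype label
        w = SLOT_WIDTH

        def mirror(s, e):
            return base + w - (e - base), base + w - (s - base)

        cs, ce = mirror(cs, ce)
        ls, le = mirror(lnc[0], lnc[1])
        lnc = (ls, le, "+" if lnc[2] == "-" else "-")
    c_iv = GenomicInterval(chrom, cs, ce, cstrand)
    l_iv = GenomicInterval(chrom, lnc[0], lnc[1], lnc[2])
    return c_iv, l_iv


def _promoter_coords(g: GeneModel, chrom_len: int, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        lo, hi = g.tss - up, g.tss + down
    else:
        lo, hi = g.tss - down + 1, g.tss + up + 1
    return max(0, lo), min(chrom_len, hi)


def _make_pwms(score_threshold: float = 1.0) -> list[PWM]:
    pwms = []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for tf, cons in TF_CONSENSUS.items():
        m = np.full((4, len(cons)), 0.01)
        for j, b in enumerate(cons):
            m[base_idx[b], j] = 0.97
        pwms.append(PWM(tf, m, score_threshold=score_threshold))
    return pwms


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate(config: SimulationConfig) -> SimulationResult:
    """Generate all pipeline inputs plus ground truth (see module docstring).

    Raises before producing anything when the requested gene count does not
    fit the configured chromosomes, and verifies at generation time that each
    planted pair realizes its intended biotype and that planted specificity
    labels are recovered exactly by the calling rules.
    """
    rng = np.random.default_rng(config.seed)

    # --- feasibility -------------------------------------------------------
    mix_keys = list(BIOTYPES) + [UNPAIRED]
    fracs = [config.biotype_mix.get(k, 0.0) for k in mix_keys]
    if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
        raise ValueError("biotype_mix fractions must be non-negative and sum to <= 1")
    bt_counts = dict(zip(mix_keys, _largest_remainder(fracs, config.n_lnc)))
    n_paired = config.n_lnc - bt_counts[UNPAIRED]
    if n_paired > config.n_coding:
        raise ValueError("need at least as many coding genes as paired lncRNAs")
    n_slots = config.n_coding + bt_counts[UNPAIRED]
    capacity = sum(
        max(0, (length - SLOT_OFFSET) // SLOT_WIDTH) for length in config.chrom_lengths.values()
    )
    if n_slots > capacity:
        raise ValueError(
            f"chromosomes too short: need {n_slots} gene slots of {SLOT_WIDTH} bp, "
            f"capacity is {capacity}"
        )

    # interleave slots round-robin across chromosomes so every scale spreads
    # genes over the whole genome (cross-chromosome null draws need this)
    per_chrom = {
        chrom: [(chrom, SLOT_OFFSET + k * SLOT_WIDTH) for k in range((length - SLOT_OFFSET) // SLOT_WIDTH)]
        for chrom, length in config.chrom_lengths.items()
    }
    slots: list[tuple[str, int]] = []
    k = 0
    while len(slots) < n_slots:
        advanced = False
        for chrom_slots in per_chrom.values():
            if k < len(chrom_slots):
                slots.append(chrom_slots[k])
                advanced = True
                if len(slots) == n_slots:
                    break
        if not advanced:
            break
        k += 1

    # --- genes -------------------------------------------------------------
    intent_list: list[str] = []
    for bt in BIOTYPES:
        intent_list += [bt] * bt_counts[bt]
    # spread biotypes over gene ids (and hence over specificity labels) so
    # per-stage biotype tables see the configured mixture
    intent_list = [intent_list[i] for i in rng.permutation(len(intent_list))]
    # the example TFs take the last coding slots, which are never pair
    # partners, so their planted fGC expression status stays untouched by the
    # correlated-pair redraw
    tf_names = list(TF_CONSENSUS)
    if config.n_coding - n_paired < len(tf_names):
        tf_names = []
    tf_first = config.n_coding - len(tf_names)

    coding: list[GeneModel] = []
    lncs: list[GeneModel] = []
    intended_biotype: dict[str, str] = {}
    partner_of: dict[str, str] = {}
    slot_i = 0
    for i in range(config.n_coding):
        chrom, base = slots[slot_i]
        slot_i += 1
        cid = tf_names[i - tf_first] if tf_names and i >= tf_first else f"PCG{i:05d}"
        if i < n_paired:
            bt = intent_list[i]
            c_iv, l_iv = _place_pair(rng, chrom, base, bt)
            lid = f"LNC{i:05d}"
            lncs.append(GeneModel(lid, lid, l_iv, "lncRNA"))
            intended_biotype[lid] = bt
            partner_of[lid] = cid
        else:
            cs = base + _CODING_OFFSET
            clen = int(rng.integers(2000, 5001))
            strand = "+" if rng.random() < 0.5 else "-"
            c_iv = GenomicInterval(chrom, cs, cs + clen, strand)
        coding.append(GeneModel(cid, cid, c_iv, "coding"))
    for j in range(bt_counts[UNPAIRED]):
        chrom, base = slots[slot_i]
        slot_i += 1
        L = int(rng.integers(500, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        lid = f"LNC{n_paired + j:05d}"
        lncs.append(GeneModel(lid, lid, GenomicInterval(chrom, base + 9000, base + 9000 + L, strand), "lncRNA"))
        intended_biotype[lid] = UNPAIRED

    # verify geometry against the classifier itself (generation-time contract)
    coding_by_chrom: dict[str, list[GeneModel]] = {}
    for cg in coding:
        coding_by_chrom.setdefault(cg.chrom, []).append(cg)
    coding_by_id = {g.gene_id: g for g in coding}
    for lg in lncs:
        near = nearest_coding(lg, coding_by_chrom.get(lg.chrom, ()), config.max_pair_distance)
        want = intended_biotype[lg.gene_id]
        if want == UNPAIRED:
            if near is not None:
                raise RuntimeError(f"{lg.gene_id}: intended unpaired but found {near.gene_id}")
            continue
        if near is None or near.gene_id != partner_of[lg.gene_id]:
            raise RuntimeError(f"{lg.gene_id}: nearest gene mismatch")
        got = classify_pair(lg, near)
        if got != want:
            raise RuntimeError(f"{lg.gene_id}: intended {want}, classifier says {got}")

    # --- catalogs ----------------------------------------------------------
    n_annot = int(round(config.annotated_fraction * len(lncs)))
    annot_idx = set(rng.choice(len(lncs), size=n_annot, replace=False).tolist()) if lncs else set()
    catalog_a = [lncs[i] for i in sorted(annot_idx)]
    catalog_b = list(lncs)
    catalog_membership = {
        g.gene_id: {
            "in_a": i in annot_idx,
            "in_b": True,
            "status": "annotated" if i in annot_idx else "unannotated",
        }
        for i, g in enumerate(lncs)
    }

    # --- cells -------------------------------------------------------------
    cell_rows = []
    for lineage in ("fGC", "mGC", "fSOMA", "mSOMA"):
        n = config.lineage_sizes.get(lineage, 0)
        stages = list(config.stage_proportions[lineage])
        counts = _largest_remainder([config.stage_proportions[lineage][s] for s in stages], n)
        sex = "female" if lineage.startswith("f") else "male"
        lo, hi = WEEK_RANGES[sex]
        k = 0
        for stage, cnt in zip(stages, counts):
            for _ in range(cnt):
                cell_rows.append(
                    {
                        "cell_id": f"{lineage}_{k:04d}",
                        "sex": sex,
                        "lineage": lineage,
                        "stage": stage,
                        "week": int(rng.integers(lo, hi + 1)),
                    }
                )
                k += 1
    cells = pd.DataFrame(cell_rows)
    if cells.empty:
        raise ValueError("no cells configured")
    cell_ids = cells["cell_id"].tolist()
    lineage_arr = cells["lineage"].to_numpy()
    stage_arr = cells["stage"].to_numpy()
    n_cells = len(cells)

    # --- specificity plan --------------------------------------------------
    n_lin = int(round(config.frac_lineage_specific * config.n_lnc))
    n_stage = int(round(config.frac_stage_specific * config.n_lnc))
    n_broad = int(round(config.frac_broad * config.n_lnc))
    label_of: dict[str, str] = {}
    lnc_ids = [g.gene_id for g in lncs]
    xh_ids = [g for g in lnc_ids if intended_biotype[g] == "XH"]
    # every other XH lncRNA is pinned to a (large) germ lineage so planted
    # pair correlations can be measured over many expressing cells; the rest
    # go through the general label pools like any other lncRNA
    germ_cycle = ["lineage:fGC", "lineage:mGC"]
    for i, g in enumerate(xh_ids[::2]):
        label_of[g] = germ_cycle[i % 2]
    n_lin_left = max(0, n_lin - (len(xh_ids) + 1) // 2)
    rest = [g for g in lnc_ids if g not in label_of]
    lin_cycle = ["lineage:fGC", "lineage:mGC", "lineage:fSOMA", "lineage:mSOMA"]
    stage_cycle = [f"stage:{lin}:{s}" for lin in ("fGC", "mGC") for s in STAGES[lin]]
    pos = 0
    for i in range(min(n_lin_left, len(rest) - pos)):
        label_of[rest[pos]] = lin_cycle[i % 4]
        pos += 1
    for i in range(min(n_stage, len(rest) - pos)):
        label_of[rest[pos]] = stage_cycle[i % len(stage_cycle)]
        pos += 1
    for i in range(min(n_broad, len(rest) - pos)):
        label_of[rest[pos]] = "broad"
        pos += 1
    while pos < len(rest):
        label_of[rest[pos]] = "silent"
        pos += 1

    def on_mask_for(label: str) -> np.ndarray:
        if label == "broad":
            return np.ones(n_cells, dtype=bool)
        if label == "silent":
            return np.zeros(n_cells, dtype=bool)
        parts = label.split(":")
        if parts[0] == "lineage":
            return lineage_arr == parts[1]
        return (lineage_arr == parts[1]) & (stage_arr == parts[2])

    # --- expression matrix -------------------------------------------------
    gene_ids = [g.gene_id for g in coding] + lnc_ids
    gene_class = pd.Series(
        ["coding"] * len(coding) + ["lncRNA"] * len(lncs), index=gene_ids
    )
    dropout_p = np.array([config.dropout[l] for l in lineage_arr])
    sigma = config.log_sigma
    arr = np.zeros((len(gene_ids), n_cells))
    mu_of: dict[str, float] = {}
    fgc_mask = lineage_arr == "fGC"
    for gi, gid in enumerate(gene_ids):
        mu = float(rng.uniform(*config.log_mu_range))
        mu_of[gid] = mu
        if gene_class[gid] == "coding":
            if gid in config.tf_in_fgc and not config.tf_in_fgc[gid]:
                on = ~fgc_mask  # TF absent from female germ cells
            else:
                on = np.ones(n_cells, dtype=bool)
        else:
            on = on_mask_for(label_of[gid])
        n_on = int(on.sum())
        if n_on == 0:
            continue
        vals = np.exp(rng.normal(mu, sigma, n_on))
        vals[rng.random(n_on) < dropout_p[on]] = 0.0
        arr[gi, on] = vals

    # planted correlations for true XH pairs (joint redraw, no dropout so the
    # expressing-cell selection keeps the full group)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    rho = config.pair_rho
    rho_latent = math.log1p(rho * math.expm1(sigma**2)) / sigma**2 if rho else 0.0
    pair_rho_truth: dict[str, float] = {}
    for lid in xh_ids:
        on = on_mask_for(label_of[lid])
        n_on = int(on.sum())
        if n_on < 3:
            continue
        z1 = rng.standard_normal(n_on)
        z2 = rho_latent * z1 + math.sqrt(max(0.0, 1 - rho_latent**2)) * rng.standard_normal(n_on)
        arr[gene_index[lid], on] = np.exp(mu_of[lid] + sigma * z1)
        cid = partner_of[lid]
        arr[gene_index[cid], on] = np.exp(mu_of[cid] + sigma * z2)
        pair_rho_truth[lid] = rho

    # --- specificity repair & leakage --------------------------------------
    # guarantee: every planted specific gene is detected (TPM >= 1) in at
    # least two target cells and in exactly `leakage_cells` outside cells
    for gid, label in label_of.items():
        if label in ("broad", "silent"):
            continue
        gi = gene_index[gid]
        on = on_mask_for(label)
        row = arr[gi]
        idx_on = np.flatnonzero(on)
        expressed_in = idx_on[row[idx_on] >= 1.0]
        if len(expressed_in) < 2:
            silent_in = idx_on[row[idx_on] < 1.0]
            row[silent_in[: 2 - len(expressed_in)]] = 8.0
        idx_out = np.flatnonzero(~on)
        row[idx_out] = 0.0  # planted genes leak only where we put leakage
        if config.leakage_cells > 0 and len(idx_out) > 0:
            k = min(config.leakage_cells, len(idx_out))
            leak = rng.choice(idx_out, size=k, replace=False)
            row[leak] = 1.5

    tpm = pd.DataFrame(arr, index=gene_ids, columns=cell_ids)
    dataset = ExpressionDataset(tpm, gene_class, cells)

    # intended recovery sets (a stage-specific gene of lineage L is also
    # lineage-specific to L: it is silent outside L altogether)
    lineage_specific = {
        lin: sorted(
            g for g, lab in label_of.items()
            if lab == f"lineage:{lin}" or lab.startswith(f"stage:{lin}:")
        )
        for lin in ("fGC", "mGC", "fSOMA", "mSOMA")
    }
    stage_specific = {
        lin: {
            s: sorted(g for g, lab in label_of.items() if lab == f"stage:{lin}:{s}")
            for s in STAGES[lin]
        }
        for lin in ("fGC", "mGC")
    }

    # generation-time contract: the planted labels are recovered exactly by
    # the calling rule that matches the configured leakage
    from .specificity import call_specific, stage_specific as call_stage_specific

    rule = "methods" if config.leakage_cells > 0 else "results"
    if lncs:
        called = call_specific(dataset, "lineage", rule_variant=rule)
        for lin, s in called.items():
            want = set(lineage_specific.get(lin, []))
            if set(s.gene_ids) != want:
                raise RuntimeError(
                    f"planted lineage specificity not recovered for {lin}: "
                    f"{sorted(set(s.gene_ids) ^ want)}"
                )
        for lin in ("fGC", "mGC"):
            if (cells.lineage == lin).sum() == 0:
                continue
            called_st = call_stage_specific(dataset, lin, rule_variant=rule)
            for stg, s in called_st.items():
                want = set(stage_specific[lin].get(stg, []))
                if set(s.gene_ids) != want:
                    raise RuntimeError(
                        f"planted stage specificity not recovered for {lin}/{stg}: "
                        f"{sorted(set(s.gene_ids) ^ want)}"
                    )

    # --- genome + motifs ----------------------------------------------------
    base_arr = {"A": 65, "C": 67, "G": 71, "T": 84}
    genome_raw: dict[str, bytearray] = {}
    lut = np.array([65, 67, 71, 84], dtype=np.uint8)
    for chrom, length in config.chrom_lengths.items():
        codes = rng.integers(0, 4, size=length)
        genome_raw[chrom] = bytearray(lut[codes].tobytes())

    pwms = _make_pwms(score_threshold=1.0)
    meiotic = stage_specific.get("fGC", {}).get("meiotic", [])
    lnc_by_id = {g.gene_id: g for g in lncs}
    up, down = config.promoter_upstream, config.promoter_downstream
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in meiotic}
    motif_plants: dict[str, dict] = {}
    for pwm in pwms:
        tf, cons = pwm.tf_name, TF_CONSENSUS[pwm.tf_name]
        rate = config.plant_rates.get(tf, 0.0)
        n_plant = int(round(rate * len(meiotic)))
        chosen = sorted(
            rng.choice(len(meiotic), size=n_plant, replace=False).tolist()
        ) if n_plant else []
        planted_ids = []
        for mi in chosen:
            gid = meiotic[mi]
            g = lnc_by_id[gid]
            lo, hi = _promoter_coords(g, config.chrom_lengths[g.chrom], up, down)
            span = hi - lo - len(cons)
            placed = False
            for _attempt in range(60):
                off = int(rng.integers(0, span + 1))
                s, e = lo + off, lo + off + len(cons)
                if all(e <= os or s >= oe for os, oe in occupied[gid]):
                    genome_raw[g.chrom][s:e] = cons.encode()
                    occupied[gid].append((s, e))
                    placed = True
                    break
            if placed:
                planted_ids.append(gid)
        motif_plants[tf] = {
            "rate": rate,
            "planted": planted_ids,
            "fraction": len(planted_ids) / len(meiotic) if meiotic else 0.0,
            "consensus": cons,
            "expressed_in_fgc": bool(config.tf_in_fgc.get(tf, True)),
        }

    # scrub accidental exact-consensus occurrences from unplanted promoters so
    # planted fractions are exact at threshold 1.0
    planted_by_gene: dict[str, set[str]] = {g: set() for g in meiotic}
    for tf, info in motif_plants.items():
        for gid in info["planted"]:
            planted_by_gene[gid].add(tf)
    patterns = {tf: (c, revcomp(c)) for tf, c in TF_CONSENSUS.items()}
    for gid in meiotic:
        g = lnc_by_id[gid]
        lo, hi = _promoter_coords(g, config.chrom_lengths[g.chrom], up, down)
        for _round in range(50):
            window = genome_raw[g.chrom][lo:hi].decode()
            dirty = False
            for tf, (fw, rc) in patterns.items():
                if tf in planted_by_gene[gid]:
                    continue
                for pat in (fw, rc):
                    p = window.find(pat)
                    while p != -1:
                        s = lo + p
                        # mutate one base of the occurrence outside planted spans
                        for k in range(len(pat)):
                            if all(
                                not (os <= s + k < oe) for os, oe in occupied[gid]
                            ):
                                cur = genome_raw[g.chrom][s + k]
                                repl = {65: 67, 67: 71, 71: 84, 84: 65}[cur]
                                genome_raw[g.chrom][s + k] = repl
                                dirty = True
                                break
                        window = genome_raw[g.chrom][lo:hi].decode()
                        p = window.find(pat, p + 1)
            if not dirty:
                break
        else:
            raise RuntimeError(f"could not scrub spurious motifs in promoter of {gid}")
    genome = {c: bytes(b).decode() for c, b in genome_raw.items()}

    # --- chip fragments -----------------------------------------------------
    region_len = config.chip_region_length
    chip_chrom = next(iter(config.chrom_lengths))
    flen = config.chip_fragment_length
    n_starts = region_len - flen + 1
    weights = np.ones(n_starts)
    for pk in config.chip_peaks:
        ps, pe = pk["start"], pk["start"] + pk["width"]
        lo = max(0, ps - flen + 1)
        hi = min(n_starts, pe)
        weights[lo:hi] = pk["fold"]

    def draw_fragments(w: np.ndarray) -> list[tuple[str, int, int]]:
        p = w / w.sum()
        starts = rng.choice(n_starts, size=config.chip_n_fragments, p=p)
        starts.sort()
        return [(chip_chrom, int(s), int(s) + flen) for s in starts]

    chip_fragments = draw_fragments(weights)
    input_fragments = draw_fragments(np.ones(n_starts))

    gt = GroundTruth(
        biotype={
            lid: {
                "biotype": intended_biotype[lid],
                "partner": partner_of.get(lid),
                "tss_distance": (
                    abs(lnc_by_id[lid].tss - coding_by_id[partner_of[lid]].tss)
                    if lid in partner_of
                    else None
                ),
            }
            for lid in lnc_ids
        },
        catalog_membership=catalog_membership,
        specificity_label={g: label_of[g] for g in lnc_ids},
        lineage_specific=lineage_specific,
        stage_specific=stage_specific,
        leakage_cells=config.leakage_cells,
        pair_rho=pair_rho_truth,
        motif_plants=motif_plants,
        chip_peaks=[
            {"chrom": chip_chrom, "start": pk["start"], "end": pk["start"] + pk["width"], "fold": pk["fold"]}
            for pk in config.chip_peaks
        ],
        chip_region={"chrom": chip_chrom, "length": region_len},
    )
    return SimulationResult(
        config=config,
        coding=coding,
        lncs=lncs,
        catalog_a=catalog_a,
        catalog_b=catalog_b,
        dataset=dataset,
        genome=genome,
        pwms=pwms,
        chip_fragments=chip_fragments,
        input_fragments=input_fragments,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# fixtures for region-category assignment
# ---------------------------------------------------------------------------


def generate_region_fixture(
    n_per_category: int = 2, seed: int = 0
) -> tuple[list[GeneModel], list[tuple[GeneModel, str]]]:
    """Coding genes with sub-features plus lncRNAs whose TSS falls in a known
    region category; returns (coding genes, [(lnc, intended category), ...]).

    Uses the same priority semantics as ``assign_region`` with its default
    windows (promoter 1000, TSS 100, TTS 1000).
    """
    rng = np.random.default_rng(seed)
    coding: list[GeneModel] = []
    placed: list[tuple[GeneModel, str]] = []
    categories = ("TSS", "promoter", "5'UTR", "exon", "intron", "3'UTR", "TTS", "intergenic")
    span = 100_000
    idx = 0
    for rep in range(n_per_category):
        for cat in categories:
            base = idx * span
            idx += 1
            cs, ce = base + 10_000, base + 20_000
            cg = GeneModel(
                f"REGC{idx:04d}",
                f"REGC{idx:04d}",
                GenomicInterval("chrR", cs, ce, "+"),
                "coding",
                exons=(
                    GenomicInterval("chrR", cs, cs + 2000, "+"),
                    GenomicInterval("chrR", cs + 4000, cs + 6000, "+"),
                    GenomicInterval("chrR", cs + 8000, ce - 500, "+"),
                ),
                utr5=(GenomicInterval("chrR", cs, cs + 500, "+"),),
                utr3=(GenomicInterval("chrR", ce - 500, ce, "+"),),
            )
            coding.append(cg)
            pos = {
                "TSS": cs + int(rng.integers(0, 101)),
                "promoter": cs - int(rng.integers(200, 1001)),
                "5'UTR": cs + int(rng.integers(101, 500)),
                "exon": cs + int(rng.integers(600, 2000)),
                "intron": cs + int(rng.integers(2100, 4000)),
                "3'UTR": ce - int(rng.integers(1, 500)),
                "TTS": ce + int(rng.integers(1, 1001)),
                "intergenic": ce + int(rng.integers(30_000, 60_000)),
            }[cat]
            lnc = GeneModel(
                f"REGL{idx:04d}",
                f"REGL{idx:04d}",
                GenomicInterval("chrR", pos, pos + 400, "+"),
                "lncRNA",
            )
            placed.append((lnc, cat))
    return coding, placed
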