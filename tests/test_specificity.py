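import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncscape.specificity import call_specific, stage_specific
from tests.conftest import build_dataset


def two_group_dataset(vectors, n_in=5, n_out=5):
    """Genes x (n_in fGC + n_out fSOMA) matrix from per-gene tuples."""
    tpm = np.array(vectors, dtype=float)
    return build_dataset(tpm, lineages=["fGC"] * n_in + ["fSOMA"] * n_out)


def test_rule_variants_on_boundary_cases():
    ds = two_group_dataset(
        [
            [5, 5, 5, 5, 5, 0, 0, 0, 0, 0],  # 5 in / 0 out: specific under both
            [5, 5, 5, 5, 5, 2, 0, 0, 0, 0],  # 5 in / 1 out: methods only
            [5, 5, 5, 5, 5, 2, 2, 0, 0, 0],  # 2 outside cells: neither
            [5, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # only 1 expressing cell: neither
        ]
    )
    results = call_specific(ds, "lineage", rule_variant="results")["fGC"].gene_ids
    methods = call_specific(ds, "lineage", rule_variant="methods")["fGC"].gene_ids
    assert results == {"G0"}
    assert methods == {"G0", "G1"}


def test_evidence_counts_recorded():
    ds = two_group_dataset([[5, 5, 5, 0, 0, 2, 0, 0, 0, 0]])
    s = call_specific(ds, "lineage", rule_variant="methods")["fGC"]
    assert s.evidence.loc["G0", "n_cells_in"] == 3
    assert s.evidence.loc["G0", "n_cells_out"] == 1


def test_planted_specificity_recovered_exactly(sim_small):
    """Zero-leakage plants: precision and recall are exactly 1 under both
    rule variants, for lineage and for stage groupings."""
    ds, gt = sim_small.dataset, sim_small.ground_truth
    for rule in ("results", "methods"):
        called = call_specific(ds, "lineage", rule_variant=rule)
        for lineage, s in called.items():
            assert set(s.gene_ids) == set(gt.lineage_specific[lineage]), (rule, lineage)
        for lineage in ("fGC", "mGC"):
            for stage, s in stage_specific(ds, lineage, rule_variant=rule).items():
                assert set(s.gene_ids) == set(gt.stage_specific[lineage][stage])


def test_one_cell_leakage_separates_the_rules(sim_leak):
    """With exactly one stray expressing cell planted outside each target
    group, the tolerant rule recovers every plant and the strict rule rejects
    every plant."""
    ds, gt = sim_leak.dataset, sim_leak.ground_truth
    assert gt.leakage_cells == 1
    methods = call_specific(ds, "lineage", rule_variant="methods")
    results = call_specific(ds, "lineage", rule_variant="results")
    n_planted = 0
    for lineage in methods:
        want = set(gt.lineage_specific[lineage])
        n_planted += len(want)
        assert set(methods[lineage].gene_ids) == want
        assert set(results[lineage].gene_ids) == set()
    assert n_planted > 0


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_disjointness_and_rule_nesting_on_random_data(seed):
    rng = np.random.default_rng(seed)
    tpm = rng.exponential(1.5, size=(40, 12)) * (rng.random((40, 12)) < 0.5)
    ds = build_dataset(tpm, lineages=["fGC"] * 4 + ["mGC"] * 4 + ["fSOMA"] * 4)
    results = call_specific(ds, "lineage", rule_variant="results")
    methods = call_specific(ds, "lineage", rule_variant="methods")
    all_results = [g for s in results.values() for g in s.gene_ids]
    assert len(all_results) == len(set(all_results))  # zero-outside => disjoint
    for grp in results:
        assert results[grp].gene_ids <= methods[grp].gene_ids


def test_removing_an_outside_cell_never_removes_a_call():
    ds = two_group_dataset([[5, 5, 5, 0, 0, 2, 0, 0, 0, 0]])
    before = call_specific(ds, "lineage", rule_variant="methods")["fGC"].gene_ids
    # drop the one leaking fSOMA cell
    keep = [c for c in ds.tpm.columns if c != "c5"]
    after = call_specific(ds, "lineage", rule_variant="methods", cells_subset=keep)["fGC"].gene_ids
    assert before <= after


def test_single_group_partition_refused():
    ds = build_dataset(np.ones((2, 4)), lineages=["fGC"] * 4)
    with pytest.raises(ValueError, match="two groups"):
        call_specific(ds, "lineage")
    with pytest.raises(ValueError, match="two groups"):
        stage_specific(ds, "fGC")  # all cells share one stage


def test_tiny_group_skipped_with_warning():
    ds = build_dataset(
        np.ones((2, 5)), lineages=["fGC", "fGC", "fSOMA", "fSOMA", "mGC"]
    )
    with pytest.warns(UserWarning, match="mGC"):
        sets = call_specific(ds, "lineage")
    assert "mGC" not in sets


def test_gene_split_between_two_stages_is_specific_to_neither():
    tpm = np.array([[5, 5, 5, 5, 0, 0]], dtype=float)
    ds = build_dataset(
        tpm,
        lineages=["fGC"] * 6,
        stages=["meiotic", "meiotic", "oogenesis", "oogenesis", "mitotic", "mitotic"],
    )
    sets = stage_specific(ds, "fGC")
    assert all("G0" not in s.gene_ids for s in sets.values())


def test_stage_background_lineage_vs_all():
    # gene expressed in fGC-meiotic cells and also in 3 somatic cells: with a
    # lineage-restricted background it is still meiotic-specific; with the
    # all-cell background it is not
    tpm = np.array([[5, 5, 0, 0, 4, 4, 4]], dtype=float)
    ds = build_dataset(
        tpm,
        lineages=["fGC"] * 4 + ["fSOMA"] * 3,
        stages=["meiotic", "meiotic", "mitotic", "mitotic", "s", "s", "s"],
    )
    lineage_bg = stage_specific(ds, "fGC", background="lineage")
    assert "G0" in lineage_bg["meiotic"].gene_ids
    all_bg = stage_specific(ds, "fGC", background="all")
    assert "G0" not in all_bg["meiotic"].gene_ids
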