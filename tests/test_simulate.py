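"""The synthetic-data generator has the statistical structure it promises."""

from __future__ import annotations

import numpy as np
import pytest

from pelodose.markers import call_mnd1, assign_nd1_haplogroup
from pelodose.simulate import (
    PondSpec,
    simulate_ancestry,
    simulate_country,
    simulate_dbr_reads,
    simulate_marker_sequences,
    simulate_pond,
    simulate_replicates,
    synthetic_nd1_references,
)
from pelodose.table import GT_HET, GT_HOM1, GT_HOM2, GT_MISSING


def test_clean_pond_has_forced_diagnostic_structure():
    """With no noise, diagnostic loci are homozygous in every LL and
    heterozygous in every LR individual, by construction."""
    spec = PondSpec("Syn", {"LL": 10, "LR": 10}, n_loci=200,
                    fraction_diagnostic=0.3, seed=4)
    table, truth = simulate_pond(spec)
    table.validate()
    diag = truth.diagnostic_loci()
    assert len(diag) == 60
    sub = table.subset(loci=diag)
    ll_rows = [i for i, g in truth.individuals.items() if g == "LL"]
    lr_rows = [i for i, g in truth.individuals.items() if g == "LR"]
    g_ll = sub.subset(individuals=ll_rows).genotype
    g_lr = sub.subset(individuals=lr_rows).genotype
    assert np.isin(g_ll, [GT_HOM1, GT_HOM2]).all()
    assert (g_lr == GT_HET).all()


def test_same_seed_reproduces_identical_tables():
    spec = PondSpec("Syn", {"LL": 5, "LLR": 5}, seed=99, missing_rate=0.2,
                    genotyping_error_rate=0.05)
    t1, tr1 = simulate_pond(spec)
    t2, tr2 = simulate_pond(spec)
    assert t1.equals(t2, include_meta=True)
    assert tr1.individuals.equals(tr2.individuals)
    assert tr1.loci.equals(tr2.loci)


@pytest.mark.parametrize("genomotype, expected_frac",
                         [("LR", 1 / 2), ("LLR", 2 / 3), ("LRR", 1 / 3)])
def test_dosage_effect_mean_relative_l_coverage(genomotype, expected_frac):
    """Mean L-allele read fraction at het diagnostic loci converges to the
    L-copy fraction: 1/2 (LR), 2/3 (LLR), 1/3 (LRR)."""
    spec = PondSpec("Dos", {genomotype: 30}, n_loci=400,
                    fraction_diagnostic=0.5, mean_depth=30.0, seed=11)
    table, truth = simulate_pond(spec)
    diag = truth.diagnostic_loci()
    l_is_a2 = truth.loci.loc[diag, "l_allele"] == "A2"
    sub = table.subset(loci=diag)
    het = sub.genotype == GT_HET
    l_depth = np.where(l_is_a2.to_numpy()[None, :],
                       sub.depth[:, :, 1], sub.depth[:, :, 0])
    total = sub.depth.sum(axis=2)
    rel = l_depth[het] / total[het]
    assert het.sum() > 1000
    assert abs(rel.mean() - expected_frac) < 0.01


def test_all_zero_counts_rejected():
    with pytest.raises(ValueError, match="zero"):
        PondSpec("Bad", {"LL": 0, "LR": 0})


def test_replicates_error_zero_and_one():
    spec = PondSpec("Rep", {"LR": 1}, n_loci=100, seed=0)
    table, _ = simulate_pond(spec)
    a, b = simulate_replicates(table, 0.0, seed=1)
    assert a.equals(b)
    a, b = simulate_replicates(table, 1.0, seed=1)
    called = (a.genotype != GT_MISSING) & (b.genotype != GT_MISSING)
    assert (a.genotype[called] != b.genotype[called]).all()


def test_replicate_discordance_matches_binomial_oracle():
    """Planted 2% flip rate recovered within 3 binomial SEs (10 000 cells)."""
    spec = PondSpec("Rep", {"LL": 3, "LR": 4, "LLR": 3}, n_loci=1000, seed=8)
    table, _ = simulate_pond(spec)
    a, b = simulate_replicates(table, 0.02, seed=21)
    diff = (a.genotype != b.genotype).mean()
    se = np.sqrt(0.02 * 0.98 / a.genotype.size)
    assert abs(diff - 0.02) <= 3 * se


def test_dbr_reads_truth_labels():
    pairs, labels = simulate_dbr_reads(100, dup_lambda=0.0, seed=3)
    assert len(pairs) == 100
    assert not any(labels)
    pairs, labels = simulate_dbr_reads(100, dup_lambda=1.0, seed=3)
    assert len(pairs) > 100
    assert sum(labels) == len(pairs) - 100
    again, _ = simulate_dbr_reads(100, dup_lambda=1.0, seed=3)
    assert [p.id for p in again] == [p.id for p in pairs]
    assert [p.dbr for p in again] == [p.dbr for p in pairs]


def test_shared_insert_templates_get_independent_dbrs():
    pairs, labels = simulate_dbr_reads(60, dup_lambda=0.0, seed=5,
                                       shared_insert_fraction=0.5)
    by_insert: dict[tuple[str, str], set[str]] = {}
    for p in pairs:
        by_insert.setdefault((p.read1_seq, p.read2_seq), set()).add(p.dbr)
    shared = [dbrs for dbrs in by_insert.values() if len(dbrs) > 1]
    assert shared, "expected some templates sharing an insert"
    assert not any(labels)  # distinct molecules are never duplicates


def test_marker_sequences_round_trip_through_callers():
    calls = {"f1": "lessonae", "f2": "esculentus", "f3": "RR"}
    seqs = simulate_marker_sequences(calls, seed=0)
    mnd1 = dict(seqs["mnd1"])
    assert call_mnd1(mnd1["f1"]) == "LESSONAE"
    assert call_mnd1(mnd1["f2"]) == "ESCULENTUS"
    assert call_mnd1(mnd1["f3"]) == "RR_GENOTYPE"
    refs = synthetic_nd1_references()
    groups = {i: assign_nd1_haplogroup(s, refs).haplogroup for i, s in seqs["nd1"]}
    assert groups["f1"] == "lessonae"
    assert groups["f2"] == "lessonae"  # hybrid carries the maternal lineage
    assert groups["f3"] == "bedriagae"
    assert all(len(s) == 33 for s in mnd1.values())
    assert all(len(s) == 336 for _, s in seqs["nd1"])


def test_marker_sequences_unknown_label_rejected():
    with pytest.raises(ValueError, match="unknown call"):
        simulate_marker_sequences({"x": "ridibundus"})


def test_country_shares_locus_model_across_ponds():
    specs = [PondSpec("A", {"LL": 4, "LR": 4}, seed=1),
             PondSpec("B", {"LR": 4, "LLR": 4}, seed=2)]
    table, truth = simulate_country(specs, seed=9)
    assert table.n_individuals == 16
    assert table.n_loci == 500
    assert set(table.sample_meta["pond_id"]) == {"A", "B"}
    # same country seed -> same locus model regardless of pond specs order
    table2, truth2 = simulate_country(list(reversed(specs)), seed=9)
    assert truth.loci.equals(truth2.loci)


def test_ancestry_matrix_rows_sum_to_one_and_track_truth():
    spec = PondSpec("Anc", {"LL": 5, "LR": 5, "LLR": 5, "RR": 2}, seed=3)
    _, truth = simulate_pond(spec)
    q = simulate_ancestry(truth.individuals, seed=1)
    assert np.allclose(q.sum(axis=1), 1.0)
    for ind, g in truth.individuals.items():
        if g in ("LL", "LR", "LLR"):
            assert q.loc[ind, f"cluster_{g}"] > 0.8
        else:
            assert (q.loc[ind] <= 0.8).all()
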