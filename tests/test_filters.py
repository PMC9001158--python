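"""Sample/SNP filter cascade and replicate resolution."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pelodose.filters import (
    FilterConfig,
    apply_replicate_resolution,
    filter_samples,
    filter_snps,
    minor_allele_frequency,
    resolve_replicates,
)
from pelodose.table import GT_HET, GT_HOM1, GT_HOM2, GT_MISSING, GenotypeTable

from conftest import random_table


def _meta(reads: dict[str, int], groups: dict[str, str] | None = None):
    ids = list(reads)
    groups = groups or {i: i for i in ids}
    return pd.DataFrame(
        {"pond_id": ["p"] * len(ids), "replicate_group": [groups[i] for i in ids],
         "total_reads": [reads[i] for i in ids]},
        index=pd.Index(ids, name="individual"))


# ------------------------------------------------------------- replicates

def test_replicate_with_most_reads_selected_above_threshold():
    meta = _meta({"r1": 400_000, "r2": 100_000}, {"r1": "g", "r2": "g"})
    assert resolve_replicates(meta) == {"g": ("keep", ["r1"])}


def test_replicates_combined_below_threshold():
    meta = _meta({"r1": 200_000, "r2": 150_000}, {"r1": "g", "r2": "g"})
    assert resolve_replicates(meta) == {"g": ("combine", ["r1", "r2"])}


def test_singleton_group_kept():
    meta = _meta({"solo": 500_000})
    assert resolve_replicates(meta) == {"solo": ("keep", ["solo"])}
    meta = _meta({"solo": 10_000})
    assert resolve_replicates(meta) == {"solo": ("combine", ["solo"])}


def test_combine_sums_depths_and_takes_consensus():
    g = np.array([[GT_HET, GT_HOM1, GT_MISSING, GT_HET],
                  [GT_HET, GT_HOM2, GT_HET, GT_MISSING]], dtype=np.int8)
    d = np.array([[[3, 4], [5, 0], [0, 0], [2, 2]],
                  [[2, 6], [0, 7], [1, 3], [0, 0]]], dtype=np.int64)
    meta = _meta({"a": 100_000, "b": 90_000}, {"a": "g", "b": "g"})
    t = GenotypeTable(["a", "b"], ["l1", "l2", "l3", "l4"], g, d, meta)
    out = apply_replicate_resolution(t, resolve_replicates(meta))
    assert out.individual_ids == ["g"]
    assert out.genotype[0].tolist() == [GT_HET, GT_MISSING, GT_HET, GT_HET]
    assert out.depth[0, 0].tolist() == [5, 10]   # summed
    assert out.depth[0, 1].tolist() == [0, 0]    # conflict -> missing, zeroed
    assert int(out.sample_meta.loc["g", "total_reads"]) == 190_000
    out.validate()


# ---------------------------------------------------------------- samples

def test_read_count_floor_keeps_strictly_above(rng):
    t = random_table(rng, 2, 10)
    t.sample_meta["total_reads"] = [60_000, 40_000]
    kept = filter_samples(t, 50_000)
    assert kept.individual_ids == ["ind000"]
    assert kept.n_loci == t.n_loci
    assert filter_samples(t, 0).individual_ids == t.individual_ids


def test_sample_filter_matches_brute_force(rng):
    t = random_table(rng, 15, 5)
    threshold = int(t.sample_meta["total_reads"].max())
    kept = filter_samples(t, threshold)
    expected = [i for i in t.individual_ids
                if t.sample_meta.loc[i, "total_reads"] > threshold]
    assert kept.individual_ids == expected  # only strict argmax ties survive


# ------------------------------------------------------------------- SNPs

def test_low_depth_cell_masked():
    g = np.array([[GT_HET]], dtype=np.int8)
    d = np.array([[[3, 2]]], dtype=np.int64)
    t = GenotypeTable(["a"], ["l"], g, d)
    out, log = filter_snps(t, FilterConfig(min_maf=0, max_missing_snp=1,
                                           max_missing_ind=1))
    assert log.cells_masked_low_depth == 1
    assert out.genotype[0, 0] == GT_MISSING


def test_rare_allele_locus_removed():
    # minor allele count 1 of 40 alleles -> MAF 0.025 < 0.05
    g = np.full((20, 1), GT_HOM1, dtype=np.int8)
    g[0, 0] = GT_HET
    d = np.zeros((20, 1, 2), dtype=np.int64)
    d[:, :, 0] = 20
    d[0, 0] = [10, 10]
    t = GenotypeTable([f"i{k}" for k in range(20)], ["l"], g, d)
    assert minor_allele_frequency(t)["l"] == pytest.approx(0.025)
    out, log = filter_snps(t, FilterConfig(max_missing_snp=1, max_missing_ind=1))
    assert out.n_loci == 0
    assert log.loci_removed_maf == 1


def _brute_force_filter(t, config):
    """Independent loop-based reimplementation of the cascade."""
    g = t.genotype.copy().astype(int)
    for i in range(t.n_individuals):
        for j in range(t.n_loci):
            if g[i, j] != GT_MISSING and t.depth[i, j].sum() < config.min_depth:
                g[i, j] = GT_MISSING
    keep_loci = []
    for j in range(t.n_loci):
        calls = [g[i, j] for i in range(t.n_individuals) if g[i, j] != GT_MISSING]
        if not calls:
            continue
        freq = sum(calls) / (2 * len(calls))
        if min(freq, 1 - freq) >= config.min_maf:
            keep_loci.append(j)
    keep_loci2 = []
    for j in keep_loci:
        miss = sum(g[i, j] == GT_MISSING for i in range(t.n_individuals))
        if miss / t.n_individuals <= config.max_missing_snp:
            keep_loci2.append(j)
    keep_ind = []
    for i in range(t.n_individuals):
        if not keep_loci2:
            miss_frac = 0.0
        else:
            miss_frac = sum(g[i, j] == GT_MISSING for j in keep_loci2) / len(keep_loci2)
        if miss_frac <= config.max_missing_ind:
            keep_ind.append(i)
    return ([t.individual_ids[i] for i in keep_ind],
            [t.locus_ids[j] for j in keep_loci2])


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_filter_cascade_matches_brute_force(seed):
    """Randomized 20x200 tables: surviving sets equal an independent
    loop-based reimplementation of the four stages."""
    t = random_table(np.random.default_rng(seed), 20, 200, missing=0.3,
                     max_depth=20)
    config = FilterConfig(min_depth=8, min_maf=0.05, max_missing_snp=0.4,
                          max_missing_ind=0.4)
    out, log = filter_snps(t, config)
    exp_ind, exp_loci = _brute_force_filter(t, config)
    assert out.individual_ids == exp_ind
    assert out.locus_ids == exp_loci
    log.check()


@pytest.mark.parametrize("field, tighter, monotone_in",
                         [("min_maf", 0.10, "n_loci"),
                          ("max_missing_snp", 0.2, "n_loci"),
                          ("max_missing_ind", 0.2, "n_individuals")])
def test_tightening_a_threshold_is_monotone(rng, field, tighter, monotone_in):
    """Tightening a locus-level threshold never increases the locus count;
    tightening the individual cap never increases the individual count."""
    t = random_table(rng, 20, 150, missing=0.25, max_depth=25)
    base = FilterConfig(max_missing_snp=0.4, max_missing_ind=0.4)
    loose, _ = filter_snps(t, base)
    strict, _ = filter_snps(t, dataclasses.replace(base, **{field: tighter}))
    assert getattr(strict, monotone_in) <= getattr(loose, monotone_in)
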