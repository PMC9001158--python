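"""Diagnostic-locus discovery, composition profiles and genomotype calls."""

from __future__ import annotations

import numpy as np
import pytest

from pelodose.diagnostic import (
    CONTAMINATION_SUSPECT,
    E_UNKNOWN_PLOIDY,
    UNDETERMINED,
    ClassifyConfig,
    CompositionProfile,
    DiagnosticSet,
    OrientationError,
    classify_genotype,
    classify_individuals,
    composition_profile,
    discover_diagnostic_loci,
    dosage_loglikelihoods,
    identify_diagnostic_loci,
)
from pelodose.simulate import PondSpec, simulate_pond
from pelodose.table import GT_HET, GT_HOM1, GT_HOM2, GT_MISSING, GenotypeTable


@pytest.fixture(scope="module")
def clean_pond():
    spec = PondSpec("Ref", {"LL": 10, "LR": 10, "LLR": 5, "LRR": 5, "RR": 3},
                    n_loci=300, fraction_diagnostic=0.3, seed=12)
    return simulate_pond(spec)


def _refs(truth, genomotype, n=10):
    return list(truth.individuals[truth.individuals == genomotype].index)[:n]


def test_planted_diagnostic_loci_recovered_exactly(clean_pond):
    table, truth = clean_pond
    diag = identify_diagnostic_loci(table, _refs(truth, "LL"), _refs(truth, "LR"))
    assert set(diag.loci) == set(truth.diagnostic_loci())
    # orientation: the allele fixed in the homozygous (LL) panel is L
    for locus in diag.loci:
        assert diag.l_allele[locus] == truth.loci.loc[locus, "l_allele"]


def test_orientation_resolved_automatically(clean_pond):
    table, truth = clean_pond
    ll, lr = _refs(truth, "LL"), _refs(truth, "LR")
    diag_a, homo = discover_diagnostic_loci(table, ll, lr)
    diag_b, homo_b = discover_diagnostic_loci(table, lr, ll)
    assert homo == "a" and homo_b == "b"  # the LL panel is homozygous either way
    assert set(diag_a.loci) == set(diag_b.loci)


def test_too_much_missing_data_excludes_locus(clean_pond):
    table, truth = clean_pond
    t = table.copy()
    ll = _refs(truth, "LL")
    locus = truth.diagnostic_loci()[0]
    j = t.locus_ids.index(locus)
    for ind in ll[:4]:  # 4 missing > the 3 tolerated per cluster
        i = t.individual_ids.index(ind)
        t.genotype[i, j] = GT_MISSING
        t.depth[i, j] = 0
    diag = identify_diagnostic_loci(t, ll, _refs(truth, "LR"))
    assert locus not in diag.loci
    # 3 missing is still tolerated
    t2 = table.copy()
    for ind in ll[:3]:
        i = t2.individual_ids.index(ind)
        t2.genotype[i, j] = GT_MISSING
        t2.depth[i, j] = 0
    assert locus in identify_diagnostic_loci(t2, ll, _refs(truth, "LR")).loci


def test_split_homozygote_panel_excludes_locus(clean_pond):
    table, truth = clean_pond
    t = table.copy()
    ll = _refs(truth, "LL")
    locus = truth.diagnostic_loci()[1]
    i = t.individual_ids.index(ll[0])
    j = t.locus_ids.index(locus)
    # one reference homozygous for the other allele: not fixed any more
    t.genotype[i, j] = GT_HOM1 if t.genotype[i, j] == GT_HOM2 else GT_HOM2
    d = int(t.depth[i, j].sum())
    t.depth[i, j] = [d, 0] if t.genotype[i, j] == GT_HOM1 else [0, d]
    diag = identify_diagnostic_loci(t, ll, _refs(truth, "LR"))
    assert locus not in diag.loci


def test_overlapping_reference_panels_rejected(clean_pond):
    table, truth = clean_pond
    ll = _refs(truth, "LL")
    with pytest.raises(ValueError, match="overlap"):
        identify_diagnostic_loci(table, ll, ll[:3])


# ------------------------------------------------------------- profiles

def test_pure_ll_profile(clean_pond):
    table, truth = clean_pond
    diag = identify_diagnostic_loci(table, _refs(truth, "LL"), _refs(truth, "LR"))
    prof = composition_profile(table, _refs(truth, "LL")[0], diag)
    assert prof.p_homL == pytest.approx(1.0)
    assert prof.rel_L == []


def test_relative_l_coverage_from_depths():
    diag = DiagnosticSet(("l1",), {"l1": "A1"})
    t = GenotypeTable(["x"], ["l1"], np.array([[GT_HET]], dtype=np.int8),
                      np.array([[[20, 10]]], dtype=np.int64))
    prof = composition_profile(t, "x", diag)
    assert prof.rel_L[0] == pytest.approx(2 / 3, abs=5e-4)
    # below the depth floor the locus contributes no rel_L entry
    t.depth[0, 0] = [4, 3]
    assert composition_profile(t, "x", diag).rel_L == []


def test_profile_proportions_partition_unity(clean_pond):
    table, truth = clean_pond
    diag = identify_diagnostic_loci(table, _refs(truth, "LL"), _refs(truth, "LR"))
    for ind in table.individual_ids[:8]:
        p = composition_profile(table, ind, diag)
        assert p.p_homL + p.p_homR + p.p_het == pytest.approx(1.0)


def test_no_called_diagnostic_loci_is_an_error():
    diag = DiagnosticSet(("l1",), {"l1": "A1"})
    t = GenotypeTable(["x"], ["l1"], np.array([[GT_MISSING]], dtype=np.int8),
                      np.zeros((1, 1, 2), dtype=np.int64))
    with pytest.raises(ValueError, match="no called diagnostic"):
        composition_profile(t, "x", diag)


# --------------------------------------------------------- classification

def _profile(p_homL=0.0, p_homR=0.0, p_het=0.0, het_counts=()):
    return CompositionProfile("x", 100, p_homL, p_homR, p_het, list(het_counts))


def test_pure_homozygous_profiles():
    assert classify_genotype(_profile(p_homR=1.0)).label == "RR"
    assert classify_genotype(_profile(p_homL=1.0)).label == "LL"


def test_exact_dosage_fractions_recover_all_hybrid_classes():
    """At high depth with exact binomial fractions the likelihood cascade is
    deterministic and correct for every hybrid class (closed-form limit)."""
    for label, frac in (("LR", 0.5), ("LLR", 2 / 3), ("LRR", 1 / 3)):
        counts = [(int(round(300 * frac)), 300)] * 30
        call = classify_genotype(_profile(p_het=1.0, het_counts=counts))
        assert call.label == label
        assert call.support[label] == max(call.support.values())


def test_few_het_loci_or_thin_margin_gives_unknown_ploidy():
    counts = [(150, 300)] * 5  # below the 10-locus evidence floor
    assert classify_genotype(_profile(p_het=1.0, het_counts=counts)).label \
        == E_UNKNOWN_PLOIDY
    # shallow, conflicting counts: no model wins by the required margin
    counts = [(1, 2), (1, 3), (2, 3)] * 4
    call = classify_genotype(_profile(p_het=1.0, het_counts=counts),
                             ClassifyConfig(margin=50.0))
    assert call.label == E_UNKNOWN_PLOIDY


def test_contaminated_profile_flagged():
    """Half fixed-L, half diploid-hybrid pattern: the signature of a sample
    carrying DNA of both a pool frog and a hybrid."""
    counts = [(15, 30)] * 20
    call = classify_genotype(_profile(p_homL=0.56, p_het=0.44, het_counts=counts))
    assert call.label == UNDETERMINED
    assert CONTAMINATION_SUSPECT in call.flags


def test_orientation_swap_symmetry(clean_pond):
    """Swapping the L/R orientation maps LL<->RR and LLR<->LRR and leaves
    LR fixed."""
    table, truth = clean_pond
    diag = identify_diagnostic_loci(table, _refs(truth, "LL"), _refs(truth, "LR"))
    calls = classify_individuals(table, diag).set_index("individual")["label"]
    swapped = classify_individuals(table, diag.swapped()).set_index("individual")["label"]
    swap_map = {"LL": "RR", "RR": "LL", "LLR": "LRR", "LRR": "LLR", "LR": "LR"}
    for ind in calls.index:
        assert swapped[ind] == swap_map.get(calls[ind], calls[ind])


def test_simulated_cohort_classified_correctly(clean_pond):
    table, truth = clean_pond
    diag = identify_diagnostic_loci(table, _refs(truth, "LL"), _refs(truth, "LR"))
    calls = classify_individuals(table, diag).set_index("individual")["label"]
    assert (calls == truth.individuals).all()


def test_dosage_loglik_pools_per_locus_binomials():
    counts = [(10, 20), (21, 30)]
    from scipy import stats
    expected = stats.binom.logpmf([10, 21], [20, 30], 0.5).sum()
    assert dosage_loglikelihoods(counts)["LR"] == pytest.approx(expected)
    assert dosage_loglikelihoods([]) == {}
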