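"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates biallelic ddRAD loci for a hybridogenetic water-frog
complex: individuals carry genomotypes LL, LR, LLR, LRR or RR (counts of
the P. lessonae-derived L genome and the P. ridibundus-complex R genome).
At diagnostic loci the L and R genomes are fixed for alternative alleles,
so genotype plus per-allele read depth reveals genome dosage: the expected
L-allele read fraction equals the L-copy fraction (1/2 in LR, 2/3 in LLR,
1/3 in LRR).  Non-diagnostic loci carry ordinary shared polymorphism so
that ordination and MAF filters have realistic work to do.

Per-cell sequencing depth is negative-binomial (RAD coverage is
overdispersed relative to Poisson); genotype calls are the underlying truth
corrupted only by an explicit per-call error rate and i.i.d. missingness,
with depths drawn conditional on the call so table invariants hold by
construction.  All randomness flows from integer seeds through
``numpy.random.default_rng``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ReadPair
from .markers import Mnd1Templates, default_mnd1_templates
from .table import GT_HET, GT_HOM1, GT_HOM2, GT_MISSING, GenotypeTable, concat_individuals

#: (n_L_copies, n_R_copies) per genomotype
GENOME_COPIES: dict[str, tuple[int, int]] = {
    "LL": (2, 0), "LR": (1, 1), "LLR": (2, 1), "LRR": (1, 2), "RR": (0, 2),
}
GENOMOTYPES = list(GENOME_COPIES)


@dataclasses.dataclass
class PondSpec:
    """Sampling design for one simulated pond.

    Defaults reflect the desk-scale study conditions used throughout the
    test suite: 500 loci of which 35% are diagnostic (175 loci, matching
    the size of a real diagnostic panel), mean depth 30 with
    negative-binomial dispersion 5, and clean calls unless noise is
    requested explicitly.
    """

    pond_id: str
    counts: Mapping[str, int]
    n_loci: int = 500
    fraction_diagnostic: float = 0.35
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(GENOME_COPIES)
        if unknown:
            raise ValueError(f"unknown genomotypes {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("genomotype counts must be >= 0")
        if sum(self.counts.values()) == 0:
            raise ValueError("all genomotype counts are zero")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for name in ("fraction_diagnostic", "missing_rate", "genotyping_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")


@dataclasses.dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated genotype table."""

    individuals: pd.Series  # individual id -> genomotype
    loci: pd.DataFrame      # index locus id; columns is_diagnostic, l_allele

    def diagnostic_loci(self) -> list[str]:
        return list(self.loci.index[self.loci["is_diagnostic"]])


@dataclasses.dataclass
class _LocusModel:
    """Shared per-locus parameters: which loci are diagnostic, the L-allele
    orientation, the A2 allele frequency within each genome, and the clonal
    haplotype pairs carried by triploids.

    Triploids inherit their doubled genome hemiclonally (an LLR mother
    passes both L copies as one unrecombined LL gamete), so all LLR share
    one fixed L-haplotype pair — which is why they form their own cluster
    in ordination space; LRR likewise share a clonal R pair.
    """

    locus_ids: list[str]
    is_diagnostic: np.ndarray  # bool (m,)
    l_allele: np.ndarray       # '<A1|A2|->' per locus
    freq_l: np.ndarray         # P(allele A2) on an L genome copy
    freq_r: np.ndarray         # P(allele A2) on an R genome copy
    clone_l: np.ndarray        # (2, m) 0/1 A2 indicators, clonal LL pair of LLR
    clone_r: np.ndarray        # (2, m) 0/1 A2 indicators, clonal RR pair of LRR

    def truth_loci(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"is_diagnostic": self.is_diagnostic, "l_allele": self.l_allele},
            index=pd.Index(self.locus_ids, name="locus"),
        )


def _draw_locus_model(rng: np.random.Generator, n_loci: int,
                      fraction_diagnostic: float) -> _LocusModel:
    n_diag = int(round(n_loci * fraction_diagnostic))
    is_diag = np.zeros(n_loci, dtype=bool)
    diag_pos = rng.choice(n_loci, size=n_diag, replace=False)
    is_diag[diag_pos] = True
    # diagnostic loci: L genome fixed for one allele, R for the other
    l_is_a2 = rng.random(n_loci) < 0.5
    freq_l = np.where(l_is_a2, 1.0, 0.0)
    freq_r = 1.0 - freq_l
    # non-diagnostic loci: allele frequencies uniform in [0.05, 0.95],
    # Hardy-Weinberg within each genome, shared between genomes w.p. 0.5
    f1 = rng.uniform(0.05, 0.95, size=n_loci)
    f2 = rng.uniform(0.05, 0.95, size=n_loci)
    shared = rng.random(n_loci) < 0.5
    nd = ~is_diag
    freq_l[nd] = f1[nd]
    freq_r[nd] = np.where(shared, f1, f2)[nd]
    l_allele = np.where(is_diag, np.where(l_is_a2, "A2", "A1"), "-")
    locus_ids = [f"loc{j:05d}" for j in range(n_loci)]
    clone_l = (rng.random((2, n_loci)) < freq_l).astype(np.int64)
    clone_r = (rng.random((2, n_loci)) < freq_r).astype(np.int64)
    return _LocusModel(locus_ids, is_diag, l_allele, freq_l, freq_r,
                       clone_l, clone_r)


def _sample_cells(rng: np.random.Generator, model: _LocusModel,
                  genomotypes: Sequence[str], mean_depth: float,
                  dispersion: float, missing_rate: float,
                  error_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Genotype and depth arrays for individuals with the given genomotypes."""
    n, m = len(genomotypes), len(model.locus_ids)
    copies = np.array([GENOME_COPIES[g] for g in genomotypes])
    nl = copies[:, [0]]  # (n,1)
    nr = copies[:, [1]]
    # triploids carry their doubled genome as the shared clonal pair; the
    # remaining copies are independent Hardy-Weinberg draws
    is_llr = np.array([g == "LLR" for g in genomotypes])[:, None]
    is_lrr = np.array([g == "LRR" for g in genomotypes])[:, None]
    nl_free = np.where(is_llr, 0, nl)
    nr_free = np.where(is_lrr, 0, nr)
    c = (rng.binomial(nl_free, model.freq_l[None, :], size=(n, m))
         + rng.binomial(nr_free, model.freq_r[None, :], size=(n, m))
         + is_llr * model.clone_l.sum(axis=0)[None, :]
         + is_lrr * model.clone_r.sum(axis=0)[None, :])
    ploidy = (nl + nr).astype(np.int64)
    call = np.full((n, m), GT_HET, dtype=np.int8)
    call[c == 0] = GT_HOM1
    call[c == ploidy] = GT_HOM2
    # genotyping error: flip to a uniformly chosen different state
    flip = rng.random((n, m)) < error_rate
    other = rng.integers(1, 3, size=(n, m)).astype(np.int8)
    call = np.where(flip, (call + other) % 3, call).astype(np.int8)
    # per-cell depth: negative binomial with given mean and dispersion
    p = dispersion / (dispersion + mean_depth)
    d = rng.negative_binomial(dispersion, p, size=(n, m)).astype(np.int64)
    het = call == GT_HET
    d[het] = np.maximum(d[het], 2)  # a het call needs a read of each allele
    frac2 = c / ploidy
    d2 = rng.binomial(d, frac2)
    d2 = np.where(het, np.clip(d2, 1, np.maximum(d - 1, 1)), d2)
    d2 = np.where(call == GT_HOM1, 0, d2)
    d2 = np.where(call == GT_HOM2, d, d2)
    miss = rng.random((n, m)) < missing_rate
    call[miss] = GT_MISSING
    depth = np.stack([d - d2, d2], axis=2)
    depth[miss] = 0
    return call, depth


def _individual_ids(pond_id: str, genomotypes: Sequence[str]) -> list[str]:
    return [f"{pond_id}{k + 1:02d}" for k in range(len(genomotypes))]


def _pond_individuals(spec: PondSpec) -> list[str]:
    return [g for g in GENOMOTYPES for _ in range(int(spec.counts.get(g, 0)))]


def _build_pond(spec: PondSpec, model: _LocusModel,
                rng: np.random.Generator) -> tuple[GenotypeTable, TruthTable]:
    genomotypes = _pond_individuals(spec)
    ids = _individual_ids(spec.pond_id, genomotypes)
    call, depth = _sample_cells(rng, model, genomotypes, spec.mean_depth,
                                spec.depth_dispersion, spec.missing_rate,
                                spec.genotyping_error_rate)
    meta = pd.DataFrame(
        {
            "pond_id": [spec.pond_id] * len(ids),
            "replicate_group": ids,
            "total_reads": rng.integers(60_000, 1_200_000, size=len(ids)),
        },
        index=pd.Index(ids, name="individual"),
    )
    table = GenotypeTable(ids, list(model.locus_ids), call, depth, meta)
    truth = TruthTable(
        individuals=pd.Series(genomotypes, index=ids, name="genomotype"),
        loci=model.truth_loci(),
    )
    return table, truth


def simulate_pond(spec: PondSpec) -> tuple[GenotypeTable, TruthTable]:
    """One pond's genotype table plus ground truth. Deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    model = _draw_locus_model(rng, spec.n_loci, spec.fraction_diagnostic)
    return _build_pond(spec, model, rng)


def simulate_country(specs: Sequence[PondSpec], seed: int = 0
                     ) -> tuple[GenotypeTable, TruthTable]:
    """Many ponds genotyped against one shared locus set.

    The locus model (diagnostic panel, allele orientation, frequencies) is
    drawn once from ``seed``; each pond's individuals are then sampled from
    a stream derived from (seed, pond index), so ponds are independent but
    the whole country is reproducible from the single seed.
    """
    if not specs:
        raise ValueError("no pond specs supplied")
    first = specs[0]
    for s in specs[1:]:
        if s.n_loci != first.n_loci or s.fraction_diagnostic != first.fraction_diagnostic:
            raise ValueError("all ponds must share n_loci and fraction_diagnostic")
    model = _draw_locus_model(np.random.default_rng(seed),
                              first.n_loci, first.fraction_diagnostic)
    tables, truths = [], []
    for k, s in enumerate(specs):
        t, tr = _build_pond(s, model, np.random.default_rng([seed, k, s.seed]))
        tables.append(t)
        truths.append(tr)
    table = concat_individuals(tables)
    truth = TruthTable(
        individuals=pd.concat([tr.individuals for tr in truths]),
        loci=model.truth_loci(),
    )
    return table, truth


# ------------------------------------------------------------- ancestry

def simulate_ancestry(truth_individuals: pd.Series, seed: int = 0,
                      q_main: float = 0.95, noise: float = 0.02) -> pd.DataFrame:
    """Synthetic admixture-coefficient (Q) matrix consistent with the truth.

    Stands in for an externally fitted ancestry model (model fitting itself
    is outside this package): LL, LR and LLR individuals load on their own
    cluster with coefficient ~``q_main``; LRR and RR individuals get spread
    coefficients so that a strict q-threshold leaves them unassigned, as
    rare off-cluster samples are in practice.  Rows sum to one.
    """
    rng = np.random.default_rng(seed)
    cols = ["cluster_LL", "cluster_LR", "cluster_LLR"]
    main_col = {"LL": 0, "LR": 1, "LLR": 2}
    rows = []
    for g in truth_individuals:
        if g in main_col:
            q = np.full(3, (1 - q_main) / 2)
            q[main_col[g]] = q_main + rng.uniform(-noise, noise)
            q = np.abs(q)
        else:
            q = np.array([0.45, 0.35, 0.20]) + rng.uniform(-noise, noise, size=3)
        rows.append(q / q.sum())
    return pd.DataFrame(rows, index=truth_individuals.index, columns=cols)


# ------------------------------------------------------------ replicates

def simulate_replicates(table: GenotypeTable, per_snp_error: float,
                        seed: int = 0) -> tuple[GenotypeTable, GenotypeTable]:
    """Two technical-replicate copies of a table.

    Copy A is the input; in copy B every non-missing call independently
    differs from A with probability ``per_snp_error`` (flipped to a
    uniformly chosen different genotype state, depths minimally adjusted to
    keep het calls supported).
    """
    if not 0.0 <= per_snp_error <= 1.0:
        raise ValueError("per_snp_error must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = table.copy()
    b = table.copy()
    called = b.genotype != GT_MISSING
    flip = (rng.random(b.genotype.shape) < per_snp_error) & called
    other = rng.integers(1, 3, size=b.genotype.shape).astype(np.int8)
    b.genotype = np.where(flip, (b.genotype + other) % 3, b.genotype).astype(np.int8)
    # keep the het-call invariant: both alleles need >= 1 read
    het = b.genotype == GT_HET
    for al in (0, 1):
        fix = het & (b.depth[:, :, al] == 0)
        b.depth[:, :, al][fix] = 1
    return a, b


def make_replicate_pair_table(table: GenotypeTable, per_snp_error: float,
                              seed: int = 0) -> GenotypeTable:
    """Stack both replicate copies into one table.

    Ids get ``_a``/``_b`` suffixes and ``replicate_group`` is set to the
    original individual id, the layout the replicate sweep consumes.
    """
    a, b = simulate_replicates(table, per_snp_error, seed)
    for t, suffix in ((a, "_a"), (b, "_b")):
        new_ids = [i + suffix for i in t.individual_ids]
        t.sample_meta = t.sample_meta.copy()
        t.sample_meta.index = pd.Index(new_ids, name="individual")
        t.sample_meta["replicate_group"] = t.individual_ids
        t.individual_ids = new_ids
    return concat_individuals([a, b])


# ------------------------------------------------------------- DBR reads

def simulate_dbr_reads(n_templates: int, dup_lambda: float, dbr_length: int = 8,
                       seed: int = 0, read_length: int = 80,
                       shared_insert_fraction: float = 0.0
                       ) -> tuple[list[ReadPair], list[bool]]:
    """Read pairs with degenerate-base-region tags plus truth duplicate labels.

    Each template molecule receives a random DBR; its PCR copies (count ~
    Poisson(``dup_lambda``)) share both the insert sequence and the DBR.
    With probability ``shared_insert_fraction`` a template reuses an earlier
    template's insert but draws an independent DBR — the case the DBR
    exists to disambiguate (identical insert, distinct molecule).  The
    truth label is True for PCR copies only.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if dbr_length < 1:
        raise ValueError("dbr_length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def random_seq(length: int) -> str:
        return "".join(rng.choice(bases, size=length))

    def random_qual(length: int) -> str:
        return "".join(chr(33 + q) for q in rng.integers(25, 41, size=length))

    inserts: list[tuple[str, str]] = []
    pairs: list[ReadPair] = []
    labels: list[bool] = []
    for t in range(n_templates):
        if inserts and rng.random() < shared_insert_fraction:
            r1, r2 = inserts[rng.integers(0, len(inserts))]
        else:
            r1, r2 = random_seq(read_length), random_seq(read_length)
        inserts.append((r1, r2))
        dbr = random_seq(dbr_length)
        n_copies = 1 + rng.poisson(dup_lambda)
        for k in range(n_copies):
            pairs.append(ReadPair(id=f"tmpl{t:05d}_c{k}", read1_seq=r1,
                                  read2_seq=r2, qual1=random_qual(read_length),
                                  qual2=random_qual(read_length), dbr=dbr))
            labels.append(k > 0)
    return pairs, labels


# ------------------------------------------------------- marker sequences

def synthetic_nd1_references(seed: int = 7, length: int = 336,
                             n_diff: int = 24) -> dict[str, str]:
    """Synthetic 336-bp ND1 haplogroup references.

    Three maternal lineages (lessonae, ridibundus, bedriagae) separated from
    each other by ~``n_diff`` substitutions; stand-ins for the GenBank
    references a real analysis would load from FASTA.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    base_seq = list("".join(bases[i] for i in rng.integers(0, 4, size=length)))
    refs = {"lessonae": "".join(base_seq)}
    for name in ("ridibundus", "bedriagae"):
        mutated = list(base_seq)
        for pos in rng.choice(length, size=n_diff, replace=False):
            mutated[pos] = bases[(bases.index(mutated[pos]) + rng.integers(1, 4)) % 4]
        refs[name] = "".join(mutated)
    return refs


#: IUPAC code for each unordered base pair
_AMBIG = {frozenset(s): c for c, s in
          {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}.items()}


def simulate_marker_sequences(calls: Mapping[str, str], seed: int = 0,
                              templates: Mnd1Templates | None = None,
                              nd1_references: Mapping[str, str] | None = None,
                              nd1_within_group_subs: int = 2
                              ) -> dict[str, list[tuple[str, str]]]:
    """MND1 and ND1 sequences for individuals with known species calls.

    ``calls`` maps individual id -> one of ``lessonae`` / ``esculentus`` /
    ``RR``.  MND1 fragments carry the L state, the R state, or the two-base
    IUPAC ambiguity at both diagnostic positions respectively.  ND1
    haplotypes are drawn near one of the reference haplogroups (lessonae
    lineage for lessonae/esculentus — the hybrid inherits its mother's
    mitochondrion — and the bedriagae lineage for RR individuals).
    """
    allowed = {"lessonae", "esculentus", "RR"}
    unknown = {v for v in calls.values() if v not in allowed}
    if unknown:
        raise ValueError(f"unknown call labels {sorted(unknown)}; expected {sorted(allowed)}")
    rng = np.random.default_rng(seed)
    tmpl = templates if templates is not None else default_mnd1_templates()
    refs = dict(nd1_references) if nd1_references is not None else synthetic_nd1_references()
    esc_seq = list(tmpl.l_seq)
    for pos in tmpl.diagnostic_positions:
        esc_seq[pos] = _AMBIG[frozenset({tmpl.l_seq[pos], tmpl.r_seq[pos]})]
    mnd1_by_call = {"lessonae": tmpl.l_seq, "RR": tmpl.r_seq,
                    "esculentus": "".join(esc_seq)}
    nd1_group = {"lessonae": "lessonae", "esculentus": "lessonae", "RR": "bedriagae"}
    bases = "ACGT"
    mnd1, nd1 = [], []
    for ind, label in calls.items():
        mnd1.append((ind, mnd1_by_call[label]))
        ref = list(refs[nd1_group[label]])
        n_subs = int(rng.integers(0, nd1_within_group_subs + 1))
        for pos in rng.choice(len(ref), size=n_subs, replace=False):
            ref[pos] = bases[(bases.index(ref[pos]) + int(rng.integers(1, 4))) % 4]
        nd1.append((ind, "".join(ref)))
    return {"mnd1": mnd1, "nd1": nd1}
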