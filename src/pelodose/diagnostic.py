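"""Diagnostic loci and genomic-composition classification.

A diagnostic locus is fixed for one allele in the L genome and the other in
the R genome, so every pure P. lessonae (LL) is homozygous, every member of
the P. ridibundus complex (RR) is homozygous for the alternative allele,
and every hybrid is heterozygous.  Reference panels of known LL and LR
individuals define the panel; each individual is then summarised by its
proportions of homozygous-L, homozygous-R and heterozygous diagnostic loci,
and — at heterozygous loci — by the relative read coverage of the L allele.

Ploidy follows from a dosage effect: the expected L-allele read fraction
equals the L-copy fraction, 1/2 for LR, 2/3 for LLR and 1/3 for LRR.  The
classifier turns the visual density-plot inspection of composition profiles
into a numeric cascade: near-total homozygosity gives LL or RR, a
predominantly heterozygous profile is assigned the allele-fraction model
(1/2, 2/3, 1/3) with the highest pooled binomial log-likelihood, and
profiles matching neither pattern stay undetermined — flagged as possible
contamination when homozygous-L and heterozygous loci are both abundant,
the signature of a sample carrying DNA of two individuals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .table import GT_HET, GT_HOM1, GT_HOM2, GT_MISSING, GenotypeTable

LL, LR, LLR, LRR, RR = "LL", "LR", "LLR", "LRR", "RR"
E_UNKNOWN_PLOIDY = "E_UNKNOWN_PLOIDY"
UNDETERMINED = "UNDETERMINED"
CONTAMINATION_SUSPECT = "CONTAMINATION_SUSPECT"
NO_DIAGNOSTIC_DATA = "NO_DIAGNOSTIC_DATA"

#: expected L-allele read fraction at a heterozygous diagnostic locus
DOSAGE_MODELS = {LR: 0.5, LLR: 2.0 / 3.0, LRR: 1.0 / 3.0}


class OrientationError(ValueError):
    """Cluster-to-genome orientation could not be resolved automatically."""


@dataclasses.dataclass(frozen=True)
class DiagnosticSet:
    """Loci diagnostic for the L/R genomes with per-locus allele orientation."""

    loci: tuple[str, ...]
    l_allele: Mapping[str, str]  # locus -> 'A1' or 'A2'

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("diagnostic loci are not unique")
        bad = {l: a for l, a in self.l_allele.items() if a not in ("A1", "A2")}
        if bad:
            raise ValueError(f"l_allele must be 'A1' or 'A2', got {bad}")
        if set(self.loci) != set(self.l_allele):
            raise ValueError("loci and l_allele keys disagree")

    def __len__(self) -> int:
        return len(self.loci)

    def r_allele(self, locus: str) -> str:
        return "A2" if self.l_allele[locus] == "A1" else "A1"

    def swapped(self) -> "DiagnosticSet":
        """Same loci with the L/R orientation reversed."""
        return DiagnosticSet(self.loci, {l: ("A2" if a == "A1" else "A1")
                                         for l, a in self.l_allele.items()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": list(self.loci),
            "L_allele": [self.l_allele[l] for l in self.loci],
            "R_allele": [self.r_allele(l) for l in self.loci],
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DiagnosticSet":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(tuple(frame["locus"]),
                   dict(zip(frame["locus"], frame["L_allele"])))


def identify_diagnostic_loci(table: GenotypeTable, refs_homo: Sequence[str],
                             refs_het: Sequence[str],
                             max_missing_per_cluster: int = 3) -> DiagnosticSet:
    """Loci homozygous (for one shared allele) in every called homozygous-
    cluster reference and heterozygous in every called reference of the
    other cluster, tolerating ``max_missing_per_cluster`` missing calls in
    each panel.  The allele fixed in ``refs_homo`` becomes the L allele.
    """
    refs_homo, refs_het = list(refs_homo), list(refs_het)
    if not refs_homo or not refs_het:
        raise ValueError("both reference panels must be non-empty")
    overlap = set(refs_homo) & set(refs_het)
    if overlap:
        raise ValueError(f"reference panels overlap: {sorted(overlap)}")
    gh = table.subset(individuals=refs_homo).genotype
    ge = table.subset(individuals=refs_het).genotype
    miss_h = (gh == GT_MISSING).sum(axis=0)
    miss_e = (ge == GT_MISSING).sum(axis=0)
    called_h = gh.shape[0] - miss_h
    called_e = ge.shape[0] - miss_e
    # all called homozygous-panel refs share one homozygous state
    all_hom1 = ((gh == GT_HOM1) | (gh == GT_MISSING)).all(axis=0)
    all_hom2 = ((gh == GT_HOM2) | (gh == GT_MISSING)).all(axis=0)
    all_het = ((ge == GT_HET) | (ge == GT_MISSING)).all(axis=0)
    ok = ((all_hom1 | all_hom2) & all_het
          & (miss_h <= max_missing_per_cluster)
          & (miss_e <= max_missing_per_cluster)
          & (called_h > 0) & (called_e > 0))
    loci = [l for l, keep in zip(table.locus_ids, ok) if keep]
    fixed1 = dict(zip(table.locus_ids, all_hom1))
    return DiagnosticSet(tuple(loci),
                         {l: ("A1" if fixed1[l] else "A2") for l in loci})


def discover_diagnostic_loci(table: GenotypeTable, refs_a: Sequence[str],
                             refs_b: Sequence[str],
                             max_missing_per_cluster: int = 3,
                             min_diagnostic: int = 10
                             ) -> tuple[DiagnosticSet, str]:
    """Try both cluster-to-genome orientations; the one yielding a usable
    panel (>= ``min_diagnostic`` loci) wins and names the L (homozygous,
    i.e. P. lessonae) cluster: returns ``(panel, "a" | "b")``.  Both
    orientations succeeding demands manual resolution; neither succeeding
    means the clusters are not an LL/LR pair.
    """
    set_a = identify_diagnostic_loci(table, refs_a, refs_b, max_missing_per_cluster)
    set_b = identify_diagnostic_loci(table, refs_b, refs_a, max_missing_per_cluster)
    ok_a, ok_b = len(set_a) >= min_diagnostic, len(set_b) >= min_diagnostic
    if ok_a and ok_b:
        raise OrientationError(
            f"both orientations yield diagnostic loci ({len(set_a)} and "
            f"{len(set_b)}); resolve the cluster-to-genome mapping manually")
    if not ok_a and not ok_b:
        raise OrientationError(
            f"neither orientation yields >= {min_diagnostic} diagnostic loci "
            f"({len(set_a)} and {len(set_b)})")
    return (set_a, "a") if ok_a else (set_b, "b")


@dataclasses.dataclass
class CompositionProfile:
    """Per-individual summary over called diagnostic loci."""

    individual_id: str
    n_called: int
    p_homL: float
    p_homR: float
    p_het: float
    het_counts: list[tuple[int, int]]  # (L-allele depth, total depth) per het locus

    def __post_init__(self) -> None:
        total = self.p_homL + self.p_homR + self.p_het
        if self.n_called > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("p_homL + p_homR + p_het must equal 1")

    @property
    def n_het(self) -> int:
        return len(self.het_counts)

    @property
    def rel_L(self) -> list[float]:
        return [l / t for l, t in self.het_counts]


def composition_profile(table: GenotypeTable, individual: str,
                        diagnostic: DiagnosticSet,
                        min_depth: int = 8) -> CompositionProfile:
    """Homozygosity proportions and per-locus relative L coverage.

    ``rel_L`` entries (via ``het_counts``) come only from heterozygous
    diagnostic loci with total depth >= ``min_depth``, echoing the
    depth floor of the SNP filters.
    """
    loci = [l for l in diagnostic.loci if l in set(table.locus_ids)]
    sub = table.subset(individuals=[individual], loci=loci)
    g = sub.genotype[0]
    d = sub.depth[0]
    called = g != GT_MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(f"individual {individual!r} has no called diagnostic loci")
    l_is_a2 = np.array([diagnostic.l_allele[l] == "A2" for l in loci])
    hom_l = called & np.where(l_is_a2, g == GT_HOM2, g == GT_HOM1)
    hom_r = called & np.where(l_is_a2, g == GT_HOM1, g == GT_HOM2)
    het = called & (g == GT_HET)
    het_counts = []
    for j in np.flatnonzero(het):
        total = int(d[j].sum())
        if total >= min_depth:
            l_depth = int(d[j, 1] if l_is_a2[j] else d[j, 0])
            het_counts.append((l_depth, total))
    return CompositionProfile(
        individual_id=individual,
        n_called=n_called,
        p_homL=float(hom_l.sum() / n_called),
        p_homR=float(hom_r.sum() / n_called),
        p_het=float(het.sum() / n_called),
        het_counts=het_counts,
    )


@dataclasses.dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds of the genomotype decision cascade.

    ``homo_min``: homozygosity proportion above which a pure species is
    called.  ``het_min``: heterozygosity proportion above which a hybrid is
    called and ploidy assessed.  ``min_het_loci`` and ``margin``: minimum
    evidence (number of depth-qualified het loci; log-likelihood margin of
    the winning dosage model) for a ploidy call — otherwise the individual
    is a hybrid of unknown ploidy.  ``contamination_min``: hom and het
    proportions both above this flag a possible mixed-DNA sample.
    """

    homo_min: float = 0.95
    het_min: float = 0.90
    min_het_loci: int = 10
    margin: float = 2.0
    contamination_min: float = 0.25


@dataclasses.dataclass
class GenomotypeCall:
    label: str
    support: dict[str, float]  # dosage model -> pooled binomial log-likelihood
    flags: list[str]


def dosage_loglikelihoods(het_counts: Sequence[tuple[int, int]]
                          ) -> dict[str, float]:
    """Pooled per-locus binomial log-likelihood of each dosage model."""
    if not het_counts:
        return {}
    l_depth = np.array([c[0] for c in het_counts])
    total = np.array([c[1] for c in het_counts])
    return {label: float(stats.binom.logpmf(l_depth, total, p).sum())
            for label, p in DOSAGE_MODELS.items()}


def classify_genotype(profile: CompositionProfile,
                      config: ClassifyConfig = ClassifyConfig()) -> GenomotypeCall:
    """Decision cascade from a composition profile to a genomotype label."""
    support = dosage_loglikelihoods(profile.het_counts)
    if profile.p_homL >= config.homo_min:
        return GenomotypeCall(LL, support, [])
    if profile.p_homR >= config.homo_min:
        return GenomotypeCall(RR, support, [])
    if profile.p_het >= config.het_min:
        if profile.n_het < config.min_het_loci:
            return GenomotypeCall(E_UNKNOWN_PLOIDY, support, [])
        ranked = sorted(support.items(), key=lambda kv: -kv[1])
        best, second = ranked[0], ranked[1]
        if best[1] - second[1] < config.margin:
            return GenomotypeCall(E_UNKNOWN_PLOIDY, support, [])
        return GenomotypeCall(best[0], support, [])
    flags = []
    if (max(profile.p_homL, profile.p_homR) > config.contamination_min
            and profile.p_het > config.contamination_min):
        flags.append(CONTAMINATION_SUSPECT)
    return GenomotypeCall(UNDETERMINED, support, flags)


def classify_individuals(table: GenotypeTable, diagnostic: DiagnosticSet,
                         config: ClassifyConfig = ClassifyConfig(),
                         min_depth: int = 8) -> pd.DataFrame:
    """Genomotype calls for every individual in the table.

    Individuals without any called diagnostic locus are UNDETERMINED with a
    NO_DIAGNOSTIC_DATA flag rather than an error, so one bad sample does
    not halt a cohort run.  Columns follow the calls-table layout:
    individual, pond, label, composition proportions, het-locus count,
    per-model log-likelihoods and flags.
    """
    rows = []
    for ind in table.individual_ids:
        try:
            profile = composition_profile(table, ind, diagnostic, min_depth)
        except ValueError:
            rows.append({"individual": ind,
                         "pond": table.sample_meta.loc[ind, "pond_id"],
                         "label": UNDETERMINED, "p_homL": np.nan,
                         "p_homR": np.nan, "p_het": np.nan, "n_het": 0,
                         "loglik_LR": np.nan, "loglik_LLR": np.nan,
                         "loglik_LRR": np.nan, "flags": NO_DIAGNOSTIC_DATA})
            continue
        call = classify_genotype(profile, config)
        rows.append({
            "individual": ind,
            "pond": table.sample_meta.loc[ind, "pond_id"],
            "label": call.label,
            "p_homL": profile.p_homL,
            "p_homR": profile.p_homR,
            "p_het": profile.p_het,
            "n_het": profile.n_het,
            "loglik_LR": call.support.get(LR, np.nan),
            "loglik_LLR": call.support.get(LLR, np.nan),
            "loglik_LRR": call.support.get(LRR, np.nan),
            "flags": ";".join(call.flags),
        })
    return pd.DataFrame(rows)
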