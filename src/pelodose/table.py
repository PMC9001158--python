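"""Core genotype-table container shared by every pipeline stage.

A :class:`GenotypeTable` holds an individuals x biallelic-loci matrix of
genotype calls together with per-allele read depths.  Alleles are the raw
A1/A2 (REF/ALT) of the source VCF; orientation to the L (P. lessonae) and
R (P. ridibundus complex) genomes happens later, in the diagnostic-locus
step.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# genotype codes (int8 matrix entries)
GT_MISSING = -1
GT_HOM1 = 0  # A1/A1
GT_HET = 1   # A1/A2
GT_HOM2 = 2  # A2/A2

GENOTYPE_LABELS = {GT_HOM1: "A1A1", GT_HET: "A1A2", GT_HOM2: "A2A2", GT_MISSING: "MISSING"}
LABEL_TO_CODE = {v: k for k, v in GENOTYPE_LABELS.items()}

META_COLUMNS = ["pond_id", "replicate_group", "total_reads"]


class TableInvariantError(ValueError):
    """A GenotypeTable violated one of its structural invariants."""


def default_sample_meta(individual_ids: Sequence[str]) -> pd.DataFrame:
    """Per-sample metadata frame with one row per individual.

    ``pond_id`` defaults to the empty string, ``replicate_group`` to the
    individual's own id (a singleton group) and ``total_reads`` to 0.
    """
    return pd.DataFrame(
        {
            "pond_id": ["" for _ in individual_ids],
            "replicate_group": list(individual_ids),
            "total_reads": np.zeros(len(individual_ids), dtype=np.int64),
        },
        index=pd.Index(list(individual_ids), name="individual"),
    )


@dataclasses.dataclass
class GenotypeTable:
    """Individuals x biallelic loci: genotype call plus per-allele read depth.

    Attributes
    ----------
    individual_ids, locus_ids:
        Unique row / column labels, in storage order.
    genotype:
        ``(n_individuals, n_loci)`` int8 array of genotype codes
        (``GT_HOM1``, ``GT_HET``, ``GT_HOM2``, ``GT_MISSING``).
    depth:
        ``(n_individuals, n_loci, 2)`` integer array of read counts for
        alleles A1 and A2.
    sample_meta:
        DataFrame indexed by individual with columns ``pond_id``,
        ``replicate_group`` and ``total_reads``.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    genotype: np.ndarray
    depth: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        n, m = len(self.individual_ids), len(self.locus_ids)
        if self.genotype.shape != (n, m):
            raise TableInvariantError(
                f"genotype shape {self.genotype.shape} != ({n}, {m})")
        if self.depth.shape != (n, m, 2):
            raise TableInvariantError(
                f"depth shape {self.depth.shape} != ({n}, {m}, 2)")
        if len(set(self.individual_ids)) != n:
            raise TableInvariantError("individual_ids are not unique")
        if len(set(self.locus_ids)) != m:
            raise TableInvariantError("locus_ids are not unique")
        if self.sample_meta is None:
            self.sample_meta = default_sample_meta(self.individual_ids)
        else:
            missing = [i for i in self.individual_ids if i not in self.sample_meta.index]
            if missing:
                raise TableInvariantError(f"sample_meta lacks individuals: {missing[:5]}")
            self.sample_meta = self.sample_meta.loc[self.individual_ids, META_COLUMNS].copy()

    # ------------------------------------------------------------------ shape
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    # ------------------------------------------------------------- missingness
    def missing_mask(self) -> np.ndarray:
        return self.genotype == GT_MISSING

    def missing_fraction(self) -> float:
        if self.genotype.size == 0:
            return 0.0
        return float(self.missing_mask().mean())

    def missing_fraction_per_individual(self) -> pd.Series:
        if self.n_loci == 0:
            vals = np.zeros(self.n_individuals)
        else:
            vals = self.missing_mask().mean(axis=1)
        return pd.Series(vals, index=self.individual_ids)

    def missing_fraction_per_locus(self) -> pd.Series:
        if self.n_individuals == 0:
            vals = np.zeros(self.n_loci)
        else:
            vals = self.missing_mask().mean(axis=0)
        return pd.Series(vals, index=self.locus_ids)

    # ---------------------------------------------------------------- subsets
    def subset(self, individuals: Iterable[str] | None = None,
               loci: Iterable[str] | None = None) -> "GenotypeTable":
        """Row/column subset, preserving the requested order."""
        inds = self.individual_ids if individuals is None else [str(i) for i in individuals]
        locs = self.locus_ids if loci is None else [str(l) for l in loci]
        ind_pos = {v: k for k, v in enumerate(self.individual_ids)}
        loc_pos = {v: k for k, v in enumerate(self.locus_ids)}
        try:
            ri = [ind_pos[i] for i in inds]
        except KeyError as e:
            raise KeyError(f"unknown individual {e.args[0]!r}") from None
        try:
            ci = [loc_pos[l] for l in locs]
        except KeyError as e:
            raise KeyError(f"unknown locus {e.args[0]!r}") from None
        return GenotypeTable(
            individual_ids=inds,
            locus_ids=locs,
            genotype=self.genotype[np.ix_(ri, ci)] if ri and ci else
            np.zeros((len(ri), len(ci)), dtype=np.int8),
            depth=self.depth[np.ix_(ri, ci)] if ri and ci else
            np.zeros((len(ri), len(ci), 2), dtype=np.int64),
            sample_meta=self.sample_meta.loc[inds] if inds else
            default_sample_meta([]),
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            individual_ids=list(self.individual_ids),
            locus_ids=list(self.locus_ids),
            genotype=self.genotype.copy(),
            depth=self.depth.copy(),
            sample_meta=self.sample_meta.copy(),
        )

    # ------------------------------------------------------------ comparisons
    def equals(self, other: "GenotypeTable", include_meta: bool = False) -> bool:
        if (self.individual_ids != other.individual_ids
                or self.locus_ids != other.locus_ids):
            return False
        if not (np.array_equal(self.genotype, other.genotype)
                and np.array_equal(self.depth, other.depth)):
            return False
        if include_meta and not self.sample_meta.equals(other.sample_meta):
            return False
        return True

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check the per-cell invariants; raise TableInvariantError on failure.

        MISSING cells must carry zero depth on both alleles and heterozygous
        calls must be supported by at least one read of each allele.
        """
        if (self.depth < 0).any():
            raise TableInvariantError("negative read depth")
        miss = self.missing_mask()
        if self.depth[miss].any():
            raise TableInvariantError("MISSING genotype with non-zero depth")
        het = self.genotype == GT_HET
        if (self.depth[het] < 1).any():
            raise TableInvariantError("heterozygous call with a zero-depth allele")

    # ------------------------------------------------------------- encodings
    def allele2_counts(self) -> np.ndarray:
        """Genotypes as counts of allele A2 in {0,1,2}; MISSING -> np.nan."""
        out = self.genotype.astype(float)
        out[self.genotype == GT_MISSING] = np.nan
        return out


def concat_individuals(tables: Sequence[GenotypeTable]) -> GenotypeTable:
    """Stack tables that share an identical locus list, row-wise."""
    if not tables:
        raise ValueError("no tables to concatenate")
    loci = tables[0].locus_ids
    for t in tables[1:]:
        if t.locus_ids != loci:
            raise ValueError("tables do not share the same locus list")
    return GenotypeTable(
        individual_ids=[i for t in tables for i in t.individual_ids],
        locus_ids=list(loci),
        genotype=np.concatenate([t.genotype for t in tables], axis=0),
        depth=np.concatenate([t.depth for t in tables], axis=0),
        sample_meta=pd.concat([t.sample_meta for t in tables], axis=0),
    )
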