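"""Sample- and SNP-level quality filters, and technical-replicate handling.

The filter cascade is fixed: (1) per-cell depth masking, (2) minor-allele-
frequency, (3) per-SNP missingness, (4) per-individual missingness — each
stage applied to the previous stage's output.  MAF is computed allele-wise
over called genotypes only.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .table import GT_HET, GT_MISSING, GenotypeTable, default_sample_meta


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the quality-filter cascade.

    ``min_depth``: summed allele depth below which a call is masked.
    ``min_maf``: minor allele frequency below which a SNP is dropped.
    ``max_missing_snp`` / ``max_missing_ind``: missing-data caps per SNP
    (mds) and per individual (mdi); the sweep explores {0.30, 0.40, 0.50}.
    ``min_reads_final`` / ``min_reads_paramtest``: read-count floors for the
    full analysis and the replicate-based parameter test.
    ``replicate_select_threshold``: above this read count the best replicate
    is kept outright instead of combining replicates.
    """

    min_depth: int = 8
    min_maf: float = 0.05
    max_missing_snp: float = 0.30
    max_missing_ind: float = 0.30
    min_reads_final: int = 50_000
    min_reads_paramtest: int = 100_000
    replicate_select_threshold: int = 300_000

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_missing_snp", "max_missing_ind"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("min_depth", "min_reads_final", "min_reads_paramtest",
                     "replicate_select_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass
class FilterLog:
    """Per-stage removal counts for one filter_snps run."""

    cells_masked_low_depth: int = 0
    loci_removed_maf: int = 0
    loci_removed_missing: int = 0
    individuals_removed_missing: int = 0
    n_loci_in: int = 0
    n_loci_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0

    def check(self) -> None:
        assert (self.n_loci_in - self.loci_removed_maf
                - self.loci_removed_missing == self.n_loci_out)
        assert (self.n_individuals_in
                - self.individuals_removed_missing == self.n_individuals_out)


# ----------------------------------------------------------- replicates

def resolve_replicates(sample_meta: pd.DataFrame,
                       select_threshold: int = 300_000
                       ) -> dict[str, tuple[str, list[str]]]:
    """Decide, per replicate group, whether to keep one replicate or combine.

    If the group's best replicate exceeds ``select_threshold`` total reads
    it is kept on its own (ties broken by lexicographically first id);
    otherwise all replicates of the group are combined.  Returns
    ``group -> ("keep", [id])`` or ``group -> ("combine", [ids])``.
    """
    if sample_meta.empty:
        raise ValueError("sample_meta is empty: no replicate groups")
    actions: dict[str, tuple[str, list[str]]] = {}
    for group, sub in sample_meta.groupby("replicate_group", sort=False):
        reads = sub["total_reads"]
        best = reads.max()
        if best > select_threshold:
            winner = sorted(reads.index[reads == best])[0]
            actions[str(group)] = ("keep", [winner])
        else:
            actions[str(group)] = ("combine", list(sub.index))
    return actions


def apply_replicate_resolution(table: GenotypeTable,
                               actions: Mapping[str, tuple[str, list[str]]]
                               ) -> GenotypeTable:
    """Collapse replicate groups into one row each.

    "Combine" sums per-allele depths cell-wise and takes the consensus
    genotype (agreeing non-missing calls win, a lone call stands, any
    conflict becomes MISSING with zeroed depths).  The combined row carries
    the group id and the summed read total.
    """
    pos = {v: k for k, v in enumerate(table.individual_ids)}
    ids, rows_g, rows_d, meta_rows = [], [], [], []
    for group, (action, members) in actions.items():
        idx = [pos[m] for m in members]
        if action == "keep":
            i = idx[0]
            ids.append(members[0])
            rows_g.append(table.genotype[i].copy())
            rows_d.append(table.depth[i].copy())
            meta_rows.append(table.sample_meta.loc[members[0]])
            continue
        g = table.genotype[idx]
        d = table.depth[idx].sum(axis=0)
        called = g != GT_MISSING
        n_called = called.sum(axis=0)
        first_call = np.where(called.any(axis=0),
                              g[called.argmax(axis=0) if len(idx) else 0,
                                np.arange(g.shape[1])],
                              GT_MISSING)
        # conflict: more than one distinct non-missing call
        masked = np.where(called, g, np.int8(127))
        agree = np.all((masked == masked.min(axis=0)) | ~called, axis=0)
        consensus = np.where(n_called == 0, GT_MISSING,
                             np.where(agree, first_call, GT_MISSING)).astype(np.int8)
        d[consensus == GT_MISSING] = 0
        # summed depths can still miss an allele of a het consensus call
        het = consensus == GT_HET
        for al in (0, 1):
            d[het & (d[:, al] == 0), al] = 1
        ids.append(group)
        rows_g.append(consensus)
        rows_d.append(d)
        m = table.sample_meta.loc[members[0]].copy()
        m["total_reads"] = int(table.sample_meta.loc[members, "total_reads"].sum())
        meta_rows.append(m)
    meta = pd.DataFrame(meta_rows)
    meta.index = pd.Index(ids, name="individual")
    meta["replicate_group"] = ids
    return GenotypeTable(ids, list(table.locus_ids),
                         np.array(rows_g, dtype=np.int8),
                         np.array(rows_d, dtype=np.int64), meta)


# -------------------------------------------------------------- samples

def filter_samples(table: GenotypeTable, min_reads: int = 50_000) -> GenotypeTable:
    """Drop individuals with ``total_reads`` <= min_reads; loci unchanged."""
    keep = [i for i in table.individual_ids
            if int(table.sample_meta.loc[i, "total_reads"]) > min_reads]
    if not keep:
        warnings.warn("filter_samples removed every individual", stacklevel=2)
    return table.subset(individuals=keep)


# ----------------------------------------------------------------- SNPs

def minor_allele_frequency(table: GenotypeTable) -> pd.Series:
    """Allele-wise MAF per locus over non-missing calls (0 when none called)."""
    g = table.genotype.astype(float)
    called = table.genotype != GT_MISSING
    a2 = np.where(called, g, 0.0).sum(axis=0)
    n_alleles = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_alleles > 0, a2 / n_alleles, 0.0)
    return pd.Series(np.minimum(f, 1.0 - f), index=table.locus_ids)


def filter_snps(table: GenotypeTable, config: FilterConfig = FilterConfig()
                ) -> tuple[GenotypeTable, FilterLog]:
    """Apply the four-stage filter cascade; returns the table and a log."""
    log = FilterLog(n_loci_in=table.n_loci, n_individuals_in=table.n_individuals)
    t = table.copy()
    # (1) depth masking
    total = t.depth.sum(axis=2)
    low = (total < config.min_depth) & (t.genotype != GT_MISSING)
    log.cells_masked_low_depth = int(low.sum())
    t.genotype[low] = GT_MISSING
    t.depth[low] = 0
    # (2) minor allele frequency
    maf = minor_allele_frequency(t)
    keep_loci = [l for l in t.locus_ids if maf[l] >= config.min_maf]
    log.loci_removed_maf = t.n_loci - len(keep_loci)
    t = t.subset(loci=keep_loci)
    # (3) per-SNP missingness
    miss_l = t.missing_fraction_per_locus()
    keep_loci = [l for l in t.locus_ids if miss_l[l] <= config.max_missing_snp]
    log.loci_removed_missing = t.n_loci - len(keep_loci)
    t = t.subset(loci=keep_loci)
    # (4) per-individual missingness over the retained loci
    miss_i = t.missing_fraction_per_individual()
    keep_ind = [i for i in t.individual_ids if miss_i[i] <= config.max_missing_ind]
    log.individuals_removed_missing = t.n_individuals - len(keep_ind)
    t = t.subset(individuals=keep_ind)
    log.n_loci_out = t.n_loci
    log.n_individuals_out = t.n_individuals
    log.check()
    if t.n_loci == 0 or t.n_individuals == 0:
        warnings.warn("filter_snps produced an empty table", stacklevel=2)
    return t, log
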