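"""Replicate-based genotyping error rate and parameter-sweep evaluation.

Technical replicates of the same individual, processed independently, give
a direct handle on the SNP-calling error rate: the fraction of cells called
in both replicates that disagree.  A sweep over assembly settings and
missing-data filters is scored by dataset size (loci, individuals), missing
fraction and that error rate; a deterministic lexicographic rule replaces
the informal "large and clean" judgement when picking the final setting.
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Mapping, Sequence

import numpy as np

from .filters import FilterConfig, filter_snps
from .table import GT_MISSING, GenotypeTable


@dataclasses.dataclass(frozen=True)
class SweepRecord:
    """One (assembly setting, mds, mdi) combination's evaluation."""

    params: dict
    n_snps: int
    n_individuals: int
    missing_fraction: float
    error_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.n_snps < 0 or self.n_individuals < 0:
            raise ValueError("n_snps and n_individuals must be >= 0")


def snp_error_rate(table_a: GenotypeTable, table_b: GenotypeTable,
                   pairing: Mapping[str, str]) -> float:
    """Discordance fraction between paired replicates.

    ``pairing`` maps individuals of table A to their replicate in table B.
    Only cells where BOTH replicates carry a non-missing call are compared;
    zero comparable cells is an error, not a rate of 0.
    """
    if set(table_a.locus_ids) != set(table_b.locus_ids):
        raise ValueError("replicate tables do not share the same locus set")
    b = table_b.subset(loci=table_a.locus_ids)
    unknown_a = [i for i in pairing if i not in table_a.individual_ids]
    unknown_b = [j for j in pairing.values() if j not in b.individual_ids]
    if unknown_a or unknown_b:
        raise KeyError(f"unknown individuals in pairing: {unknown_a + unknown_b}")
    pos_a = {v: k for k, v in enumerate(table_a.individual_ids)}
    pos_b = {v: k for k, v in enumerate(b.individual_ids)}
    compared = 0
    discordant = 0
    for ia, ib in pairing.items():
        ga = table_a.genotype[pos_a[ia]]
        gb = b.genotype[pos_b[ib]]
        both = (ga != GT_MISSING) & (gb != GT_MISSING)
        compared += int(both.sum())
        discordant += int((ga[both] != gb[both]).sum())
    if compared == 0:
        raise ValueError("no cells with non-missing calls in both replicates")
    return discordant / compared


def _split_replicates(table: GenotypeTable
                      ) -> tuple[GenotypeTable, GenotypeTable, dict[str, str]]:
    """First and second member of each >=2-member replicate group."""
    first, second = [], []
    for group, sub in table.sample_meta.groupby("replicate_group", sort=False):
        ids = list(sub.index)
        if len(ids) >= 2:
            first.append(ids[0])
            second.append(ids[1])
    if not first:
        raise ValueError("table contains no replicate pairs")
    return (table.subset(individuals=first), table.subset(individuals=second),
            dict(zip(first, second)))


def run_sweep(datasets: Mapping[Hashable, GenotypeTable],
              mds_grid: Sequence[float] = (0.3, 0.4, 0.5),
              mdi_grid: Sequence[float] = (0.3, 0.4, 0.5),
              base_config: FilterConfig = FilterConfig()) -> list[SweepRecord]:
    """Evaluate every (dataset, mds, mdi) combination.

    ``datasets`` maps an assembly-parameter key (e.g. ``(("m", 3), ("M",
    3))``) to a genotype table containing technical replicates, paired via
    ``sample_meta.replicate_group``.  Each combination is filtered with the
    base config at that (mds, mdi) and scored by size, missingness and
    replicate error rate.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    records: list[SweepRecord] = []
    for key, table in datasets.items():
        try:
            params_base = dict(key)  # key given as tuple of (name, value) pairs
        except (TypeError, ValueError):
            params_base = {"setting": key}
        for mds in mds_grid:
            for mdi in mdi_grid:
                config = dataclasses.replace(base_config, max_missing_snp=mds,
                                             max_missing_ind=mdi)
                filtered, _ = filter_snps(table, config)
                a, b, pairing = _split_replicates(filtered)
                rate = snp_error_rate(a, b, pairing)
                records.append(SweepRecord(
                    params={**params_base, "mds": mds, "mdi": mdi},
                    n_snps=filtered.n_loci,
                    n_individuals=filtered.n_individuals,
                    missing_fraction=filtered.missing_fraction(),
                    error_rate=rate,
                ))
    return records


def select_setting(records: Sequence[SweepRecord],
                   error_percentile: float = 25.0) -> SweepRecord:
    """Pick the final setting by a deterministic lexicographic rule.

    Records with an error rate above the ``error_percentile``-th percentile
    of observed error rates are discarded; among the rest the record with
    the most individuals wins, then the most SNPs, then the lowest error
    rate, then first in input order.
    """
    if not records:
        raise ValueError("no sweep records to select from")
    errors = np.array([r.error_rate for r in records])
    cutoff = float(np.percentile(errors, error_percentile))
    eligible = [(k, r) for k, r in enumerate(records) if r.error_rate <= cutoff]
    eligible.sort(key=lambda kr: (-kr[1].n_individuals, -kr[1].n_snps,
                                  kr[1].error_rate, kr[0]))
    return eligible[0][1]
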