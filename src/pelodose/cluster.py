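"""Ordination, ancestry-threshold assignment and reference-panel selection.

With no a-priori species labels, individuals are first ordinated by PCA on
allele counts and assigned to clusters from an externally supplied
admixture (Q) matrix using a strict q-threshold.  The two large clusters
then provide reference panels — centrally located, well-genotyped samples
— for diagnostic-locus discovery.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .table import GenotypeTable

UNASSIGNED = "UNASSIGNED"


@dataclasses.dataclass
class Ordination:
    individual_ids: list[str]
    coordinates: np.ndarray        # (n_individuals, n_components)
    variance_explained: np.ndarray  # per-component proportion, non-increasing

    def coords_of(self, individual: str) -> np.ndarray:
        return self.coordinates[self.individual_ids.index(individual)]


def pca(table: GenotypeTable, n_components: int = 10) -> Ordination:
    """PCA of the genotype matrix encoded as counts of allele A2.

    Missing calls are mean-imputed per locus (all-missing loci dropped with
    a warning); the decomposition uses a full, deterministic SVD, so the
    result is reproducible up to component sign conventions.
    """
    if table.n_individuals < 2 or table.n_loci < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 loci")
    x = table.allele2_counts()
    all_missing = np.isnan(x).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing loci from PCA",
                      stacklevel=2)
        x = x[:, ~all_missing]
    col_means = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = col_means[idx[1]]
    k = min(n_components, table.n_individuals - 1, x.shape[1])
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(x)
    return Ordination(
        individual_ids=list(table.individual_ids),
        coordinates=coords,
        variance_explained=model.explained_variance_ratio_,
    )


def assign_from_q(q_matrix: pd.DataFrame, threshold: float = 0.8,
                  tol: float = 1e-6) -> dict[str, str]:
    """Cluster assignment from admixture coefficients with a strict threshold.

    An individual joins its argmax cluster iff that coefficient strictly
    exceeds ``threshold``; otherwise it is UNASSIGNED.  Rows must sum to 1
    within ``tol``.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    values = q_matrix.to_numpy(dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("admixture coefficients must lie in [0, 1]")
    sums = values.sum(axis=1)
    bad = np.abs(sums - 1.0) > tol
    if bad.any():
        offenders = list(q_matrix.index[bad][:5])
        raise ValueError(f"Q-matrix rows do not sum to 1 (e.g. {offenders})")
    out: dict[str, str] = {}
    for ind, row in zip(q_matrix.index, values):
        j = int(np.argmax(row))
        out[str(ind)] = str(q_matrix.columns[j]) if row[j] > threshold else UNASSIGNED
    return out


def select_references(ordination: Ordination, assignments: Mapping[str, str],
                      cluster: str, n: int = 10,
                      missingness: Mapping[str, float] | None = None,
                      max_missing: float = 0.2) -> list[str]:
    """The ``n`` most central, well-genotyped members of one cluster.

    Members are ranked by Euclidean distance to the cluster centroid in the
    first two PCA components (ties: lower missingness, then id); individuals
    with missingness above ``max_missing`` are ineligible.
    """
    members = [i for i in ordination.individual_ids
               if assignments.get(i) == cluster]
    if len(members) < n:
        raise ValueError(f"cluster {cluster!r} has {len(members)} members, "
                         f"fewer than the {n} requested references")
    miss = dict(missingness) if missingness is not None else {}
    k = min(2, ordination.coordinates.shape[1])
    pos = {v: i for i, v in enumerate(ordination.individual_ids)}
    coords = ordination.coordinates[[pos[i] for i in members], :k]
    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    eligible = [(d, miss.get(i, 0.0), i) for d, i in zip(dist, members)
                if miss.get(i, 0.0) <= max_missing]
    if len(eligible) < n:
        raise ValueError(
            f"cluster {cluster!r}: only {len(eligible)} members pass the "
            f"missingness cap {max_missing}, {n - len(eligible)} short of {n}")
    eligible.sort()
    return [i for _, _, i in eligible[:n]]
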