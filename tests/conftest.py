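"""Shared fixtures: randomized genotype tables and small simulated ponds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pelodose.table import GT_HET, GT_HOM1, GT_HOM2, GT_MISSING, GenotypeTable


def random_table(rng: np.random.Generator, n_individuals: int, n_loci: int,
                 missing: float = 0.2, max_depth: int = 40) -> GenotypeTable:
    """A structurally valid random table (depths consistent with calls)."""
    g = rng.choice([GT_HOM1, GT_HET, GT_HOM2], size=(n_individuals, n_loci)).astype(np.int8)
    miss = rng.random((n_individuals, n_loci)) < missing
    g[miss] = GT_MISSING
    d = np.zeros((n_individuals, n_loci, 2), dtype=np.int64)
    total = rng.integers(0, max_depth, size=(n_individuals, n_loci))
    d[:, :, 0] = np.where(g == GT_HOM1, total, 0)
    d[:, :, 1] = np.where(g == GT_HOM2, total, 0)
    het = g == GT_HET
    split = rng.integers(1, np.maximum(total, 2), size=total.shape)
    d[:, :, 0] = np.where(het, np.maximum(total, 2) - split, d[:, :, 0])
    d[:, :, 1] = np.where(het, split, d[:, :, 1])
    ids = [f"ind{i:03d}" for i in range(n_individuals)]
    meta = pd.DataFrame(
        {
            "pond_id": [f"pond{i % 3}" for i in range(n_individuals)],
            "replicate_group": ids,
            "total_reads": rng.integers(10_000, 1_000_000, size=n_individuals),
        },
        index=pd.Index(ids, name="individual"),
    )
    table = GenotypeTable(ids, [f"loc{j:04d}" for j in range(n_loci)], g, d, meta)
    table.validate()
    return table


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table(rng) -> GenotypeTable:
    return random_table(rng, 12, 60)
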