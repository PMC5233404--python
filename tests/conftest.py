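"""Shared fixtures: small random graphs and expression datasets."""

from __future__ import annotations

import numpy as np
import pytest

from padnet.enrichment import CASE, CONTROL, ExpressionDataset
from padnet.network import PathwayDrugMatrix, build_bipartite, symmetric_normalize


def random_normalized_bipartite(rng: np.random.Generator, n_u: int, n_v: int, density: float = 0.4):
    """A random weighted bipartite graph and its normalization."""
    w = rng.uniform(0.1, 1.0, size=(n_u, n_v)) * (rng.random((n_u, n_v)) < density)
    # guarantee no isolated node
    for i in range(n_u):
        if w[i].sum() == 0:
            w[i, rng.integers(n_v)] = rng.uniform(0.1, 1.0)
    for j in range(n_v):
        if w[:, j].sum() == 0:
            w[rng.integers(n_u), j] = rng.uniform(0.1, 1.0)
    m = PathwayDrugMatrix([f"u{i}" for i in range(n_u)], [f"v{j}" for j in range(n_v)], w)
    g = build_bipartite(m, "abs", 0.0)
    return g, symmetric_normalize(g)


def null_dataset(rng: np.random.Generator, n_genes: int = 200, n_per_class: int = 10) -> ExpressionDataset:
    values = rng.standard_normal((n_genes, 2 * n_per_class))
    labels = [CASE] * n_per_class + [CONTROL] * n_per_class
    return ExpressionDataset([f"G{i:04d}" for i in range(n_genes)], values, labels)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
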