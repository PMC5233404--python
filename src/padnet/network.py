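"""Pathway-drug enrichment matrix, weighted bipartite graph, normalization.

The pathway-drug matrix holds one enrichment score per (pathway, drug)
pair.  The bipartite graph G = (U, V, E, w) has pathway nodes U, drug
nodes V and nonnegative edge weights derived from the scores; its
symmetric normalization ``B = D_u^{-1/2} W D_v^{-1/2}`` (degree matrices
on both sides) has spectral norm at most 1, which guarantees convergence
of the label-propagation iteration for alpha < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

WEIGHT_TRANSFORMS = ("abs", "positive-only")


@dataclass
class PathwayDrugMatrix:
    """Pathways x drugs matrix of enrichment scores in [-1, 1]."""

    pathway_ids: list[str]
    drug_ids: list[str]
    es: np.ndarray

    def __post_init__(self) -> None:
        self.es = np.asarray(self.es, dtype=float)
        if self.es.shape != (len(self.pathway_ids), len(self.drug_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isfinite(self.es).all():
            raise ValueError("enrichment matrix contains non-finite entries")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("duplicate pathway ids")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.es, index=self.pathway_ids, columns=self.drug_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PathwayDrugMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class BipartiteGraph:
    """Weighted pathway-drug bipartite graph; weights strictly positive."""

    pathway_ids: list[str]
    drug_ids: list[str]
    weights: np.ndarray  # |U| x |V|, zero entries mean "no edge"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.pathway_ids), len(self.drug_ids)):
            raise ValueError("weight matrix shape does not match id lists")
        if (self.weights < 0).any():
            raise ValueError("edge weights must be nonnegative")

    @property
    def pathway_degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def drug_degrees(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum())


@dataclass
class NormalizedBipartite:
    """Symmetrically normalized bipartite weights B[u, v] = w/sqrt(d(u)d(v))."""

    pathway_ids: list[str]
    drug_ids: list[str]
    b: np.ndarray


def build_pathway_drug_matrix(
    per_drug_enrichments: Mapping[str, Sequence[EnrichmentResult]] | Iterable[tuple[str, Sequence[EnrichmentResult]]],
) -> PathwayDrugMatrix:
    """Assemble the pathways x drugs enrichment-score matrix.

    Accepts a mapping (or iterable of pairs) from drug id to that drug's
    per-pathway enrichment results.  The pathway universe is the union of
    all result pathways; a drug missing a pathway's result contributes 0
    there (counted and logged).
    """
    if isinstance(per_drug_enrichments, Mapping):
        pairs = list(per_drug_enrichments.items())
    else:
        pairs = list(per_drug_enrichments)
    drug_ids = [d for d, _ in pairs]
    if len(set(drug_ids)) != len(drug_ids):
        raise ValueError("duplicate drug ids in enrichment input")
    pathway_ids = sorted({r.pathway_name for _, results in pairs for r in results})
    index = {p: i for i, p in enumerate(pathway_ids)}
    es = np.zeros((len(pathway_ids), len(drug_ids)))
    n_missing = 0
    for j, (_, results) in enumerate(pairs):
        seen = set()
        for r in results:
            es[index[r.pathway_name], j] = r.es
            seen.add(r.pathway_name)
        n_missing += len(pathway_ids) - len(seen)
    if n_missing:
        logger.warning("pathway-drug matrix: %d missing (pathway, drug) cells filled with 0", n_missing)
    return PathwayDrugMatrix(pathway_ids, drug_ids, es)


def build_bipartite(
    m: PathwayDrugMatrix,
    weight_transform: str = "abs",
    threshold: float = 0.0,
) -> BipartiteGraph:
    """Turn the score matrix into a weighted bipartite graph.

    ``abs`` keeps ``|es|`` wherever ``|es| > threshold`` (both directions of
    pathway perturbation count as evidence of association);
    ``positive-only`` keeps ``es`` wherever ``es > threshold``.  Nodes left
    with no incident edge are dropped with a warning.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if weight_transform not in WEIGHT_TRANSFORMS:
        raise ValueError(f"weight_transform must be one of {WEIGHT_TRANSFORMS}")
    if weight_transform == "abs":
        w = np.where(np.abs(m.es) > threshold, np.abs(m.es), 0.0)
    else:
        w = np.where(m.es > threshold, m.es, 0.0)
    keep_u = w.sum(axis=1) > 0
    keep_v = w.sum(axis=0) > 0
    n_iso = int((~keep_u).sum() + (~keep_v).sum())
    if n_iso:
        logger.warning("dropping %d isolated nodes (no edge above threshold %g)", n_iso, threshold)
    w = w[np.ix_(keep_u, keep_v)]
    if w.size == 0 or not (w > 0).any():
        raise ValueError("bipartite graph has no edges after thresholding")
    g = BipartiteGraph(
        [p for p, k in zip(m.pathway_ids, keep_u) if k],
        [d for d, k in zip(m.drug_ids, keep_v) if k],
        w,
    )
    logger.info(
        "bipartite graph: %d pathways, %d drugs, %d edges", len(g.pathway_ids), len(g.drug_ids), g.n_edges
    )
    return g


def symmetric_normalize(g: BipartiteGraph) -> NormalizedBipartite:
    """B = D_u^{-1/2} W D_v^{-1/2}; requires every retained degree > 0."""
    du = g.pathway_degrees
    dv = g.drug_degrees
    if (du <= 0).any() or (dv <= 0).any():
        raise ValueError("zero-degree node encountered; construction should have dropped it")
    b = g.weights / np.sqrt(np.outer(du, dv))
    return NormalizedBipartite(list(g.pathway_ids), list(g.drug_ids), b)
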