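"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators share one scenario object and one seed:

* case/control expression datasets with a subset of pathways whose member
  genes are shifted upward in cases (planted disease pathways), with
  independent noise per dataset so cross-dataset integration is
  meaningful;
* a pathway-drug enrichment-score matrix in which a small group of
  "signal" drugs (the planted repositioning candidates plus the known
  treatment drugs) carries boosted |ES| on the planted disease pathways,
  over a truncated-Gaussian background;
* a heterogeneous validation network with planted hub drugs wired to the
  known drugs and target genes at high weight, over a sparse
  Erdos-Renyi background with Uniform(0.2, 0.6) weights (so a 0.4
  weight cutoff removes about half the background edges).

Every generator is fully determined by ``SimulationScenario.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import CASE, CONTROL, ExpressionDataset, GeneSetCollection
from .network import PathwayDrugMatrix
from .validation import HeterogeneousNetwork, assemble_validation_network

logger = logging.getLogger(__name__)

# substream tags so the three generators draw independent, reproducible streams
_STREAM_PATHWAYS = 0
_STREAM_EXPRESSION = 1
_STREAM_DRUGS = 2
_STREAM_VALNET = 3


@dataclass
class SimulationScenario:
    """Study conditions for the synthetic pipeline.

    Sizes default to a desk-scale study: four case/control cohorts of 30
    samples per arm over 2000 genes and 200 pathways, a 200 x 1000
    pathway-drug matrix with 5 planted candidate drugs and 5 known drugs,
    and a small validation network.  The drug panel must be two orders of
    magnitude larger than the planted-signal group for the Gaussian
    p < 0.001 tail to be able to contain every planted drug: with k
    elevated drugs among n, population z-scores are bounded near
    sqrt((n - k)/k), and the known drugs' self-label offset inflates the
    score variance further, so the smallest planted-candidate z clears
    the 3.09 selection cut only when the background panel is large and
    the planted enrichment (0.9) stands well above the matrix noise
    (sd 0.05).
    """

    n_genes: int = 2000
    n_samples_per_class: int = 30
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (15, 40)
    n_datasets: int = 4
    n_planted_pathways: int = 10
    effect_size: float = 2.0  # case shift of planted-pathway genes, in sd units
    n_drugs: int = 1000
    n_candidate_drugs: int = 5
    n_known_drugs: int = 5
    es_signal_mean: float = 0.9
    es_noise_sd: float = 0.05
    n_validation_genes: int = 40
    n_validation_extra_drugs: int = 10
    n_hub_drugs: int = 1
    validation_edge_prob: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("pathway_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("pathway sizes exceed the gene count")
        if self.n_planted_pathways > self.n_pathways:
            raise ValueError("more planted pathways than pathways")
        if self.n_candidate_drugs + self.n_known_drugs > self.n_drugs:
            raise ValueError("planted drug counts exceed the drug panel")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.es_signal_mean > 1:
            raise ValueError("es_signal_mean must be <= 1 (enrichment scores live in [-1, 1])")
        if self.es_noise_sd < 0:
            raise ValueError("es_noise_sd must be >= 0")
        if self.n_hub_drugs > self.n_candidate_drugs:
            raise ValueError("hub drugs must be a subset of the planted candidates")
        if not 0 <= self.validation_edge_prob <= 1:
            raise ValueError("validation_edge_prob must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


def _gene_ids(sc: SimulationScenario) -> list[str]:
    return [f"G{i:05d}" for i in range(sc.n_genes)]


def _drug_ids(sc: SimulationScenario) -> list[str]:
    return [f"D{i:04d}" for i in range(sc.n_drugs)]


@dataclass
class PathwayStructure:
    gene_sets: GeneSetCollection
    planted_pathways: list[str]
    shifted_genes: set[str]


def pathway_structure(sc: SimulationScenario) -> PathwayStructure:
    """Pathway memberships and the planted disease-pathway subset.

    Shared by the expression and drug-matrix generators so both see the
    same pathway universe for a given seed.
    """
    rng = sc.rng(_STREAM_PATHWAYS)
    genes = np.array(_gene_ids(sc))
    lo, hi = sc.pathway_size_range
    sets: dict[str, set[str]] = {}
    for i in range(sc.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(sc.n_genes, size=size, replace=False)
        sets[f"PW{i:04d}"] = set(genes[members])
    planted_idx = rng.choice(sc.n_pathways, size=sc.n_planted_pathways, replace=False)
    planted = sorted(f"PW{i:04d}" for i in planted_idx)
    shifted = set().union(*(sets[p] for p in planted)) if planted else set()
    return PathwayStructure(GeneSetCollection(sets), planted, shifted)


def simulate_expression_datasets(
    sc: SimulationScenario,
) -> tuple[list[ExpressionDataset], GeneSetCollection, list[str]]:
    """Independent case/control cohorts with planted differential pathways.

    Control expression is Normal(0, 1) per gene; genes belonging to any
    planted disease pathway are shifted by +``effect_size`` in cases.
    Returns (datasets, pathway collection, planted pathway names).
    """
    structure = pathway_structure(sc)
    genes = _gene_ids(sc)
    shifted_rows = np.array([g in structure.shifted_genes for g in genes])
    rng = sc.rng(_STREAM_EXPRESSION)
    n = sc.n_samples_per_class
    labels = [CASE] * n + [CONTROL] * n
    datasets = []
    for d in range(sc.n_datasets):
        x = rng.standard_normal((sc.n_genes, 2 * n))
        x[np.ix_(shifted_rows, np.arange(n))] += sc.effect_size
        datasets.append(ExpressionDataset(genes, x, labels, name=f"SIM{d + 1}"))
    return datasets, structure.gene_sets, structure.planted_pathways


@dataclass
class DrugMatrixTruth:
    matrix: PathwayDrugMatrix
    candidate_drugs: list[str]
    known_drugs: list[str]
    planted_pathways: list[str]


def simulate_drug_phenotype_matrix(sc: SimulationScenario) -> DrugMatrixTruth:
    """Pathway-drug ES matrix with planted signal drugs.

    Background scores are Normal(0, ``es_noise_sd``) truncated to [-1, 1].
    The planted candidate drugs and the known drugs receive |ES| around
    ``es_signal_mean`` (random sign) on the planted disease pathways, so
    that drugs treating the phenotype share the pathways they perturb.
    """
    structure = pathway_structure(sc)
    rng = sc.rng(_STREAM_DRUGS)
    pathway_ids = sorted(structure.gene_sets.sets)
    drug_ids = _drug_ids(sc)
    es = np.clip(rng.normal(0.0, sc.es_noise_sd, size=(sc.n_pathways, sc.n_drugs)), -1.0, 1.0)

    n_signal = sc.n_candidate_drugs + sc.n_known_drugs
    signal_idx = rng.choice(sc.n_drugs, size=n_signal, replace=False)
    known_idx = signal_idx[: sc.n_known_drugs]
    candidate_idx = signal_idx[sc.n_known_drugs :]
    planted_rows = np.array([pathway_ids.index(p) for p in structure.planted_pathways], dtype=int)
    for j in signal_idx:
        mag = np.clip(rng.normal(sc.es_signal_mean, 0.05, size=planted_rows.size), 0.05, 1.0)
        sign = rng.choice([-1.0, 1.0], size=planted_rows.size)
        es[planted_rows, j] = sign * mag

    matrix = PathwayDrugMatrix(pathway_ids, drug_ids, es)
    return DrugMatrixTruth(
        matrix=matrix,
        candidate_drugs=sorted(drug_ids[i] for i in candidate_idx),
        known_drugs=sorted(drug_ids[i] for i in known_idx),
        planted_pathways=list(structure.planted_pathways),
    )


@dataclass
class ValidationNetworkTruth:
    edges: pd.DataFrame  # raw edge list incl. a 'planted' flag column
    network: HeterogeneousNetwork
    hub_drugs: list[str]
    known_drugs: list[str]


def simulate_validation_network(
    sc: SimulationScenario,
    weight_min: float = 0.4,
    neighbor_cap: int = 40,
) -> ValidationNetworkTruth:
    """Drug-gene validation network with planted hub drugs.

    Hub drugs (a subset of the planted candidates) connect to every known
    drug and to most target genes with Uniform(0.7, 0.99) weights;
    background edges are Erdos-Renyi with Uniform(0.2, 0.6) weights so
    the default 0.4 cutoff removes about half of them.
    """
    truth = simulate_drug_phenotype_matrix(sc)
    rng = sc.rng(_STREAM_VALNET)
    extra = [d for d in _drug_ids(sc) if d not in set(truth.candidate_drugs + truth.known_drugs)]
    drugs = sorted(truth.known_drugs + truth.candidate_drugs + extra[: sc.n_validation_extra_drugs])
    genes = [f"TG{i:03d}" for i in range(sc.n_validation_genes)]
    hub_drugs = sorted(truth.candidate_drugs)[: sc.n_hub_drugs]

    rows: list[tuple[str, str, str, float, bool]] = []
    hub_set = set(hub_drugs)
    for hub in hub_drugs:
        for kd in truth.known_drugs:
            rows.append((hub, kd, "drug-drug", float(rng.uniform(0.7, 0.99)), True))
        for gene in genes:
            if rng.random() < 0.9:
                rows.append((hub, gene, "drug-gene", float(rng.uniform(0.7, 0.99)), True))

    def background(a: str, b: str, etype: str) -> None:
        if rng.random() < sc.validation_edge_prob:
            rows.append((a, b, etype, float(rng.uniform(0.2, 0.6)), False))

    for i, d1 in enumerate(drugs):
        for d2 in drugs[i + 1 :]:
            if not (d1 in hub_set and d2 in set(truth.known_drugs)) and not (
                d2 in hub_set and d1 in set(truth.known_drugs)
            ):
                background(d1, d2, "drug-drug")
        for gene in genes:
            if d1 not in hub_set:
                background(d1, gene, "drug-gene")
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            background(g1, g2, "gene-gene")

    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "edge_type", "weight", "planted"])
    network = assemble_validation_network(
        edges[["node_a", "node_b", "edge_type", "weight"]],
        weight_min=weight_min,
        neighbor_cap=neighbor_cap,
    )
    return ValidationNetworkTruth(edges=edges, network=network, hub_drugs=hub_drugs, known_drugs=truth.known_drugs)
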