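"""Heterogeneous drug-gene validation network and topology metrics.

Candidate drugs are triaged on a network assembled from drug-drug
chemical-similarity edges, drug-gene target edges and gene-gene
interaction edges (STITCH/STRING-style scores rescaled to [0, 1]).
Assembly keeps only edges with weight strictly above a cutoff (default
0.4) and caps each drug at its strongest ``neighbor_cap`` neighbors
(default 40).  Triage metrics: degree centrality degree/(n-1),
unnormalized shortest-path betweenness, and weighted PageRank
(damping 0.85) reported both raw (sums to 1) and min-max scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_TYPES = ("drug-drug", "drug-gene", "gene-gene")
EDGE_COLUMNS = ["node_a", "node_b", "edge_type", "weight"]


@dataclass
class HeterogeneousNetwork:
    """Undirected weighted graph whose nodes are drugs or genes."""

    graph: nx.Graph

    @property
    def drugs(self) -> list[str]:
        return sorted(n for n, k in self.graph.nodes(data="kind") if k == "drug")

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, k in self.graph.nodes(data="kind") if k == "gene")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _as_edge_frame(edge_lists) -> pd.DataFrame:
    if isinstance(edge_lists, pd.DataFrame):
        df = edge_lists.copy()
    else:
        df = pd.DataFrame(list(edge_lists), columns=EDGE_COLUMNS)
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    bad = set(df["edge_type"]) - set(EDGE_TYPES)
    if bad:
        raise ValueError(f"unknown edge types: {sorted(bad)}")
    df["weight"] = df["weight"].astype(float)
    return df[EDGE_COLUMNS]


def _node_kinds(df: pd.DataFrame) -> dict[str, str]:
    """Infer node kinds; node_a is the drug in drug-gene rows."""
    kinds: dict[str, str] = {}

    def put(node: str, kind: str) -> None:
        prev = kinds.setdefault(node, kind)
        if prev != kind:
            raise ValueError(f"node {node!r} appears as both drug and gene")

    for a, b, etype in zip(df["node_a"], df["node_b"], df["edge_type"]):
        ka, kb = etype.split("-")
        put(a, ka)
        put(b, kb)
    return kinds


def assemble_validation_network(
    edge_lists: pd.DataFrame | Iterable[tuple],
    weight_min: float = 0.4,
    neighbor_cap: int = 40,
    rescale_divisor: float | None = None,
) -> HeterogeneousNetwork:
    """Filter, deduplicate and cap the raw edge lists into a network.

    Rules, in order: optional division of all weights by
    ``rescale_divisor`` (required when any weight exceeds 1, e.g. STITCH
    0-900 integer scores); duplicate edges collapsed keeping the maximum
    weight; edges with weight <= ``weight_min`` dropped (strict
    inequality); each drug keeps only its ``neighbor_cap`` strongest
    incident edges (ties broken by neighbor id), and an edge between two
    drugs must be retained by both; gene-gene edges survive only if both
    endpoint genes remain attached to some retained drug edge.
    """
    df = _as_edge_frame(edge_lists)
    if rescale_divisor is not None:
        if rescale_divisor <= 0:
            raise ValueError("rescale_divisor must be positive")
        df["weight"] = df["weight"] / rescale_divisor
    if (df["weight"] > 1).any():
        raise ValueError(
            "edge weights exceed 1; supply rescale_divisor (e.g. 1000 for STITCH 0-900 scores)"
        )
    if (df["weight"] < 0).any():
        raise ValueError("edge weights must be nonnegative")
    kinds = _node_kinds(df)

    # canonical undirected key; duplicates keep the maximum weight
    pairs = [tuple(sorted((a, b))) for a, b in zip(df["node_a"], df["node_b"])]
    df = df.assign(lo=[p[0] for p in pairs], hi=[p[1] for p in pairs])
    df = df.loc[df["lo"] != df["hi"]]
    df = (
        df.sort_values("weight", ascending=False)
        .drop_duplicates(["lo", "hi"], keep="first")
        .reset_index(drop=True)
    )
    df = df[df["weight"] > weight_min]

    # per-drug cap: strongest neighbor_cap incident edges, ties by neighbor id
    keep_per_drug: dict[str, set[tuple[str, str]]] = {}
    for drug in (n for n, k in kinds.items() if k == "drug"):
        inc = df[(df["lo"] == drug) | (df["hi"] == drug)]
        if inc.empty:
            continue
        neighbor = np.where(inc["lo"] == drug, inc["hi"], inc["lo"])
        ranked = inc.assign(nb=neighbor).sort_values(["weight", "nb"], ascending=[False, True])
        top = ranked.head(neighbor_cap)
        keep_per_drug[drug] = set(zip(top["lo"], top["hi"]))

    def edge_kept(key: tuple[str, str]) -> bool:
        for node in key:
            if kinds[node] == "drug" and key not in keep_per_drug.get(node, set()):
                return False
        return True

    drug_rows = df[df["edge_type"] != "gene-gene"]
    if not drug_rows.empty:
        drug_rows = drug_rows[[edge_kept((lo, hi)) for lo, hi in zip(drug_rows["lo"], drug_rows["hi"])]]

    surviving_genes = {
        n
        for lo, hi in zip(drug_rows["lo"], drug_rows["hi"])
        for n in (lo, hi)
        if kinds[n] == "gene"
    }
    gg = df[df["edge_type"] == "gene-gene"]
    gg = gg[gg["lo"].isin(surviving_genes) & gg["hi"].isin(surviving_genes)]

    kept = pd.concat([drug_rows, gg], ignore_index=True)
    if kept.empty:
        raise ValueError("validation network is empty after filtering")

    g = nx.Graph()
    for row in kept.itertuples():
        g.add_node(row.lo, kind=kinds[row.lo])
        g.add_node(row.hi, kind=kinds[row.hi])
        g.add_edge(row.lo, row.hi, weight=row.weight, edge_type=row.edge_type)
    net = HeterogeneousNetwork(g)
    logger.info(
        "validation network: %d drugs, %d genes, %d edges",
        len(net.drugs),
        len(net.genes),
        net.n_edges,
    )
    return net


def degree_centrality(net: HeterogeneousNetwork) -> pd.Series:
    """Unweighted degree / (n - 1) per node."""
    if net.n_nodes < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return pd.Series(nx.degree_centrality(net.graph), name="degree_centrality").sort_index()


def betweenness(net: HeterogeneousNetwork) -> pd.Series:
    """Unnormalized shortest-path betweenness on the unweighted graph.

    Each unordered pair is counted once, with fractional credit split
    among equal-length shortest paths (matches the small-integer scale of
    hand-counted bottleneck tallies).
    """
    bc = nx.betweenness_centrality(net.graph, normalized=False, weight=None)
    return pd.Series(bc, name="betweenness").sort_index()


def pagerank(
    net: HeterogeneousNetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> tuple[pd.Series, pd.Series]:
    """Weighted PageRank: (raw scores summing to 1, min-max scaled scores).

    Each undirected edge acts as two directed arcs with transition
    probability proportional to its weight.  When all raw scores coincide
    the scaled values are undefined and returned as NaN with a warning.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    try:
        pr = nx.pagerank(net.graph, alpha=damping, weight="weight", tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(f"PageRank power iteration failed to converge in {max_iter} iterations") from exc
    raw = pd.Series(pr, name="pagerank_raw").sort_index()
    span = raw.max() - raw.min()
    if span == 0:
        logger.warning("all PageRank scores equal; min-max scaling undefined")
        scaled = pd.Series(np.nan, index=raw.index, name="pagerank_scaled")
    else:
        scaled = ((raw - raw.min()) / span).rename("pagerank_scaled")
    return raw, scaled


def topology_metrics(net: HeterogeneousNetwork, damping: float = 0.85) -> pd.DataFrame:
    """All triage metrics in one per-node table (index: node id)."""
    raw, scaled = pagerank(net, damping=damping)
    df = pd.concat([degree_centrality(net), betweenness(net), raw, scaled], axis=1)
    df.insert(0, "kind", pd.Series(dict(net.graph.nodes(data="kind"))))
    return df.sort_index()
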