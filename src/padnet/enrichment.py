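"""Gene-set enrichment of case/control expression profiles.

Implements the weighted Kolmogorov-Smirnov running-sum enrichment score
(GSEA-style), a permutation null for nominal p-values and normalized
enrichment scores, and the integration of per-dataset significant pathways
into a disease-specific pathway set (the union of pathways with nominal
p below a threshold in at least one dataset).

Ranking uses the signal-to-noise metric
``(mean_case - mean_control) / (sd_case + sd_control)`` with each standard
deviation floored at ``max(sd, 0.2*|mean|, eps)``.  Ties are broken by
lexicographic gene id so rankings are fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fraction of |mean| used to floor a class standard deviation
SD_FLOOR_FRACTION = 0.2
_EPS = 1e-8

#: phenotype permutation requires at least this many samples per class;
#: below it the null falls back to gene-set permutation (GSEA convention)
MIN_CLASS_FOR_PHENOTYPE_PERM = 7

CASE = "case"
CONTROL = "control"


class NoOverlapError(ValueError):
    """Raised when a gene set shares no genes with the ranked list."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A genes x samples log-expression matrix with case/control labels."""

    gene_ids: list[str]
    values: np.ndarray
    sample_labels: list[str]
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_labels = list(self.sample_labels)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene id count does not match matrix rows")
        if self.values.shape[1] != len(self.sample_labels):
            raise ValueError("sample label count does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids (collapse probes first)")
        bad = set(self.sample_labels) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"sample labels must be 'case'/'control', got {sorted(bad)}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s == CASE for s in self.sample_labels])

    @property
    def control_mask(self) -> np.ndarray:
        return ~self.case_mask

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSetCollection:
    """Named pathways, each a set of gene symbols (GMT-backed)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


@dataclass
class RankedGeneList:
    """Genes ordered by the ranking metric, descending."""

    gene_ids: list[str]
    metric_values: np.ndarray

    def __post_init__(self) -> None:
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if len(self.gene_ids) != len(self.metric_values):
            raise ValueError("gene ids and metric values differ in length")
        if not np.isfinite(self.metric_values).all():
            raise ValueError("ranking metric contains non-finite values")


@dataclass
class EnrichmentResult:
    """Enrichment of one pathway in one case/control contrast.

    ``nes`` is NaN when no same-sign permutation score exists.
    """

    pathway_name: str
    es: float
    nes: float
    nominal_p: float
    n_genes_matched: int


@dataclass
class DiseasePathwaySet:
    """Union of significant pathways across datasets, with provenance."""

    pathway_names: set[str]
    provenance: dict[str, list[str]]

    def __len__(self) -> int:
        return len(self.pathway_names)

    def __contains__(self, name: str) -> bool:
        return name in self.pathway_names


# ---------------------------------------------------------------------------
# probe collapsing and ranking
# ---------------------------------------------------------------------------


def collapse_probes(
    probe_matrix: pd.DataFrame,
    mapping: Mapping[str, str] | pd.Series,
    sample_labels: Sequence[str],
    *,
    missing: str = "reject",
    name: str = "dataset",
) -> ExpressionDataset:
    """Collapse a probes x samples matrix to unique gene symbols.

    Probes with no mapped symbol are discarded; multiple probes mapping to
    the same gene are averaged element-wise.  Rows with missing values are
    dropped (``missing='reject'``, default) or row-mean imputed
    (``missing='impute'``) before collapsing.
    """
    if missing not in ("reject", "impute"):
        raise ValueError("missing policy must be 'reject' or 'impute'")
    if probe_matrix.index.has_duplicates:
        raise ValueError("probe ids must be unique")
    map_s = mapping if isinstance(mapping, pd.Series) else pd.Series(dict(mapping))

    df = probe_matrix.astype(float)
    if df.isna().any().any():
        if missing == "reject":
            n_before = len(df)
            df = df.dropna(axis=0)
            logger.warning("%s: dropped %d probe rows with missing values", name, n_before - len(df))
        else:
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)

    symbols = map_s.reindex(df.index)
    mapped = symbols.notna()
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.info("%s: discarded %d probes with no gene symbol", name, n_dropped)
    df = df.loc[mapped]
    if df.empty:
        raise ValueError("probe mapping matched no probes: unusable mapping")
    collapsed = df.groupby(symbols[mapped].to_numpy()).mean()
    return ExpressionDataset(list(collapsed.index), collapsed.to_numpy(), sample_labels, name=name)


def _floored_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    return np.maximum(sd, np.maximum(SD_FLOOR_FRACTION * np.abs(mean), _EPS))


def signal_to_noise(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio with the GSEA sd floor."""
    m1, m0 = case.mean(axis=1), control.mean(axis=1)
    s1 = _floored_sd(case.std(axis=1, ddof=1), m1)
    s0 = _floored_sd(control.std(axis=1, ddof=1), m0)
    return (m1 - m0) / (s1 + s0)


def rank_genes(ds: ExpressionDataset) -> RankedGeneList:
    """Rank genes by signal-to-noise, descending; ties lexicographic by id."""
    case = ds.values[:, ds.case_mask]
    control = ds.values[:, ds.control_mask]
    for cls, block in ((CASE, case), (CONTROL, control)):
        if block.shape[1] < 2:
            raise ValueError(f"class '{cls}' has fewer than 2 samples; cannot rank")
    metric = signal_to_noise(case, control)
    # lexsort: last key is primary -> metric descending, gene id ascending on ties
    order = np.lexsort((np.asarray(ds.gene_ids, dtype=object), -metric))
    return RankedGeneList([ds.gene_ids[i] for i in order], metric[order])


# ---------------------------------------------------------------------------
# enrichment score (weighted KS running sum)
# ---------------------------------------------------------------------------


def _running_sum_es(member: np.ndarray, abs_metric: np.ndarray, p: float) -> float:
    """Signed maximal deviation of the weighted KS running sum for one set."""
    n = member.size
    n_hit = int(member.sum())
    w = abs_metric**p
    hit_total = w[member].sum()
    if hit_total <= 0.0:  # all hit metrics zero: fall back to unweighted steps
        incr = np.where(member, 1.0 / n_hit, 0.0)
    else:
        incr = np.where(member, w / hit_total, 0.0)
    if n_hit < n:
        incr = incr - np.where(member, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(incr)
    return float(running[np.argmax(np.abs(running))])


def enrichment_score(ranked: RankedGeneList, gene_set: Iterable[str], weight_exponent: float = 1.0) -> float:
    """Weighted KS enrichment score of ``gene_set`` in the ranked list.

    Hits add ``|metric|^p / sum_hits |metric|^p``; misses subtract
    ``1/(N - k)``.  The score is the running-sum value of maximal absolute
    deviation from zero (signed), always in [-1, 1].  Set genes absent from
    the ranking are ignored (count logged).
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    gene_set = set(gene_set)
    member = np.fromiter((g in gene_set for g in ranked.gene_ids), dtype=bool, count=len(ranked.gene_ids))
    n_hit = int(member.sum())
    if n_hit == 0:
        raise NoOverlapError("gene set has no overlap with the ranked list")
    n_absent = len(gene_set) - n_hit
    if n_absent:
        logger.debug("%d set genes absent from the ranking (ignored)", n_absent)
    return _running_sum_es(member, np.abs(ranked.metric_values), weight_exponent)


def _es_batch(member_ordered: np.ndarray, abs_metric_ordered: np.ndarray, p: float) -> np.ndarray:
    """Enrichment scores for many sets against one ranking.

    ``member_ordered``: (n_sets, N) boolean membership in rank order.
    Every row must have at least one hit.
    """
    n_sets, n = member_ordered.shape
    w = abs_metric_ordered**p
    hit_tot = member_ordered @ w
    n_hit = member_ordered.sum(axis=1)
    degenerate = hit_tot <= 0.0
    hit_tot = np.where(degenerate, 1.0, hit_tot)
    hit_incr = np.where(degenerate[:, None], 1.0 / n_hit[:, None], (w / hit_tot[:, None]))
    n_miss = n - n_hit
    miss_pen = np.divide(1.0, n_miss, out=np.zeros(n_sets), where=n_miss > 0)
    incr = np.where(member_ordered, hit_incr, -miss_pen[:, None])
    running = np.cumsum(incr, axis=1)
    idx = np.abs(running).argmax(axis=1)
    return running[np.arange(n_sets), idx]


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _lex_sorted(ds: ExpressionDataset) -> tuple[list[str], np.ndarray]:
    order = np.argsort(np.asarray(ds.gene_ids, dtype=object), kind="stable")
    return [ds.gene_ids[i] for i in order], ds.values[order]


def _membership_matrix(gene_ids: Sequence[str], sets: Sequence[set[str]]) -> np.ndarray:
    index = {g: i for i, g in enumerate(gene_ids)}
    m = np.zeros((len(sets), len(gene_ids)), dtype=bool)
    for row, members in enumerate(sets):
        for g in members:
            i = index.get(g)
            if i is not None:
                m[row, i] = True
    return m


def _phenotype_perm_metrics(values: np.ndarray, case_mask: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Signal-to-noise metrics (genes x n_perm) under label permutation."""
    n_s = case_mask.size
    n1 = int(case_mask.sum())
    n0 = n_s - n1
    perm_case = np.empty((n_s, n_perm), dtype=float)
    for j in range(n_perm):
        perm_case[:, j] = rng.permutation(case_mask.astype(float))
    v, v2 = values, values**2
    sum1 = v @ perm_case
    sum2_1 = v2 @ perm_case
    tot = v.sum(axis=1, keepdims=True)
    tot2 = v2.sum(axis=1, keepdims=True)
    m1 = sum1 / n1
    m0 = (tot - sum1) / n0
    var1 = np.maximum(sum2_1 - n1 * m1**2, 0.0) / (n1 - 1)
    var0 = np.maximum((tot2 - sum2_1) - n0 * m0**2, 0.0) / (n0 - 1)
    s1 = _floored_sd(np.sqrt(var1), m1)
    s0 = _floored_sd(np.sqrt(var0), m0)
    return (m1 - m0) / (s1 + s0)


def _null_es(
    ds: ExpressionDataset,
    member: np.ndarray,
    obs_order: np.ndarray,
    obs_metric: np.ndarray,
    weight_exponent: float,
    n_perm: int,
    rng: np.random.Generator,
    scheme: str,
) -> np.ndarray:
    """(n_sets, n_perm) permutation enrichment scores.

    ``member`` is membership over lexicographically sorted genes;
    ``obs_order``/``obs_metric`` describe the observed ranking of those genes.
    """
    n_sets = member.shape[0]
    es_null = np.empty((n_sets, n_perm))
    if scheme == "phenotype":
        values = ds.values  # caller passes lex-sorted values via ds
        metrics = _phenotype_perm_metrics(values, ds.case_mask, n_perm, rng)
        for j in range(n_perm):
            mj = metrics[:, j]
            order = np.argsort(-mj, kind="stable")
            es_null[:, j] = _es_batch(member[:, order], np.abs(mj[order]), weight_exponent)
    elif scheme == "geneset":
        m_obs = member[:, obs_order]
        w_obs = np.abs(obs_metric)
        for j in range(n_perm):
            sigma = rng.permutation(member.shape[1])
            es_null[:, j] = _es_batch(m_obs[:, sigma], w_obs, weight_exponent)
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return es_null


def _p_and_nes(es_obs: float, es_null_row: np.ndarray, n_perm: int) -> tuple[float, float, int]:
    """Add-one nominal p and NES from the same-sign permutation scores."""
    if es_obs == 0.0:
        return 1.0, float("nan"), 0
    same_sign = es_null_row * es_obs > 0
    n_ss = int(same_sign.sum())
    if n_ss == 0:
        return 1.0 / (1.0 + n_perm), float("nan"), 0
    extreme = int((np.abs(es_null_row[same_sign]) >= abs(es_obs)).sum())
    p = (1.0 + extreme) / (1.0 + n_ss)
    nes = es_obs / np.abs(es_null_row[same_sign]).mean()
    return p, float(nes), n_ss


def _resolve_scheme(ds: ExpressionDataset, scheme: str) -> str:
    if scheme not in ("auto", "phenotype", "geneset"):
        raise ValueError("scheme must be 'auto', 'phenotype' or 'geneset'")
    if scheme != "auto":
        return scheme
    min_class = min(int(ds.case_mask.sum()), int(ds.control_mask.sum()))
    if min_class < MIN_CLASS_FOR_PHENOTYPE_PERM:
        logger.info("%s: %d samples in smallest class -> gene-set permutation", ds.name, min_class)
        return "geneset"
    return "phenotype"


@dataclass
class NominalPResult:
    """Permutation significance of a single enrichment score."""

    es: float
    nominal_p: float
    nes: float
    n_same_sign: int


def nominal_p(
    ds: ExpressionDataset,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    weight_exponent: float = 1.0,
    scheme: str = "auto",
) -> NominalPResult:
    """Permutation nominal p-value and NES for one gene set.

    The null permutes phenotype labels by default, falling back to gene-set
    permutation when the smallest class has fewer than
    ``MIN_CLASS_FOR_PHENOTYPE_PERM`` samples.  ``nominal_p`` uses the add-one
    estimator ``(1 + extreme) / (1 + same_sign)`` so it is never zero; NES is
    ES divided by the mean absolute same-sign permutation ES (NaN when no
    same-sign permutation score exists).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    results = _enrich_core(ds, [set(gene_set)], n_perm, seed, weight_exponent, scheme)
    es, p, nes, n_ss = results[0]
    return NominalPResult(es=es, nominal_p=p, nes=nes, n_same_sign=n_ss)


def _enrich_core(
    ds: ExpressionDataset,
    sets: Sequence[set[str]],
    n_perm: int,
    seed: int | None,
    weight_exponent: float,
    scheme: str,
) -> list[tuple[float, float, float, int]]:
    """Observed ES plus permutation (p, nes, n_same_sign) for each set."""
    scheme = _resolve_scheme(ds, scheme)
    rng = np.random.default_rng(seed)
    gene_ids, values = _lex_sorted(ds)
    lex_ds = ExpressionDataset(gene_ids, values, ds.sample_labels, name=ds.name)
    member = _membership_matrix(gene_ids, sets)
    if (member.sum(axis=1) == 0).any():
        raise NoOverlapError("a gene set has no overlap with the dataset genes")

    metric = signal_to_noise(values[:, lex_ds.case_mask], values[:, lex_ds.control_mask])
    obs_order = np.argsort(-metric, kind="stable")  # lex genes -> ties lexicographic
    obs_metric = metric[obs_order]
    es_obs = _es_batch(member[:, obs_order], np.abs(obs_metric), weight_exponent)
    es_null = _null_es(lex_ds, member, obs_order, obs_metric, weight_exponent, n_perm, rng, scheme)

    out = []
    for i in range(len(sets)):
        p, nes, n_ss = _p_and_nes(float(es_obs[i]), es_null[i], n_perm)
        out.append((float(es_obs[i]), p, nes, n_ss))
    return out


def enrich_dataset(
    ds: ExpressionDataset,
    gene_sets: GeneSetCollection,
    *,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_overlap: int = 5,
    scheme: str = "auto",
) -> list[EnrichmentResult]:
    """Enrichment of every pathway with >= ``min_overlap`` matched genes."""
    if len(gene_sets) == 0:
        raise ValueError("empty gene-set collection")
    gene_universe = set(ds.gene_ids)
    names, sets, overlaps = [], [], []
    for name in gene_sets:
        k = len(gene_sets[name] & gene_universe)
        if k >= min_overlap:
            names.append(name)
            sets.append(gene_sets[name])
            overlaps.append(k)
        else:
            logger.info("%s: pathway %s skipped (overlap %d < %d)", ds.name, name, k, min_overlap)
    if not names:
        return []
    core = _enrich_core(ds, sets, n_perm, seed, weight_exponent, scheme)
    return [
        EnrichmentResult(pathway_name=name, es=es, nes=nes, nominal_p=p, n_genes_matched=k)
        for name, k, (es, p, nes, _) in zip(names, overlaps, core)
    ]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "n_matched": [r.n_genes_matched for r in results],
        }
    )


# ---------------------------------------------------------------------------
# cross-dataset integration
# ---------------------------------------------------------------------------


def integrate_disease_pathways(
    results_per_dataset: Sequence[Sequence[EnrichmentResult]],
    p_threshold: float = 0.01,
    dataset_names: Sequence[str] | None = None,
) -> DiseasePathwaySet:
    """Union of pathways with nominal p < threshold in any dataset."""
    if not results_per_dataset:
        raise ValueError("need results from at least one dataset")
    if dataset_names is None:
        dataset_names = [f"dataset_{i + 1}" for i in range(len(results_per_dataset))]
    provenance: dict[str, list[str]] = {}
    for dname, results in zip(dataset_names, results_per_dataset):
        for r in results:
            if r.nominal_p < p_threshold:
                provenance.setdefault(r.pathway_name, []).append(dname)
    if not provenance:
        logger.warning("no pathway passed p < %g in any dataset; union is empty", p_threshold)
    return DiseasePathwaySet(pathway_names=set(provenance), provenance=provenance)
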