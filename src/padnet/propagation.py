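"""Semisupervised label propagation over the normalized bipartite graph.

Known-positive pathway and drug nodes carry label 1; everything else 0.
Labels diffuse by the Jacobi iteration

    f_v(t) = (1 - alpha) y_v + alpha * sum_u B[u, v] f_u(t-1)
    f_u(t) = (1 - alpha) y_u + alpha * sum_v B[u, v] f_v(t-1)

where both updates read the previous iterate.  Because the symmetric
normalization has spectral norm <= 1, the map is a contraction with
factor alpha < 1 and converges to the fixed point

    f = (1 - alpha) (I - alpha * M)^{-1} y,   M = [[0, B], [B^T, 0]],

which ``propagate_closed_form`` computes directly as a test oracle and a
small-problem shortcut.  For binary labels every score lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .enrichment import DiseasePathwaySet
from .network import BipartiteGraph, NormalizedBipartite

logger = logging.getLogger(__name__)


@dataclass
class LabelAssignment:
    """Binary initial labels for pathway (y_u) and drug (y_v) nodes."""

    pathway_ids: list[str]
    drug_ids: list[str]
    y_u: np.ndarray
    y_v: np.ndarray
    unmatched_pathways: list[str]
    unmatched_drugs: list[str]

    def __post_init__(self) -> None:
        self.y_u = np.asarray(self.y_u, dtype=float)
        self.y_v = np.asarray(self.y_v, dtype=float)
        if set(np.unique(self.y_u)) - {0.0, 1.0} or set(np.unique(self.y_v)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")


@dataclass
class PropagationConfig:
    alpha: float = 0.8
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int | None = None  # reserved; the iteration is deterministic

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class PropagationScores:
    pathway_ids: list[str]
    drug_ids: list[str]
    f_u: np.ndarray
    f_v: np.ndarray
    n_iter: int
    converged: bool
    residual: float

    def drug_scores(self) -> dict[str, float]:
        return dict(zip(self.drug_ids, map(float, self.f_v)))


def _normalize_id(name: str, case_insensitive: bool) -> str:
    return name.lower() if case_insensitive else name


def initialize_labels(
    g: BipartiteGraph,
    disease_pathways: DiseasePathwaySet | Iterable[str],
    known_drugs: Sequence[str],
    *,
    case_insensitive: bool = True,
) -> LabelAssignment:
    """Label matched disease pathways and known drugs 1, everything else 0.

    Matching is exact string equality after optional lower-casing (the
    default).  Names that fail to match any node are returned in the
    ``unmatched_*`` lists and logged: with real drug vocabularies heavy
    mapping loss is normal and must be visible, not silent.
    """
    if isinstance(disease_pathways, DiseasePathwaySet):
        pathway_names = set(disease_pathways.pathway_names)
    else:
        pathway_names = set(disease_pathways)
    norm = lambda s: _normalize_id(s, case_insensitive)  # noqa: E731

    want_u = {norm(p) for p in pathway_names}
    want_v = {norm(d) for d in known_drugs}
    y_u = np.array([1.0 if norm(p) in want_u else 0.0 for p in g.pathway_ids])
    y_v = np.array([1.0 if norm(d) in want_v else 0.0 for d in g.drug_ids])

    have_u = {norm(p) for p in g.pathway_ids}
    have_v = {norm(d) for d in g.drug_ids}
    unmatched_p = sorted(p for p in pathway_names if norm(p) not in have_u)
    unmatched_d = sorted(d for d in known_drugs if norm(d) not in have_v)
    if unmatched_p:
        logger.warning("%d/%d disease pathways not present in the network", len(unmatched_p), len(pathway_names))
    if unmatched_d:
        logger.warning("%d/%d known drugs not present in the network", len(unmatched_d), len(set(known_drugs)))
    if y_u.sum() == 0 and y_v.sum() == 0:
        raise ValueError("no disease pathway and no known drug matched any network node")
    if y_u.sum() == 0 or y_v.sum() == 0:
        logger.warning("one-sided initialization: %d pathway and %d drug seeds", int(y_u.sum()), int(y_v.sum()))
    return LabelAssignment(list(g.pathway_ids), list(g.drug_ids), y_u, y_v, unmatched_p, unmatched_d)


def _check_alignment(b: NormalizedBipartite, labels: LabelAssignment) -> None:
    if b.pathway_ids != labels.pathway_ids or b.drug_ids != labels.drug_ids:
        raise ValueError("label assignment does not match the normalized graph's node order")


def propagate(b: NormalizedBipartite, labels: LabelAssignment, cfg: PropagationConfig) -> PropagationScores:
    """Jacobi iteration of the propagation updates until convergence.

    Stops when the maximum absolute change across all node scores drops
    below ``cfg.tol``; returns ``converged=False`` (with a warning) if
    ``cfg.max_iter`` is reached first.
    """
    _check_alignment(b, labels)
    if not np.isfinite(b.b).all():
        raise ValueError("normalized weights contain non-finite entries")
    a = cfg.alpha
    y_u, y_v = labels.y_u, labels.y_v
    f_u, f_v = y_u.copy(), y_v.copy()
    residual = np.inf
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        f_v_new = (1 - a) * y_v + a * (b.b.T @ f_u)
        f_u_new = (1 - a) * y_u + a * (b.b @ f_v)
        residual = max(
            float(np.max(np.abs(f_v_new - f_v), initial=0.0)),
            float(np.max(np.abs(f_u_new - f_u), initial=0.0)),
        )
        f_u, f_v = f_u_new, f_v_new
        if residual < cfg.tol:
            return PropagationScores(b.pathway_ids, b.drug_ids, f_u, f_v, n_iter, True, residual)
    logger.warning("propagation did not converge in %d iterations (residual %.3g)", cfg.max_iter, residual)
    return PropagationScores(b.pathway_ids, b.drug_ids, f_u, f_v, n_iter, False, residual)


def propagate_closed_form(b: NormalizedBipartite, labels: LabelAssignment, alpha: float) -> PropagationScores:
    """Fixed point of the propagation updates by direct linear solve."""
    _check_alignment(b, labels)
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    nu, nv = b.b.shape
    m = np.zeros((nu + nv, nu + nv))
    m[:nu, nu:] = b.b
    m[nu:, :nu] = b.b.T
    y = np.concatenate([labels.y_u, labels.y_v])
    try:
        f = scipy.linalg.solve(np.eye(nu + nv) - alpha * m, (1 - alpha) * y)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - impossible for ||B|| <= 1, alpha < 1
        raise ValueError("singular propagation system") from exc
    return PropagationScores(b.pathway_ids, b.drug_ids, f[:nu], f[nu:], 0, True, 0.0)
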