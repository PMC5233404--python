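"""Z-score normalization of propagated drug scores and candidate selection.

The final drug label scores l are standardized with the population
standard deviation, z_i = (l_i - mean(l)) / sd(l), and converted to
one-sided Gaussian upper-tail p-values via the complementary error
function.  Drugs with p below a threshold (default 0.001) are the
repositioning candidates; removing the already-known drugs leaves the
novel candidates.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

logger = logging.getLogger(__name__)


def zscore_normalize(scores: Sequence[float] | np.ndarray) -> np.ndarray:
    """Population z-scores (divisor n). Errors on constant input."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 scores to z-normalize")
    sd = x.std()  # population sd
    if sd == 0:
        raise ValueError("zero variance: scores are constant, z-score undefined")
    return (x - x.mean()) / sd


def gaussian_p(z: float | np.ndarray) -> float | np.ndarray:
    """One-sided upper-tail standard-normal p-value, via erfc."""
    p = 0.5 * erfc(np.asarray(z, dtype=float) / np.sqrt(2.0))
    return float(p) if np.isscalar(z) or np.ndim(z) == 0 else p


def build_score_table(
    drug_ids: Sequence[str],
    raw_scores: Sequence[float] | np.ndarray,
    known_drugs: Sequence[str] = (),
    p_threshold: float = 0.001,
    *,
    case_insensitive: bool = True,
) -> pd.DataFrame:
    """Per-drug score table: raw score, z, p, known flag, candidate flag.

    Sorted by z descending, ties broken by drug id.  ``candidate`` marks
    drugs with p < ``p_threshold`` (known drugs included; use
    :func:`select_candidates` to split off the novel ones).
    """
    if len(drug_ids) != len(list(raw_scores)):
        raise ValueError("drug ids and scores differ in length")
    z = zscore_normalize(raw_scores)
    p = gaussian_p(z)
    norm = (lambda s: s.lower()) if case_insensitive else (lambda s: s)
    known_set = {norm(d) for d in known_drugs}
    table = pd.DataFrame(
        {
            "drug": list(drug_ids),
            "raw_score": np.asarray(raw_scores, dtype=float),
            "z": z,
            "p": p,
            "known": [norm(d) in known_set for d in drug_ids],
        }
    )
    table["candidate"] = table["p"] < p_threshold
    table = table.sort_values(["z", "drug"], ascending=[False, True], kind="stable").reset_index(drop=True)
    return table


def select_candidates(
    table: pd.DataFrame,
    p_threshold: float,
    known_drugs: Sequence[str],
    *,
    case_insensitive: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a score table at p < threshold into (all selected, novel).

    Both frames are sorted by z descending with lexicographic tie-break.
    The novel frame drops the known drugs.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    norm = (lambda s: s.lower()) if case_insensitive else (lambda s: s)
    known_set = {norm(d) for d in known_drugs}
    selected = (
        table[table["p"] < p_threshold]
        .sort_values(["z", "drug"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    novel = selected[~selected["drug"].map(norm).isin(known_set)].reset_index(drop=True)
    if selected.empty:
        logger.warning("no drug passed p < %g", p_threshold)
    return selected, novel
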