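"""Evaluation: neighbor preservation under dimensionality reduction, and
Precision@R for ranked translation candidates.

A dimensionality reduction is judged by how well it preserves each vector's
*neighborhood*: for every anchor x_j, cosine similarities to the other n-1
vectors are computed before and after projection, and compared with

* Pearson's r over the two similarity lists (absolute agreement), and
* Kendall's tau over the two induced orderings (rank agreement), computed
  from the concordant-pair count C as  tau = 4C / ((n-1)(n-2)) - 1,

then averaged over all anchors. Ties in cosine similarity (common when many
similarities are exactly zero) are broken by neighbor index before forming
the orderings, so both inputs to the tau statistic are genuine permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pvp import reduce_matrix
from .similarity import RankedCandidates

logger = logging.getLogger(__name__)

__all__ = [
    "neighbor_pearson",
    "neighbor_kendall",
    "ordering_by_similarity",
    "cosine_similarities",
    "precision_at_R",
    "neighbor_preservation_experiment",
    "EvalReport",
]


def neighbor_pearson(before: np.ndarray, after: np.ndarray) -> float:
    """Pearson correlation of the two similarity lists; 0 (with a warning)
    when either list has zero variance."""
    before = np.asarray(before, dtype=float).ravel()
    after = np.asarray(after, dtype=float).ravel()
    if before.size != after.size:
        raise ValueError("similarity lists must have equal length")
    if before.size < 2:
        raise ValueError("need at least 2 neighbors")
    b = before - before.mean()
    a = after - after.mean()
    denom = np.sqrt((b @ b) * (a @ a))
    if denom == 0:
        logger.warning("zero variance in a similarity list; Pearson r set to 0")
        return 0.0
    return float((b @ a) / denom)


def ordering_by_similarity(sims: np.ndarray) -> np.ndarray:
    """Neighbor indices in descending similarity, ties broken by index."""
    return np.argsort(-np.asarray(sims, dtype=float), kind="stable")


def _concordant_pairs(phi: np.ndarray, sigma: np.ndarray) -> int:
    k = phi.size
    pos_phi = np.empty(k, dtype=np.int64)
    pos_phi[phi] = np.arange(k)
    pos_sigma = np.empty(k, dtype=np.int64)
    pos_sigma[sigma] = np.arange(k)
    d1 = pos_phi[:, None] - pos_phi[None, :]
    d2 = pos_sigma[:, None] - pos_sigma[None, :]
    return int(np.count_nonzero(d1 * d2 > 0) // 2)


def neighbor_kendall(phi, sigma) -> float:
    """Kendall's tau between two neighbor orderings, from the concordant-pair
    count: tau = 4C / (k (k-1)) - 1 for k neighbors."""
    phi = np.asarray(phi, dtype=np.int64).ravel()
    sigma = np.asarray(sigma, dtype=np.int64).ravel()
    k = phi.size
    if k < 2:
        raise ValueError("need at least 2 neighbors")
    ref = np.arange(k)
    if not (np.array_equal(np.sort(phi), ref) and np.array_equal(np.sort(sigma), ref)):
        raise ValueError("orderings must be permutations of 0..k-1")
    C = _concordant_pairs(phi, sigma)
    return 4.0 * C / (k * (k - 1)) - 1.0


def cosine_similarities(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity matrix; rows with zero norm get similarity
    0 to everything."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    U = X / safe[:, None]
    S = U @ U.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    return S


def precision_at_R(ranked: RankedCandidates | list[str], gold: set[str], R: int) -> float:
    """Fraction of the top-R ranked candidates that are correct translations."""
    if R < 1:
        raise ValueError("R must be >= 1")
    terms = ranked.terms() if isinstance(ranked, RankedCandidates) else list(ranked)
    if R > len(terms):
        logger.warning(
            "R=%d exceeds ranking length %d; computing over the prefix", R, len(terms)
        )
    top = terms[:R]
    return sum(t in gold for t in top) / R


@dataclass
class EvalReport:
    """Per-(method, dimension) mean neighbor-preservation coefficients."""

    table: pd.DataFrame  # columns: method, d, pearson_mean, kendall_mean

    def value(self, method: str, d: int, stat: str) -> float:
        row = self.table[(self.table.method == method) & (self.table.d == d)]
        if row.empty:
            raise KeyError((method, d))
        return float(row.iloc[0][stat])


def _neighbor_stats(S_before: np.ndarray, S_after: np.ndarray) -> tuple[float, float]:
    n = S_before.shape[0]
    rs = np.empty(n)
    taus = np.empty(n)
    mask = ~np.eye(n, dtype=bool)
    for j in range(n):
        b = S_before[j][mask[j]]
        a = S_after[j][mask[j]]
        rs[j] = neighbor_pearson(b, a)
        taus[j] = neighbor_kendall(
            ordering_by_similarity(b), ordering_by_similarity(a)
        )
    return float(rs.mean()), float(taus.mean())


def neighbor_preservation_experiment(
    X,
    methods: list[str],
    dims: list[int],
    seed: int = 0,
    raw_prototypes: bool = False,
    nmf_max_iter: int = 500,
) -> EvalReport:
    """Project X with every (method, d) and report mean Pearson r and mean
    Kendall tau of neighbor preservation, averaged over all anchors."""
    from .pvp import _as_array

    A = _as_array(X)
    if A.size and A.min() < 0:
        raise ValueError("expects non-negative feature vectors")
    S_before = cosine_similarities(A)
    rows = []
    for method in methods:
        for d in dims:
            proj = reduce_matrix(
                A,
                method,
                d,
                seed=seed,
                raw_prototypes=raw_prototypes,
                nmf_max_iter=nmf_max_iter,
            )
            S_after = cosine_similarities(proj.values)
            r_mean, tau_mean = _neighbor_stats(S_before, S_after)
            rows.append(
                {
                    "method": method,
                    "d": d,
                    "pearson_mean": r_mean,
                    "kendall_mean": tau_mean,
                }
            )
            logger.info(
                "%s d=%d: r=%.4f tau=%.4f", method, d, r_mean, tau_mean
            )
    return EvalReport(table=pd.DataFrame(rows))
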