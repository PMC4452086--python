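"""Prototype Vector Projection (PVP) and comparison dimensionality reductions.

PVP selects ``d`` actual data vectors as *prototypes*: in each round the
centroid of the not-yet-selected vectors is computed, every remaining vector
is scored by the number of non-zero entries of its elementwise product with
that centroid, and the argmax is taken (ties go to the lowest original row
index). The selected prototypes are Gram-Schmidt orthonormalized in selection
order and every vector is projected by its inner products with the resulting
basis. Because prototypes are drawn from the data, PVP behaves like a
k-medoid analogue of a linear projection: the basis directions are real,
interpretable feature vectors rather than abstract components.

Comparison methods share the same projection interface:

* ``l2``  — prototypes are the ``d`` rows with the largest Euclidean norm;
* ``svd`` — rank-d truncated SVD scores ``U_d D_d`` with negative entries
  set to zero (Turney's remedy for negative similarities);
* ``nmf`` — rows of the W factor of a non-negative matrix factorization.

A ``raw_prototypes`` mode skips the orthonormalization and projects onto the
prototypes themselves; with non-negative inputs this keeps all projected
values non-negative (the orthonormalized basis does not, since Gram-Schmidt
introduces signed directions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .io import FeatureMatrix

__all__ = [
    "PrototypeBasis",
    "ProjectedMatrix",
    "LinearDependenceError",
    "pvp_score",
    "select_prototypes",
    "orthonormalize",
    "pvp_fit",
    "pvp_project",
    "l2_select_prototypes",
    "svd_project_nonneg",
    "nmf_project",
    "reduce_matrix",
]

DEPENDENCE_TOL = 1e-10


class LinearDependenceError(ValueError):
    """A prototype is (numerically) linearly dependent on earlier ones."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"prototype {index} is linearly dependent on earlier ones")


@dataclass
class PrototypeBasis:
    """Selected prototypes and their orthonormalized basis.

    ``selected_prototypes`` holds the accepted prototype vectors (rows, in
    selection order); ``orthonormal_basis`` the corresponding Gram-Schmidt
    basis; ``indices`` the original row indices of the prototypes.
    """

    selected_prototypes: np.ndarray  # d x m
    orthonormal_basis: np.ndarray  # d x m
    indices: tuple[int, ...]
    source_dim: int
    target_dim: int

    def __post_init__(self) -> None:
        d = self.target_dim
        if self.orthonormal_basis.shape != (d, self.source_dim):
            raise ValueError("basis shape inconsistent with dims")
        G = self.orthonormal_basis @ self.orthonormal_basis.T
        if np.abs(G - np.eye(d)).max() > 1e-8:
            raise ValueError("basis is not orthonormal within 1e-8")


@dataclass
class ProjectedMatrix:
    """n x d projected coordinates with the method that produced them."""

    values: np.ndarray
    method: str  # pvp | l2 | svd | nmf
    d: int

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != self.d:
            raise ValueError("values must be n x d")
        if self.method == "nmf" and self.values.size and self.values.min() < 0:
            raise ValueError("nmf projection must be non-negative")


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        X = X.values
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def pvp_score(x: np.ndarray, c: np.ndarray) -> int:
    """Number of dimensions where the elementwise product x_j * c_j is
    non-zero — the prototype-selection score s(x, c)."""
    x = np.asarray(x).ravel()
    c = np.asarray(c).ravel()
    if x.shape != c.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {c.shape}")
    return int(np.count_nonzero(x * c))


def _iter_prototypes(X: np.ndarray) -> Iterator[int]:
    """Yield row indices in PVP selection order (the full ranking, lazily).

    Relies on non-negativity: the centroid of the remaining rows has a
    non-zero j-th entry exactly when some remaining row does, so the score
    of row x is |supp(x) ∩ union-support(remaining)| and can be maintained
    incrementally instead of recomputing the centroid product each round.
    """
    M = X != 0
    n = M.shape[0]
    colcounts = M.sum(axis=0)
    support = colcounts > 0
    scores = (M & support).sum(axis=1).astype(float)
    remaining = np.ones(n, dtype=bool)
    for _ in range(n):
        masked = np.where(remaining, scores, -1.0)
        pick = int(np.argmax(masked))  # ties -> lowest original index
        yield pick
        remaining[pick] = False
        colcounts = colcounts - M[pick]
        dead = (colcounts == 0) & support
        if dead.any():
            support = support & ~dead
            scores = scores - M[:, dead].sum(axis=1)


def select_prototypes(X, d: int) -> list[int]:
    """PVP prototype selection: iteratively pick the remaining row with the
    highest centroid-overlap score, remove it, recompute, d times."""
    A = _as_array(X)
    n = A.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"d must be in 1..{n}, got {d}")
    if A.size and A.min() < 0:
        raise ValueError("PVP requires non-negative input")
    it = _iter_prototypes(A)
    return [next(it) for _ in range(d)]


def _gs_append(basis: list[np.ndarray], v: np.ndarray, tol: float) -> np.ndarray | None:
    """Orthonormalize v against basis (with one re-orthogonalization pass for
    numerical stability); None if the residual norm is below tol."""
    w = v.astype(float).copy()
    if basis:
        Q = basis[0] if len(basis) == 1 else np.vstack(basis)
        Q = np.atleast_2d(Q)
        for _ in range(2):
            w -= Q.T @ (Q @ w)
    nrm = np.linalg.norm(w)
    if nrm < tol:
        return None
    return w / nrm


def orthonormalize(
    prototypes: Sequence[np.ndarray] | np.ndarray, tol: float = DEPENDENCE_TOL
) -> np.ndarray:
    """Gram-Schmidt orthonormalization in the given order.

    Raises :class:`LinearDependenceError` (carrying the offending position)
    when a vector's residual against the earlier ones has norm below ``tol``;
    the caller is expected to extend the selection with the next-best
    prototype.
    """
    vecs = [np.asarray(v, dtype=float).ravel() for v in prototypes]
    basis: list[np.ndarray] = []
    for i, v in enumerate(vecs):
        q = _gs_append(basis, v, tol)
        if q is None:
            raise LinearDependenceError(i)
        basis.append(q)
    return np.array(basis)


def pvp_fit(X, d: int, tol: float = DEPENDENCE_TOL) -> PrototypeBasis:
    """Run prototype selection plus orthonormalization, skipping prototypes
    that are linearly dependent on earlier ones by continuing the selection
    loop until ``d`` independent prototypes are found."""
    A = _as_array(X)
    n, m = A.shape
    if not 1 <= d <= n:
        raise ValueError(f"d must be in 1..{n}, got {d}")
    if A.size and A.min() < 0:
        raise ValueError("PVP requires non-negative input")
    basis: list[np.ndarray] = []
    accepted: list[int] = []
    n_skipped = 0
    for idx in _iter_prototypes(A):
        q = _gs_append(basis, A[idx], tol)
        if q is None:
            n_skipped += 1
            continue
        basis.append(q)
        accepted.append(idx)
        if len(accepted) == d:
            break
    if len(accepted) < d:
        raise ValueError(
            f"input has numerical rank {len(accepted)} < requested d={d}"
        )
    if n_skipped:
        warnings.warn(
            f"{n_skipped} dependent prototypes replaced by next-best vectors"
        )
    return PrototypeBasis(
        selected_prototypes=A[accepted],
        orthonormal_basis=np.array(basis),
        indices=tuple(accepted),
        source_dim=m,
        target_dim=d,
    )


def pvp_project(
    X, basis: PrototypeBasis, raw_prototypes: bool = False
) -> ProjectedMatrix:
    """Project rows of X by inner products with the basis vectors (or with
    the raw prototypes when ``raw_prototypes`` — keeping non-negative inputs
    non-negative)."""
    A = _as_array(X)
    if A.shape[1] != basis.source_dim:
        raise ValueError(
            f"dimension mismatch: X has {A.shape[1]} columns, basis expects "
            f"{basis.source_dim}"
        )
    P = basis.selected_prototypes if raw_prototypes else basis.orthonormal_basis
    return ProjectedMatrix(values=A @ P.T, method="pvp", d=basis.target_dim)


def l2_select_prototypes(X, d: int) -> list[int]:
    """Baseline selection: the d rows with the largest L2 norms, descending,
    ties broken toward the lowest index."""
    A = _as_array(X)
    n = A.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"d must be in 1..{n}, got {d}")
    norms = np.linalg.norm(A, axis=1)
    order = np.argsort(-norms, kind="stable")
    return [int(i) for i in order[:d]]


def l2_fit(X, d: int, tol: float = DEPENDENCE_TOL) -> PrototypeBasis:
    """Orthonormalized basis from the L2-norm prototype ranking (dependent
    vectors replaced by the next-ranked ones)."""
    A = _as_array(X)
    norms = np.linalg.norm(A, axis=1)
    ranking = np.argsort(-norms, kind="stable")
    basis: list[np.ndarray] = []
    accepted: list[int] = []
    for idx in ranking:
        q = _gs_append(basis, A[idx], tol)
        if q is None:
            continue
        basis.append(q)
        accepted.append(int(idx))
        if len(accepted) == d:
            break
    if len(accepted) < d:
        raise ValueError(f"input has numerical rank {len(accepted)} < d={d}")
    return PrototypeBasis(
        selected_prototypes=A[accepted],
        orthonormal_basis=np.array(basis),
        indices=tuple(accepted),
        source_dim=A.shape[1],
        target_dim=d,
    )


def svd_project_nonneg(X, d: int) -> ProjectedMatrix:
    """Rank-d truncated SVD scores U_d D_d with negative entries zeroed."""
    A = _as_array(X)
    n, m = A.shape
    if d > min(n, m):
        raise ValueError(f"d={d} exceeds min(n, m)={min(n, m)}")
    U, S, _ = np.linalg.svd(A, full_matrices=False)
    Z = U[:, :d] * S[:d]
    Z[Z < 0] = 0.0
    return ProjectedMatrix(values=Z, method="svd", d=d)


def nmf_project(
    X, d: int, seed: int = 0, max_iter: int = 500, tol: float = 1e-4
) -> ProjectedMatrix:
    """Rows of the W factor of a non-negative matrix factorization X ≈ WH.

    Uses the multiplicative-update solver with a dense random non-negative
    initialization; multiplicative updates keep every iterate strictly
    positive, so the returned coordinates are non-negative by construction.
    Deterministic given ``seed``.
    """
    from sklearn.decomposition import NMF
    from sklearn.exceptions import ConvergenceWarning

    A = _as_array(X)
    if A.size and A.min() < 0:
        raise ValueError("NMF requires non-negative input")
    model = NMF(
        n_components=d,
        solver="mu",
        init="random",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("default", category=ConvergenceWarning)
        W = model.fit_transform(A)
    return ProjectedMatrix(values=W, method="nmf", d=d)


def reduce_matrix(
    X,
    method: str,
    d: int,
    seed: int = 0,
    raw_prototypes: bool = False,
    nmf_max_iter: int = 500,
) -> ProjectedMatrix:
    """Uniform front door for the four reduction methods."""
    if method == "pvp":
        basis = pvp_fit(X, d)
        return pvp_project(X, basis, raw_prototypes=raw_prototypes)
    if method == "l2":
        basis = l2_fit(X, d)
        proj = pvp_project(X, basis, raw_prototypes=raw_prototypes)
        return ProjectedMatrix(values=proj.values, method="l2", d=d)
    if method == "svd":
        return svd_project_nonneg(X, d)
    if method == "nmf":
        return nmf_project(X, d, seed=seed, max_iter=nmf_max_iter)
    raise ValueError(f"unknown method {method!r}")
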