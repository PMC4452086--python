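"""Cross-lingual mapping via two-block NIPALS partial least squares
regression.

Given row-aligned blocks X (reduced source-language vectors) and Y (reduced
target-language vectors of their translations), PLSR extracts r pairs of
score vectors (λ_l, γ_l) with maximal covariance by alternating power-style
iterations, deflates both blocks and assembles the mapping matrix

    M = V (P'V)^{-1} C Q',

a d_source x d_target linear operator. A reduced source vector w is mapped
into the target space as the row-vector product w @ M. With r equal to the
full rank of X the fit coincides with the ordinary least-squares solution;
smaller r acts as regularization, which is what makes PLSR usable when the
seed bilingual lexicon is small relative to the dimensionality.

The inner coefficient defaults to the standard regression form
c_l = λ'γ / (λ'λ); a sign-only variant (c_l = λ'γ / |λ'γ|) is available via
``inner="sign"`` for auditability but cannot reproduce magnitudes in the
Y-deflation. No mean-centering is applied by default (the feature vectors
are non-negative by construction); pass ``center=True`` to fit on centered
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainingBlock", "PlsrMap", "fit_plsr", "apply_map"]


@dataclass
class TrainingBlock:
    """Row-aligned source/target blocks: row i of X and of Y are the reduced
    vectors of the i-th seed translation pair."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 training pairs")


@dataclass
class PlsrMap:
    """Fitted cross-lingual mapping."""

    rank: int
    V: np.ndarray  # d_s x r source weights (unit columns)
    P: np.ndarray  # d_s x r source loadings
    Q: np.ndarray  # d_t x r target loadings (unit columns)
    C: np.ndarray  # r inner coefficients
    M: np.ndarray  # d_s x d_t assembled mapping
    Lambda: np.ndarray  # n x r source scores (diagnostics)
    Gamma: np.ndarray  # n x r target scores (diagnostics)
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None

    @property
    def source_dim(self) -> int:
        return self.M.shape[0]

    @property
    def target_dim(self) -> int:
        return self.M.shape[1]


def fit_plsr(
    block: TrainingBlock,
    r: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    inner: str = "regression",
    init: str = "max_norm_column",
    center: bool = False,
    seed: int = 0,
) -> PlsrMap:
    """Fit the two-block NIPALS PLSR mapping with ``r`` components.

    Components whose intermediate vectors degenerate to zero norm stop the
    extraction early (the map is returned with fewer components and a
    warning). Non-convergent power iterations use the last iterate, with a
    warning.
    """
    X = block.X.copy()
    Y = block.Y.copy()
    n, d_s = X.shape
    d_t = Y.shape[1]
    if not 1 <= r <= min(d_s, n):
        raise ValueError(f"r must be in 1..min(d_s, n)={min(d_s, n)}")
    if inner not in ("regression", "sign"):
        raise ValueError("inner must be 'regression' or 'sign'")
    if init not in ("max_norm_column", "random"):
        raise ValueError("init must be 'max_norm_column' or 'random'")
    if tol <= 0:
        raise ValueError("tol must be positive")

    x_mean = y_mean = None
    if center:
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        X = X - x_mean
        Y = Y - y_mean

    rng = np.random.default_rng(seed)
    Vs, Ps, Qs, Cs, Ls, Gs = [], [], [], [], [], []
    eps = np.finfo(float).tiny

    for l in range(r):
        col_norms = np.linalg.norm(Y, axis=0)
        if col_norms.max() < 1e-12:
            warnings.warn(
                f"target block degenerate after {l} components; stopping early"
            )
            break
        if init == "max_norm_column":
            gamma = Y[:, int(np.argmax(col_norms))].copy()
        else:
            gamma = Y[:, int(rng.integers(Y.shape[1]))].copy()
            if np.linalg.norm(gamma) < 1e-12:  # resample a non-degenerate column
                gamma = Y[:, int(np.argmax(col_norms))].copy()

        lam = None
        q = None
        converged = False
        for _ in range(max_iter):
            v = X.T @ gamma
            v_norm = np.linalg.norm(v)
            if v_norm < eps:
                break
            v /= v_norm
            lam = X @ v
            q = Y.T @ lam
            q_norm = np.linalg.norm(q)
            if q_norm < eps:
                break
            q /= q_norm
            gamma_new = Y @ q
            if np.linalg.norm(gamma_new - gamma) <= tol * max(
                np.linalg.norm(gamma_new), 1e-300
            ):
                gamma = gamma_new
                converged = True
                break
            gamma = gamma_new
        if lam is None or q is None:
            warnings.warn(
                f"component {l + 1} degenerate; returning {l}-component map"
            )
            break
        if not converged:
            warnings.warn(f"component {l + 1} did not converge; using last iterate")

        lam_sq = lam @ lam
        if lam_sq < 1e-300:
            warnings.warn(
                f"component {l + 1} has zero score; returning {l}-component map"
            )
            break
        if inner == "regression":
            c = (lam @ gamma) / lam_sq
        else:
            denom = abs(lam @ gamma)
            c = (lam @ gamma) / denom if denom > 0 else 0.0
        p = X.T @ lam / lam_sq

        Vs.append(v)
        Ps.append(p)
        Qs.append(q)
        Cs.append(c)
        Ls.append(lam)
        Gs.append(gamma)

        X = X - np.outer(lam, p)
        Y = Y - c * np.outer(lam, q)

    if not Vs:
        # zero target block: the best linear map is identically zero
        M = np.zeros((d_s, d_t))
        return PlsrMap(
            rank=0,
            V=np.zeros((d_s, 0)),
            P=np.zeros((d_s, 0)),
            Q=np.zeros((d_t, 0)),
            C=np.zeros(0),
            M=M,
            Lambda=np.zeros((n, 0)),
            Gamma=np.zeros((n, 0)),
            x_mean=x_mean,
            y_mean=y_mean,
        )

    V = np.column_stack(Vs)
    P = np.column_stack(Ps)
    Q = np.column_stack(Qs)
    C = np.asarray(Cs)
    M = V @ np.linalg.solve(P.T @ V, C[:, None] * Q.T)
    return PlsrMap(
        rank=len(Cs),
        V=V,
        P=P,
        Q=Q,
        C=C,
        M=M,
        Lambda=np.column_stack(Ls),
        Gamma=np.column_stack(Gs),
        x_mean=x_mean,
        y_mean=y_mean,
    )


def apply_map(plsr_map: PlsrMap, w: np.ndarray) -> np.ndarray:
    """Map reduced source vector(s) into the target space: w @ M.

    Accepts a single vector (returns a vector) or an n x d_s matrix
    (returns n x d_t).
    """
    w = np.asarray(w, dtype=float)
    single = w.ndim == 1
    W = np.atleast_2d(w)
    if W.shape[1] != plsr_map.source_dim:
        raise ValueError(
            f"dimension mismatch: input has {W.shape[1]} columns, map expects "
            f"{plsr_map.source_dim}"
        )
    if plsr_map.x_mean is not None:
        out = (W - plsr_map.x_mean) @ plsr_map.M + plsr_map.y_mean
    else:
        out = W @ plsr_map.M
    return out[0] if single else out
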