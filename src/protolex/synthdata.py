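"""Synthetic inputs for exercising the pipeline without external data.

Two generators:

* :func:`gen_sparse_vectors` — the sparse non-negative vectors used to
  benchmark dimensionality reductions: elements drawn uniformly on [0, 1)
  and independently zeroed with probability 0.98, giving vectors that are
  98% zeros on average (the sparsity regime of character-n-gram and
  contextual term vectors).
* :func:`gen_planted_bilingual` — a stand-in for a real bilingual lexicon:
  a sparse non-negative source matrix, a planted sparse non-negative linear
  map B, and target vectors X_T = max(0, X_S B + noise), aligned row by
  row, optionally with distractor target rows (images of extra source
  vectors that have no paired source term in the lexicon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import FeatureMatrix, PairList

__all__ = [
    "SparseSynthConfig",
    "PlantedBilingual",
    "gen_sparse_vectors",
    "gen_planted_bilingual",
]


@dataclass(frozen=True)
class SparseSynthConfig:
    """Sparse synthetic vector settings (defaults follow the benchmark
    protocol: 1000 vectors, 1000 dims, 98% zeros)."""

    n_vectors: int = 1000
    dim: int = 1000
    zero_probability: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.zero_probability < 1):
            raise ValueError("zero_probability must be in [0, 1)")
        if self.n_vectors < 1 or self.dim < 1:
            raise ValueError("n_vectors and dim must be >= 1")


def gen_sparse_vectors(cfg: SparseSynthConfig = SparseSynthConfig()) -> FeatureMatrix:
    """Uniform [0, 1) values, independently zeroed with
    ``cfg.zero_probability``; bit-identical under the same seed."""
    rng = np.random.default_rng(cfg.seed)
    values = rng.random((cfg.n_vectors, cfg.dim))
    mask = rng.random((cfg.n_vectors, cfg.dim)) < cfg.zero_probability
    values[mask] = 0.0
    return FeatureMatrix(
        values=sp.csr_matrix(values),
        vocabulary=tuple(f"f{j:05d}" for j in range(cfg.dim)),
        row_terms=tuple(f"v{i:05d}" for i in range(cfg.n_vectors)),
        language="synthetic",
        feature_kind="other",
    )


@dataclass
class PlantedBilingual:
    """Planted-map bilingual data: row i of X_S translates to row i of X_T.

    ``X_T`` has ``n + n_distractors`` rows; the trailing distractor rows are
    images of extra source vectors whose sources are withheld, so they are
    plausible but incorrect candidates.
    """

    X_S: np.ndarray
    B: np.ndarray
    X_T: np.ndarray
    sigma: float
    pairs: PairList
    source_terms: tuple[str, ...]
    target_terms: tuple[str, ...]
    n_distractors: int = 0


def gen_planted_bilingual(
    n: int,
    d_s: int,
    d_t: int,
    sparsity: float = 0.9,
    sigma: float = 0.05,
    seed: int = 0,
    n_distractors: int = 0,
) -> PlantedBilingual:
    """Generate aligned source/target matrices linked by a planted sparse
    non-negative linear map.

    ``sparsity`` is the zero probability for both the source vectors and the
    planted map B; ``sigma`` the Gaussian noise level on the target side
    (clipped at zero so all outputs stay non-negative).
    """
    if min(n, d_s, d_t) < 1:
        raise ValueError("n, d_s, d_t must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_total = n + n_distractors

    src_cfg = SparseSynthConfig(
        n_vectors=n_total, dim=d_s, zero_probability=sparsity, seed=seed
    )
    X_all = gen_sparse_vectors(src_cfg).toarray()

    B = rng.random((d_s, d_t))
    B[rng.random((d_s, d_t)) < sparsity] = 0.0

    noise = rng.normal(0.0, sigma, size=(n_total, d_t)) if sigma > 0 else 0.0
    X_T = np.maximum(0.0, X_all @ B + noise)

    source_terms = tuple(f"src{i:05d}" for i in range(n))
    target_terms = tuple(f"tgt{i:05d}" for i in range(n_total))
    pairs = PairList(pairs=tuple(zip(source_terms, target_terms[:n])))
    return PlantedBilingual(
        X_S=X_all[:n],
        B=B,
        X_T=X_T,
        sigma=sigma,
        pairs=pairs,
        source_terms=source_terms,
        target_terms=target_terms,
        n_distractors=n_distractors,
    )
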