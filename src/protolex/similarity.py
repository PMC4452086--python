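"""Classifier-based cross-lingual similarity.

A candidate translation pair (w_S, w_T) is represented by concatenating
three blocks: the reduced source vector, the reduced target vector, and the
source vector mapped into the target space by the fitted PLSR map —
[w_S; w_T; map(w_S)]. A random-forest binary classifier is trained on seed
translation pairs (positives) against an equal number of randomly paired
terms (negatives); its positive-class probability is the cross-lingual
similarity score, and target candidates are ranked by it in descending
order. A forest is used rather than a linear model because detecting a
translation requires feature *interactions* — agreement between the target
block and the mapped-source block — which axis-aligned tree splits can
capture but a linear scorer cannot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import PairList, TermLexicon
from .xmap import PlsrMap, apply_map

__all__ = [
    "PairVector",
    "SimilarityModel",
    "RankedCandidates",
    "make_pair_vector",
    "sample_negative_pairs",
    "train_similarity_model",
    "score_pair",
    "rank_candidates",
]


@dataclass(frozen=True)
class PairVector:
    """[source; target; mapped-source] concatenation with an optional label."""

    values: np.ndarray
    label: str = "unlabeled"  # positive | negative | unlabeled

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class RankedCandidates:
    """Translation candidates for one source term, best first."""

    source_term: str
    ranking: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranking]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")

    def terms(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.ranking)


def make_pair_vector(
    ws: np.ndarray, wt: np.ndarray, plsr_map: PlsrMap, label: str = "unlabeled"
) -> PairVector:
    """Build [ws; wt; map(ws)] for one candidate pair."""
    ws = np.asarray(ws, dtype=float).ravel()
    wt = np.asarray(wt, dtype=float).ravel()
    if ws.size != plsr_map.source_dim or wt.size != plsr_map.target_dim:
        raise ValueError(
            f"dimension mismatch: got ({ws.size}, {wt.size}), map expects "
            f"({plsr_map.source_dim}, {plsr_map.target_dim})"
        )
    return PairVector(
        values=np.concatenate([ws, wt, apply_map(plsr_map, ws)]), label=label
    )


def sample_negative_pairs(
    positives: PairList,
    source_lexicon: TermLexicon,
    target_lexicon: TermLexicon,
    seed: int = 0,
) -> PairList:
    """Randomly pair source and target terms into ``len(positives)`` negative
    pairs, rejecting any pair that is a known positive (or already sampled)."""
    pos = set(positives.pairs)
    n_needed = len(positives)
    n_possible = len(source_lexicon) * len(target_lexicon) - len(pos)
    if n_possible < n_needed:
        raise ValueError(
            f"only {n_possible} non-positive pairs exist; need {n_needed}"
        )
    rng = np.random.default_rng(seed)
    src = source_lexicon.terms
    tgt = target_lexicon.terms
    out: dict[tuple[str, str], None] = {}
    attempts = 0
    limit = 1000 * max(n_needed, 1)
    while len(out) < n_needed:
        pair = (src[rng.integers(len(src))], tgt[rng.integers(len(tgt))])
        attempts += 1
        if attempts > limit:
            raise ValueError("rejection sampling failed to find enough negatives")
        if pair in pos or pair in out:
            continue
        out[pair] = None
    return PairList(pairs=tuple(out))


def _lookup(vectors: Mapping[str, np.ndarray], term: str) -> np.ndarray:
    try:
        return vectors[term]
    except KeyError:
        raise KeyError(f"no vector for term {term!r}") from None


def _pair_matrix(
    pairs: Sequence[tuple[str, str]],
    source_vectors: Mapping[str, np.ndarray],
    target_vectors: Mapping[str, np.ndarray],
    plsr_map: PlsrMap,
) -> np.ndarray:
    S = np.array([_lookup(source_vectors, s) for s, _ in pairs], dtype=float)
    T = np.array([_lookup(target_vectors, t) for _, t in pairs], dtype=float)
    return np.hstack([S, T, apply_map(plsr_map, S)])


@dataclass
class SimilarityModel:
    """Trained random-forest pair classifier plus the map it was built on."""

    forest: object
    plsr_map: PlsrMap
    n_trees: int
    seed: int

    @property
    def pair_dim(self) -> int:
        return self.plsr_map.source_dim + 2 * self.plsr_map.target_dim

    def score_vectors(self, pair_vectors: np.ndarray) -> np.ndarray:
        """Positive-class probability for each row of pair vectors."""
        from sklearn.exceptions import NotFittedError
        from sklearn.utils.validation import check_is_fitted

        try:
            check_is_fitted(self.forest)
        except NotFittedError as exc:
            raise RuntimeError("similarity model is not fitted") from exc
        proba = self.forest.predict_proba(np.atleast_2d(pair_vectors))
        pos_col = list(self.forest.classes_).index(1)
        return proba[:, pos_col]


def train_similarity_model(
    positives: PairList,
    negatives: PairList,
    source_vectors: Mapping[str, np.ndarray],
    target_vectors: Mapping[str, np.ndarray],
    plsr_map: PlsrMap,
    n_trees: int = 150,
    seed: int = 0,
) -> SimilarityModel:
    """Train the forest on positive vs negative pair vectors."""
    from sklearn.ensemble import RandomForestClassifier

    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both positive and negative pairs are required")
    Xpos = _pair_matrix(positives.pairs, source_vectors, target_vectors, plsr_map)
    Xneg = _pair_matrix(negatives.pairs, source_vectors, target_vectors, plsr_map)
    X = np.vstack([Xpos, Xneg])
    y = np.concatenate([np.ones(len(Xpos), int), np.zeros(len(Xneg), int)])
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return SimilarityModel(forest=forest, plsr_map=plsr_map, n_trees=n_trees, seed=seed)


def score_pair(model: SimilarityModel, ws: np.ndarray, wt: np.ndarray) -> float:
    """Cross-lingual similarity of one (source, target) vector pair in [0, 1]."""
    pv = make_pair_vector(ws, wt, model.plsr_map)
    return float(model.score_vectors(pv.values[None, :])[0])


def rank_candidates(
    model: SimilarityModel,
    source_term: str,
    ws: np.ndarray,
    target_vectors: Mapping[str, np.ndarray],
    k: int | None = None,
) -> RankedCandidates:
    """Score every candidate target term against ``ws`` and return the top-k
    by descending similarity (ties broken by lexicographic target term)."""
    if not target_vectors:
        raise ValueError("empty target candidate set")
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    terms = sorted(target_vectors)  # lexicographic order makes ties deterministic
    ws = np.asarray(ws, dtype=float).ravel()
    S = np.tile(ws, (len(terms), 1))
    T = np.array([target_vectors[t] for t in terms], dtype=float)
    pair_vecs = np.hstack([S, T, apply_map(model.plsr_map, S)])
    scores = model.score_vectors(pair_vecs)
    order = np.argsort(-scores, kind="stable")
    if k is not None:
        order = order[:k]
    ranking = tuple((terms[i], float(scores[i])) for i in order)
    return RankedCandidates(source_term=source_term, ranking=ranking)
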