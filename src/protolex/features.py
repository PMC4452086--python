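"""Monolingual feature vector construction.

Terms are represented by two mutually exclusive feature families:

* **intrinsic** — binary character n-grams (n = 2..5 by default) extracted
  from the term string itself;
* **extrinsic** — contextual unigrams and bigrams drawn from a small token
  window around each corpus occurrence of the term, weighted by positive
  pointwise mutual information (PPMI).

Feature vocabularies are capped at ``vocab_size`` features, ranked by the
number of distinct lexicon terms a feature is extracted from (ties broken
lexicographically so that runs are reproducible).
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import Corpus, FeatureMatrix, TermLexicon

logger = logging.getLogger(__name__)

__all__ = [
    "NgramConfig",
    "ContextConfig",
    "ContextCounts",
    "extract_char_ngrams",
    "build_ngram_matrix",
    "extract_context_counts",
    "ppmi_weight",
]


@dataclass(frozen=True)
class NgramConfig:
    """Character n-gram extraction settings (lengths ``n_min``..``n_max``)."""

    n_min: int = 2
    n_max: int = 5
    vocab_size: int = 10_000

    def __post_init__(self) -> None:
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("require 1 <= n_min <= n_max")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")


@dataclass(frozen=True)
class ContextConfig:
    """Contextual feature settings: a window of ``window_before`` tokens
    preceding and ``window_after`` tokens succeeding each term occurrence."""

    window_before: int = 2
    window_after: int = 2
    vocab_size: int = 10_000
    log_base: str = "natural"  # "natural" or "base2"

    def __post_init__(self) -> None:
        if self.window_before < 0 or self.window_after < 0:
            raise ValueError("windows must be >= 0")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        if self.log_base not in ("natural", "base2"):
            raise ValueError("log_base must be 'natural' or 'base2'")


def extract_char_ngrams(term: str, cfg: NgramConfig = NgramConfig()) -> set[str]:
    """All contiguous character substrings of ``term`` with lengths in
    ``cfg.n_min..cfg.n_max`` (binary presence — a set).

    The term is case-folded first. Internal spaces of multi-word terms are
    kept as ordinary characters, preserving word-boundary signal. No boundary
    padding is added.
    """
    if not term:
        raise ValueError("empty term")
    term = term.casefold()
    grams: set[str] = set()
    for n in range(cfg.n_min, cfg.n_max + 1):
        for i in range(len(term) - n + 1):
            grams.add(term[i : i + n])
    return grams


def build_ngram_matrix(
    lexicon: TermLexicon, cfg: NgramConfig = NgramConfig()
) -> FeatureMatrix:
    """Binary term x n-gram matrix over the top-``vocab_size`` n-grams.

    The vocabulary keeps the n-grams contained in the largest number of
    lexicon terms (term-level presence, not occurrence counts), ties broken
    lexicographically.
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    per_term = [extract_char_ngrams(t, cfg) for t in lexicon.terms]
    df = Counter()
    for grams in per_term:
        df.update(grams)
    vocab = sorted(df, key=lambda g: (-df[g], g))[: cfg.vocab_size]
    col = {g: j for j, g in enumerate(vocab)}
    rows, cols = [], []
    for i, grams in enumerate(per_term):
        for g in grams:
            j = col.get(g)
            if j is not None:
                rows.append(i)
                cols.append(j)
    values = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(lexicon), len(vocab))
    )
    return FeatureMatrix(
        values=values,
        vocabulary=tuple(vocab),
        row_terms=lexicon.terms,
        language=lexicon.language,
        feature_kind="ngram",
    )


@dataclass
class ContextCounts:
    """Co-occurrence context counts backing the PPMI estimates.

    A *context* is one occurrence of a lexicon term in the corpus. The
    stored counts estimate p(c) (contexts in which feature c appears),
    p(w) (contexts of term w, i.e. its occurrence count) and p(c, w)
    (occurrences of w whose window contains c), all relative to
    ``total_contexts``.
    """

    terms: tuple[str, ...]
    vocabulary: tuple[str, ...]
    total_contexts: int
    feature_context_counts: dict[str, int]
    term_context_counts: dict[str, int]
    joint_counts: dict[str, dict[str, int]]  # term -> feature -> count
    language: str = ""

    def validate(self) -> None:
        for c, fc in self.feature_context_counts.items():
            if fc < 0 or fc > self.total_contexts:
                raise ValueError(f"feature count out of range for {c!r}")
        for w, d in self.joint_counts.items():
            for c, jc in d.items():
                if jc > self.feature_context_counts.get(c, 0):
                    raise ValueError("joint count exceeds feature marginal")
                if jc > self.term_context_counts.get(w, 0):
                    raise ValueError("joint count exceeds term marginal")


def _window_features(
    doc: tuple[str, ...], start: int, stop: int, cfg: ContextConfig
) -> set[str]:
    """Context features of one term occurrence ``doc[start:stop]``:
    window unigrams plus bigrams lying wholly inside one side's window."""
    before = doc[max(0, start - cfg.window_before) : start]
    after = doc[stop : stop + cfg.window_after]
    feats: set[str] = set(before) | set(after)
    for side in (before, after):
        for i in range(len(side) - 1):
            feats.add(side[i] + " " + side[i + 1])
    return feats


def extract_context_counts(
    corpus: Corpus,
    lexicon: TermLexicon,
    cfg: ContextConfig = ContextConfig(),
) -> ContextCounts:
    """Collect context counts for every occurrence of every lexicon term.

    Terms are matched as exact (case-folded) token sequences; a multi-token
    term's window surrounds the whole sequence. Bigrams never span across
    the term itself. Candidate features are ranked by the number of distinct
    lexicon terms they co-occur with and cut to ``cfg.vocab_size`` (ties
    lexicographic).
    """
    term_tokens = {t: tuple(t.casefold().split()) for t in lexicon.terms}
    # index: first token -> terms starting with it
    by_first: dict[str, list[str]] = defaultdict(list)
    for t, toks in term_tokens.items():
        by_first[toks[0]].append(t)

    total = 0
    feat_counts: Counter = Counter()
    term_counts: Counter = Counter()
    joint: dict[str, Counter] = defaultdict(Counter)

    for doc in corpus.documents:
        folded = tuple(tok.casefold() for tok in doc)
        for i, tok in enumerate(folded):
            for term in by_first.get(tok, ()):
                toks = term_tokens[term]
                if folded[i : i + len(toks)] != toks:
                    continue
                feats = _window_features(folded, i, i + len(toks), cfg)
                total += 1
                term_counts[term] += 1
                feat_counts.update(feats)
                joint[term].update(feats)

    missing = [t for t in lexicon.terms if term_counts[t] == 0]
    if missing:
        logger.warning(
            "%d lexicon terms never occur in the corpus (e.g. %r)",
            len(missing),
            missing[0],
        )

    # distinct-term document frequency per feature, for vocabulary selection
    feat_df: Counter = Counter()
    for term, fc in joint.items():
        feat_df.update(fc.keys())
    vocab = sorted(feat_df, key=lambda c: (-feat_df[c], c))[: cfg.vocab_size]

    counts = ContextCounts(
        terms=lexicon.terms,
        vocabulary=tuple(vocab),
        total_contexts=total,
        feature_context_counts=dict(feat_counts),
        term_context_counts=dict(term_counts),
        joint_counts={t: dict(c) for t, c in joint.items()},
        language=lexicon.language,
    )
    return counts


def ppmi_weight(counts: ContextCounts, log_base: str = "natural") -> FeatureMatrix:
    """PPMI-weighted term x context-feature matrix.

    PPMI(c, w) = max(0, log p(c,w) / (p(c) p(w))), with probabilities
    estimated as context-count ratios. Zero joint counts give weight 0.
    The log base only rescales the matrix.
    """
    if counts.total_contexts <= 0:
        raise ValueError("no contexts observed; cannot estimate probabilities")
    log = math.log if log_base == "natural" else math.log2
    total = counts.total_contexts
    col = {c: j for j, c in enumerate(counts.vocabulary)}
    rows, cols, data = [], [], []
    for i, term in enumerate(counts.terms):
        tw = counts.term_context_counts.get(term, 0)
        if tw == 0:
            continue
        for c, jc in counts.joint_counts.get(term, {}).items():
            j = col.get(c)
            if j is None or jc == 0:
                continue
            fc = counts.feature_context_counts[c]
            val = log(jc * total / (fc * tw))
            if val > 0:
                rows.append(i)
                cols.append(j)
                data.append(val)
    values = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(counts.terms), len(counts.vocabulary))
    )
    return FeatureMatrix(
        values=values,
        vocabulary=counts.vocabulary,
        row_terms=counts.terms,
        language=counts.language,
        feature_kind="context",
    )
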