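"""Reading and writing of term lexicons, bilingual pair lists, corpora and
feature matrices.

All text formats are plain UTF-8:

* term lexicon — one term per line;
* bilingual pairs — two tab-separated columns, no header;
* corpus — one document (or sentence) per line, whitespace-tokenized;
* feature matrix — Matrix Market coordinate file plus a ``<name>.vocab.txt``
  sidecar listing one feature name per line, and a ``<name>.terms.txt``
  sidecar listing the row terms.

Terms are NFC-normalized on input so that the same Greek or Japanese string
compares equal regardless of how the source file encoded its combining
characters.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "TermLexicon",
    "PairList",
    "Corpus",
    "FeatureMatrix",
    "read_term_list",
    "write_term_list",
    "read_pair_tsv",
    "write_pair_tsv",
    "read_corpus",
    "read_matrix",
    "write_matrix",
]


def _normalize_term(raw: str) -> str:
    return unicodedata.normalize("NFC", raw.strip())


@dataclass(frozen=True)
class TermLexicon:
    """Ordered list of unique terms for one language."""

    language: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(not t for t in self.terms):
            raise ValueError("lexicon contains an empty term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("lexicon contains duplicate terms")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


@dataclass(frozen=True)
class PairList:
    """Seed bilingual lexicon: unique (source term, target term) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for s, t in self.pairs:
            if not s or not t:
                raise ValueError(f"empty term in pair ({s!r}, {t!r})")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def source_terms(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.pairs)

    @property
    def target_terms(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.pairs)


@dataclass(frozen=True)
class Corpus:
    """A tokenized monolingual corpus; one token sequence per document."""

    documents: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


@dataclass
class FeatureMatrix:
    """n terms x m features, non-negative, with a named feature vocabulary.

    ``feature_kind`` is ``"ngram"`` for binary character n-gram features or
    ``"context"`` for PPMI-weighted contextual features (``"other"`` for
    anything else, e.g. synthetic data).
    """

    values: sp.csr_matrix
    vocabulary: tuple[str, ...]
    row_terms: tuple[str, ...]
    language: str = ""
    feature_kind: str = "other"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.vocabulary = tuple(self.vocabulary)
        self.row_terms = tuple(self.row_terms)
        n, m = self.values.shape
        if len(self.vocabulary) != m:
            raise ValueError(
                f"vocabulary length {len(self.vocabulary)} != column count {m}"
            )
        if len(self.row_terms) != n:
            raise ValueError(
                f"row_terms length {len(self.row_terms)} != row count {n}"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary names must be unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("feature values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


def read_term_list(path: str | Path, language: str) -> TermLexicon:
    """Read a one-term-per-line UTF-8 lexicon.

    Surrounding whitespace is stripped, blank lines are skipped and duplicate
    terms (after NFC normalization) are dropped keeping the first occurrence,
    with a logged warning.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    n_dup = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            term = _normalize_term(line)
            if not term:
                continue
            if term in seen:
                n_dup += 1
                continue
            seen[term] = None
    if n_dup:
        logger.warning("%s: dropped %d duplicate terms", path, n_dup)
    if not seen:
        raise ValueError(f"{path}: no terms after filtering")
    return TermLexicon(language=language, terms=tuple(seen))


def write_term_list(lexicon: TermLexicon, path: str | Path) -> None:
    Path(path).write_text(
        "".join(t + "\n" for t in lexicon.terms), encoding="utf-8"
    )


def read_pair_tsv(path: str | Path) -> PairList:
    """Read a two-column TSV of (source term, target term) pairs.

    Raises ``ValueError`` naming the line number for a malformed line.
    Duplicate pairs are dropped with a warning.
    """
    path = Path(path)
    seen: dict[tuple[str, str], None] = {}
    n_dup = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            pair = (_normalize_term(cols[0]), _normalize_term(cols[1]))
            if not pair[0] or not pair[1]:
                raise ValueError(f"{path}:{lineno}: empty term in pair")
            if pair in seen:
                n_dup += 1
                continue
            seen[pair] = None
    if n_dup:
        logger.warning("%s: dropped %d duplicate pairs", path, n_dup)
    return PairList(pairs=tuple(seen))


def write_pair_tsv(pairs: PairList, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{t}\n" for s, t in pairs.pairs), encoding="utf-8"
    )


def read_corpus(path: str | Path) -> Corpus:
    """Read a plain-text corpus, one document per line, split on whitespace."""
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            tokens = unicodedata.normalize("NFC", line).split()
            if tokens:
                docs.append(tuple(tokens))
    return Corpus(documents=tuple(docs))


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    return (
        stem.with_name(stem.name + ".vocab.txt"),
        stem.with_name(stem.name + ".terms.txt"),
    )


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Serialize a feature matrix as Matrix Market + vocabulary/terms sidecars."""
    path = Path(path)
    if path.suffix != ".mtx":
        path = path.with_suffix(".mtx")
    mmwrite(str(path), sp.coo_matrix(matrix.values))
    vocab_path, terms_path = _sidecar_paths(path)
    vocab_path.write_text(
        "".join(v + "\n" for v in matrix.vocabulary), encoding="utf-8"
    )
    terms_path.write_text(
        "".join(t + "\n" for t in matrix.row_terms), encoding="utf-8"
    )


def _read_lines(path: Path) -> tuple[str, ...]:
    return tuple(
        line.rstrip("\n")
        for line in path.read_text(encoding="utf-8").splitlines()
    )


def read_matrix(
    path: str | Path, language: str = "", feature_kind: str = "other"
) -> FeatureMatrix:
    path = Path(path)
    if path.suffix != ".mtx":
        path = path.with_suffix(".mtx")
    values = sp.csr_matrix(mmread(str(path)))
    vocab_path, terms_path = _sidecar_paths(path)
    vocabulary = _read_lines(vocab_path)
    row_terms = _read_lines(terms_path) if terms_path.exists() else tuple(
        str(i) for i in range(values.shape[0])
    )
    return FeatureMatrix(
        values=values,
        vocabulary=vocabulary,
        row_terms=row_terms,
        language=language,
        feature_kind=feature_kind,
    )
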