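"""Per-document latent semantic analysis baseline.

Each document gets its own term-sentence matrix (log(1+count) weighting by
default), decomposed by truncated SVD into a 12-dimensional latent space.
A word's vector is its row of the left singular matrix scaled by the
singular values and normalized to unit length, so the scalar product of
two word vectors is a cosine in [-1, 1]. The similarity of the two query
words in this space is the classical vector-semantics baseline against
which the entanglement measure is compared.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .corpus import SentenceCorpus

__all__ = [
    "DegenerateCorpusError",
    "MissingTermError",
    "TermMatrix",
    "LsaEmbedding",
    "build_term_matrix",
    "lsa_embed",
    "lsa_similarity",
]

_RANK_TOL = 1e-10


class DegenerateCorpusError(ValueError):
    """Corpus too small to carry a latent space (needs >=2 sentences, >=2 terms)."""


class MissingTermError(KeyError):
    """A query word does not occur in the embedded document."""


@dataclass(frozen=True)
class TermMatrix:
    """Weighted term-by-sentence matrix; rows follow first-occurrence order."""

    terms: tuple[str, ...]
    weights: np.ndarray  # shape (n_terms, n_units), non-negative

    def __post_init__(self) -> None:
        if self.weights.shape[0] != len(self.terms):
            raise ValueError("row count must match vocabulary size")
        if np.any(self.weights.sum(axis=1) == 0.0):
            raise ValueError("all-zero term rows are not allowed")


@dataclass(frozen=True)
class LsaEmbedding:
    """Unit-norm word vectors in a k-dimensional latent space."""

    dimension: int
    word_vectors: Mapping[str, np.ndarray]

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.word_vectors[term]
        except KeyError:
            raise MissingTermError(term) from None

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["term"] + [f"v{i+1}" for i in range(self.dimension)])
        for term, vec in self.word_vectors.items():
            writer.writerow([term] + [f"{v:.12g}" for v in vec])
        return buf.getvalue()


def build_term_matrix(corpus: SentenceCorpus, weighting: str = "log") -> TermMatrix:
    """Count term occurrences per sentence, optionally log-damped.

    ``log`` entries are log(1 + count), damping burstiness; ``raw`` keeps
    plain counts.
    """
    if weighting not in ("raw", "log"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    terms: list[str] = []
    index: dict[str, int] = {}
    for sentence in corpus:
        for tok in sentence.tokens:
            if tok not in index:
                index[tok] = len(terms)
                terms.append(tok)
    if corpus.n_units < 2 or len(terms) < 2:
        raise DegenerateCorpusError(
            "latent space needs at least 2 sentences and 2 distinct terms"
        )
    mat = np.zeros((len(terms), corpus.n_units), dtype=float)
    for j, sentence in enumerate(corpus):
        for tok in sentence.tokens:
            mat[index[tok], j] += 1.0
    if weighting == "log":
        mat = np.log1p(mat)
    return TermMatrix(terms=tuple(terms), weights=mat)


def lsa_embed(matrix: TermMatrix, k: int = 12) -> LsaEmbedding:
    """Truncated SVD embedding of the vocabulary.

    ``k`` is clipped to the matrix rank so the decomposition always
    exists; word vectors are singular-value-scaled rows of U, normalized
    to unit length.
    """
    if k < 1:
        raise ValueError("embedding dimension must be >= 1")
    u, s, _ = np.linalg.svd(matrix.weights, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise DegenerateCorpusError("matrix has rank 0")
    k_eff = min(k, rank)
    scaled = u[:, :k_eff] * s[:k_eff]
    vectors: dict[str, np.ndarray] = {}
    for i, term in enumerate(matrix.terms):
        row = scaled[i]
        norm = np.linalg.norm(row)
        if norm == 0.0:
            raise DegenerateCorpusError(f"term {term!r} has no projection in the latent space")
        vectors[term] = row / norm
    return LsaEmbedding(dimension=k_eff, word_vectors=vectors)


def lsa_similarity(embedding: LsaEmbedding, word_a: str, word_b: str) -> float:
    """Cosine of the two word vectors, clipped to [-1, 1]."""
    va = embedding.vector(word_a)
    vb = embedding.vector(word_b)
    return float(np.clip(va @ vb, -1.0, 1.0))
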