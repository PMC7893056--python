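"""Text-to-counts layer: segmentation, tokenization, neighbor sets, contingency counts.

A document is treated as a *bag of sentences*: each sentence (or paragraph,
depending on granularity) is an unordered multiset of normalized word types.
For a pair of concept words ``A`` and ``B`` we build the neighbor sets
``O_A`` and ``O_B`` — the words co-occurring with each concept within a
sentence — and classify every sentence into one of four activation classes

* ``00`` — the sentence touches neither ``O_A`` nor ``O_B``,
* ``01`` — only ``O_B``,
* ``10`` — only ``O_A``,
* ``11`` — both.

The four sentence counts ``N_ij`` (total ``N``) are the sole textual input
to the downstream quantum-state construction; word order within sentences
and sentence order within the document are irrelevant by design.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmptyInputError",
    "TokenizerConfig",
    "TokenizedSentence",
    "SentenceCorpus",
    "NeighborSet",
    "ContingencyCounts",
    "default_stopwords",
    "segment_text",
    "build_neighbor_set",
    "categorize_sentences",
    "shuffle_words",
]


class EmptyInputError(ValueError):
    """Raised when a document yields no non-empty text units."""


# Sentence terminators: run of . ! ? followed by whitespace or end of text.
_DEFAULT_DELIMITER = r"[.!?]+(?:\s+|$)"
_PARAGRAPH_DELIMITER = r"\n\s*\n"
# Word = maximal run of unicode letters; digits and punctuation are stripped.
_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def default_stopwords() -> frozenset[str]:
    """English function-word list packaged with the library.

    Applied when building neighbor sets: with function words inside ``O_w``
    nearly every sentence would activate both concepts and the contingency
    counts would degenerate.
    """
    text = resources.files("qsemantics").joinpath("data/stopwords.txt").read_text("utf-8")
    words: set[str] = set()
    for line in text.splitlines():
        if line.lstrip().startswith("#"):
            continue
        words.update(line.split())
    return frozenset(words)


@dataclass(frozen=True)
class TokenizerConfig:
    """Segmentation/normalization settings for turning raw text into units.

    Parameters
    ----------
    delimiter : str
        Regex that terminates a sentence unit. The default splits on runs
        of ``. ! ?`` followed by whitespace or end of input; no abbreviation
        heuristics are applied.
    granularity : {"sentence", "paragraph"}
        Text unit used as one perception trial. ``paragraph`` splits on
        blank lines instead of sentence punctuation.
    case_fold : bool
        Lower-case tokens before anything else.
    stopwords : frozenset of str or None
        Words excluded from neighbor sets. ``None`` selects the packaged
        English list; pass ``frozenset()`` to disable filtering.
    """

    delimiter: str = _DEFAULT_DELIMITER
    granularity: str = "sentence"
    case_fold: bool = True
    stopwords: frozenset[str] | None = None

    def resolved_stopwords(self) -> frozenset[str]:
        return default_stopwords() if self.stopwords is None else self.stopwords


@dataclass(frozen=True)
class TokenizedSentence:
    """One text unit as a multiset of normalized word types."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("TokenizedSentence must contain at least one token")

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class SentenceCorpus:
    """Ordered sequence of tokenized units; order never affects scoring."""

    sentences: tuple[TokenizedSentence, ...]

    def __post_init__(self) -> None:
        if not self.sentences:
            raise EmptyInputError("corpus must contain at least one sentence")

    @property
    def n_units(self) -> int:
        return len(self.sentences)

    def vocabulary(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sentences:
            out |= s.types
        return frozenset(out)

    def __iter__(self):
        return iter(self.sentences)


@dataclass(frozen=True)
class NeighborSet:
    """The set ``O_w`` of word types co-occurring with concept ``w``.

    The concept word itself is always a member, so a sentence mentioning
    the concept activates it.
    """

    concept: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.concept not in self.members:
            object.__setattr__(self, "members", self.members | {self.concept})

    def intersects(self, sentence: TokenizedSentence) -> bool:
        return not self.members.isdisjoint(sentence.types)


@dataclass(frozen=True)
class ContingencyCounts:
    """Sentence counts ``N_ij`` over the four activation classes.

    ``n10`` counts sentences activating only concept A (first index),
    ``n01`` only concept B, ``n11`` both, ``n00`` neither.
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        for v in (self.n00, self.n01, self.n10, self.n11):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")

    @property
    def n_total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n00, self.n01, self.n10, self.n11)

    def to_dict(self) -> dict[str, int]:
        return {"n00": self.n00, "n01": self.n01, "n10": self.n10, "n11": self.n11}


def _tokenize_unit(unit: str, config: TokenizerConfig) -> tuple[str, ...]:
    if config.case_fold:
        unit = unit.lower()
    return tuple(_WORD_RE.findall(unit))


def segment_text(raw_text: str, config: TokenizerConfig | None = None) -> SentenceCorpus:
    """Split raw text into tokenized units.

    Raises
    ------
    EmptyInputError
        If no unit survives normalization (e.g. whitespace-only input).
    """
    config = config or TokenizerConfig()
    if not raw_text.strip():
        raise EmptyInputError("input text is empty")
    if config.granularity == "paragraph":
        pieces = re.split(_PARAGRAPH_DELIMITER, raw_text)
    elif config.granularity == "sentence":
        pieces = re.split(config.delimiter, raw_text)
    else:
        raise ValueError(f"unknown granularity: {config.granularity!r}")
    units = []
    for piece in pieces:
        tokens = _tokenize_unit(piece, config)
        if tokens:
            units.append(TokenizedSentence(tokens))
    if not units:
        raise EmptyInputError("no non-empty units after tokenization")
    return SentenceCorpus(tuple(units))


def build_neighbor_set(
    corpus: SentenceCorpus,
    concept: str,
    stopwords: Iterable[str] | None = None,
) -> NeighborSet:
    """Collect the words co-occurring with ``concept`` in any sentence.

    The result is the union of the token sets of all sentences containing
    the concept, minus stopwords, plus the concept itself. If the concept
    never occurs the set degenerates to ``{concept}`` and a warning is
    emitted — such documents score zero connection rather than erroring,
    so they remain rankable.
    """
    stop = frozenset(default_stopwords() if stopwords is None else stopwords)
    members: set[str] = set()
    seen = False
    for sentence in corpus:
        if concept in sentence.types:
            seen = True
            members |= sentence.types
    if not seen:
        warnings.warn(
            f"concept {concept!r} does not occur in the corpus; "
            "neighbor set degenerates to the concept itself",
            stacklevel=2,
        )
    members -= stop
    members.add(concept)
    return NeighborSet(concept, frozenset(members))


def categorize_sentences(
    corpus: SentenceCorpus, set_a: NeighborSet, set_b: NeighborSet
) -> ContingencyCounts:
    """Assign every sentence to exactly one activation class and count.

    A sentence activates concept A (first index 1) iff it shares at least
    one word with ``set_a.members``, and likewise for B; the four counts
    always sum to the number of units.
    """
    n = np.zeros((2, 2), dtype=np.int64)
    for sentence in corpus:
        i = 1 if set_a.intersects(sentence) else 0
        j = 1 if set_b.intersects(sentence) else 0
        n[i, j] += 1
    return ContingencyCounts(n00=int(n[0, 0]), n01=int(n[0, 1]), n10=int(n[1, 0]), n11=int(n[1, 1]))


def shuffle_words(corpus: SentenceCorpus, seed: int) -> SentenceCorpus:
    """Randomly redistribute all tokens over the existing sentence lengths.

    The global token multiset and the sentence-length profile are preserved;
    only the assignment of words to sentences changes. Destroying the
    sentence structure this way is the null model against which detected
    semantic connection is judged: a shuffled text should factorize.
    """
    rng = np.random.default_rng(seed)
    pool = [tok for sentence in corpus for tok in sentence.tokens]
    order = rng.permutation(len(pool))
    shuffled = [pool[k] for k in order]
    out = []
    pos = 0
    for sentence in corpus:
        ln = len(sentence)
        out.append(TokenizedSentence(tuple(shuffled[pos : pos + ln])))
        pos += ln
    return SentenceCorpus(tuple(out))
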