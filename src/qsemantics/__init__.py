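"""Quantum-cognitive measurement of semantic connection between word pairs.

A document is read as a bag of sentences, each sentence is classified by
co-occurrence with two concept words into one of four activation classes,
and the resulting counts define a two-qubit perception state whose
concurrence — with one free quantum phase — quantifies how strongly the
text ties the two concepts together. Classical baselines (phi coefficient,
per-document LSA cosine, search-engine rank) and a reference benchmark of
15 expert-scored probe documents are included.
"""

from .corpus import (
    ContingencyCounts,
    EmptyInputError,
    NeighborSet,
    SentenceCorpus,
    TokenizedSentence,
    TokenizerConfig,
    build_neighbor_set,
    categorize_sentences,
    default_stopwords,
    segment_text,
    shuffle_words,
)
from .states import (
    MarginalAmplitudes,
    PhaseConfig,
    ProbabilityTable,
    SingleQubitState,
    TwoQubitState,
    ZeroTotalError,
    build_state,
    estimate_probabilities,
    factorization_check,
    marginal_models,
)
from .entanglement import (
    SIGMA_Y,
    SPIN_FLIP,
    ConcurrenceRange,
    ConnectivityReport,
    NotNormalizedError,
    concurrence,
    concurrence_from_counts,
    concurrence_range,
    is_defined,
    phi_coefficient,
    score_counts,
    spin_flip_concurrence,
)
from .evaluation import (
    RegressionFit,
    TuningResult,
    r_squared,
    rank_documents,
    relevance_to_concurrence,
    tune_concurrences,
)
from .lsa import (
    DegenerateCorpusError,
    LsaEmbedding,
    MissingTermError,
    TermMatrix,
    build_term_matrix,
    lsa_embed,
    lsa_similarity,
)
from .synthetic import (
    CorruptedFixtureError,
    DocumentRecord,
    GeneratorSpec,
    InvalidSpecError,
    fixture_ranges,
    generate_corpus,
    load_fixture,
    reproduce_figure3,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def score_text(
    raw_text: str,
    concept_a: str,
    concept_b: str,
    *,
    config: TokenizerConfig | None = None,
    delta: float | None = None,
) -> ConnectivityReport:
    """End-to-end scoring of one document for a concept pair.

    Segments and tokenizes the text, builds both neighbor sets, classifies
    the sentences and returns the full connectivity report (counts,
    probabilities, concurrence range, phi, and optionally the concurrence
    at a caller-supplied phase ``delta``).
    """
    config = config or TokenizerConfig()
    corpus = segment_text(raw_text, config)
    stop = config.resolved_stopwords()
    set_a = build_neighbor_set(corpus, concept_a, stopwords=stop)
    set_b = build_neighbor_set(corpus, concept_b, stopwords=stop)
    counts = categorize_sentences(corpus, set_a, set_b)
    return score_counts(counts, delta=delta)
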