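import numpy as np
import pytest

from qsemantics import ContingencyCounts, SentenceCorpus, TokenizedSentence


@pytest.fixture
def counts_4321() -> ContingencyCounts:
    """Small reference table used across the closed-form examples."""
    return ContingencyCounts(n00=4, n01=3, n10=2, n11=1)


@pytest.fixture
def tiny_corpus() -> SentenceCorpus:
    return SentenceCorpus(
        (
            TokenizedSentence(("cats", "purr")),
            TokenizedSentence(("dogs", "bark")),
            TokenizedSentence(("cats", "chase", "dogs")),
            TokenizedSentence(("rain", "falls")),
        )
    )


def random_counts(rng: np.random.Generator, max_count: int = 50) -> ContingencyCounts:
    while True:
        vals = rng.integers(0, max_count + 1, size=4)
        if vals.sum() >= 1:
            return ContingencyCounts(*map(int, vals))
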