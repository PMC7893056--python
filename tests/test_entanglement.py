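"""Concurrence in its three forms, its phase range, and the phi baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsemantics import (
    ContingencyCounts,
    NeighborSet,
    NotNormalizedError,
    PhaseConfig,
    TwoQubitState,
    build_state,
    categorize_sentences,
    concurrence,
    concurrence_from_counts,
    concurrence_range,
    estimate_probabilities,
    factorization_check,
    is_defined,
    phi_coefficient,
    score_counts,
    shuffle_words,
    spin_flip_concurrence,
)
from qsemantics.synthetic import GeneratorSpec, generate_corpus
from qsemantics.states import ProbabilityTable

from conftest import random_counts

counts_strategy = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
).filter(lambda t: sum(t) >= 1)


def spin_flip_oracle(vec: np.ndarray) -> float:
    """Independent |<Psi| sigma_y x sigma_y |Psi*>| built from scratch."""
    sy = np.array([[0, -1j], [1j, 0]])
    m = np.kron(sy, sy)
    return abs(vec.conj() @ (m @ vec.conj()))


def random_state(rng: np.random.Generator) -> TwoQubitState:
    v = rng.normal(size=4) + 1j * rng.normal(size=4)
    v /= np.linalg.norm(v)
    return TwoQubitState(*v)


class TestConcurrence:
    def test_bell_state_is_maximally_entangled(self):
        s = TwoQubitState(1 / math.sqrt(2), 0, 0, 1 / math.sqrt(2))
        assert concurrence(s) == pytest.approx(1.0)

    def test_product_state_has_zero_concurrence(self):
        a0, a1 = math.cos(0.3), math.sin(0.3)
        b0, b1 = math.cos(1.1), math.sin(1.1)
        s = TwoQubitState(a0 * b0, a0 * b1, a1 * b0, a1 * b1)
        assert concurrence(s) == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_matches_spin_flip_on_random_states(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = random_state(rng)
            q = concurrence(s)
            assert abs(q - spin_flip_oracle(s.as_vector())) < 1e-12
            assert abs(q - spin_flip_concurrence(s)) < 1e-12
            assert -1e-12 <= q <= 1.0 + 1e-12

    def test_non_normalized_rejected(self):
        s = TwoQubitState(1 / math.sqrt(2), 0, 0, 1 / math.sqrt(2))
        object.__setattr__(s, "c00", 0.9)
        with pytest.raises(NotNormalizedError):
            concurrence(s)


class TestCountForm:
    def test_factorized_counts_zero_at_delta_zero(self):
        assert concurrence_from_counts(ContingencyCounts(4, 2, 6, 3), 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_known_values_4321(self, counts_4321):
        assert concurrence_from_counts(counts_4321, math.pi) == pytest.approx(0.8899, abs=5e-5)
        assert concurrence_from_counts(counts_4321, math.pi / 2) == pytest.approx(
            2 * math.sqrt(10) / 10, abs=1e-12
        )

    @given(counts_strategy, st.floats(0, 2 * math.pi))
    @settings(max_examples=80, deadline=None)
    def test_three_forms_agree(self, raw, delta):
        """Count form == amplitude closed form == spin-flip overlap."""
        counts = ContingencyCounts(*raw)
        q_counts = concurrence_from_counts(counts, delta)
        state = build_state(estimate_probabilities(counts), PhaseConfig.from_delta(delta))
        assert abs(q_counts - concurrence(state)) < 1e-10
        assert abs(q_counts - spin_flip_oracle(state.as_vector())) < 1e-10
        assert 0.0 <= q_counts <= 1.0 + 1e-12

    def test_delta_continuity_and_extrema_location(self, counts_4321):
        deltas = np.linspace(0, 2 * math.pi, 2001)
        qs = np.array([concurrence_from_counts(counts_4321, d) for d in deltas])
        assert np.max(np.abs(np.diff(qs))) < 0.01  # continuous on a fine grid
        assert qs.argmin() in (0, len(qs) - 1)      # min at cos=+1
        assert abs(deltas[qs.argmax()] - math.pi) < 0.01  # max at cos=-1


class TestConcurrenceRange:
    def test_reference_table(self, counts_4321):
        r = concurrence_range(counts_4321)
        assert r.q_min == pytest.approx(0.08990, abs=5e-5)
        assert r.q_max == pytest.approx(0.88990, abs=5e-5)
        assert r.q_rand == pytest.approx(2 * math.sqrt(10) / 10, abs=1e-12)

    def test_vanishing_cross_product_collapses_interval(self):
        r = concurrence_range(ContingencyCounts(4, 3, 2, 0))
        expected = 2 * math.sqrt(6) / 9
        assert r.q_min == pytest.approx(expected, abs=1e-12)
        assert r.q_max == pytest.approx(expected, abs=1e-12)
        assert r.q_rand == pytest.approx(expected, abs=1e-12)
        assert r.degenerate

    @given(counts_strategy)
    @settings(max_examples=80, deadline=None)
    def test_grid_oracle_and_ordering(self, raw):
        counts = ContingencyCounts(*raw)
        r = concurrence_range(counts)
        grid = np.array(
            [concurrence_from_counts(counts, d) for d in np.linspace(0, 2 * math.pi, 721)]
        )
        assert r.q_min <= r.q_rand <= r.q_max + 1e-12
        assert grid.min() == pytest.approx(r.q_min, abs=1e-4)
        assert grid.max() == pytest.approx(r.q_max, abs=1e-4)
        assert 0.0 <= r.q_min and r.q_max <= 1.0 + 1e-12


class TestPhiCoefficient:
    def test_reference_value(self, counts_4321):
        assert phi_coefficient(counts_4321) == pytest.approx(-0.08909, abs=5e-6)

    def test_perfect_association(self):
        assert phi_coefficient(ContingencyCounts(3, 0, 0, 5)) == pytest.approx(1.0)

    def test_zero_marginal_is_undefined(self):
        phi = phi_coefficient(ContingencyCounts(0, 3, 0, 1))
        assert not is_defined(phi)

    def test_matches_pearson_of_indicator_vectors(self):
        """phi equals Pearson r of the expanded 0/1 indicator vectors."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 200:
            counts = random_counts(rng, max_count=12)
            x, y = [], []
            for (i, j), n in zip(((0, 0), (0, 1), (1, 0), (1, 1)), counts.as_tuple()):
                x += [i] * n
                y += [j] * n
            x, y = np.array(x), np.array(y)
            phi = phi_coefficient(counts)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                assert not is_defined(phi)
                continue
            assert phi == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-12)
            assert -1.0 <= phi <= 1.0
            checked += 1

    @given(counts_strategy)
    @settings(max_examples=80, deadline=None)
    def test_probability_substitution_reproduces_phi_numerator(self, raw):
        """Swapping amplitudes for probabilities in the concurrence difference
        yields the numerator of the phi coefficient (up to the 1/N^2 scale)."""
        counts = ContingencyCounts(*raw)
        p = estimate_probabilities(counts)
        diff = p.p01 * p.p10 - p.p00 * p.p11
        num = (counts.n01 * counts.n10 - counts.n00 * counts.n11) / counts.n_total**2
        assert diff == pytest.approx(num, abs=1e-12)


class TestShuffleNull:
    def test_word_shuffle_drives_concurrence_down(self):
        """Shuffling words across sentences destroys the detected connection."""
        spec = GeneratorSpec(
            p_table=ProbabilityTable(0.45, 0.05, 0.05, 0.45), n_sentences=300, seed=9
        )
        corpus = generate_corpus(spec)
        set_a, set_b = spec.neighbor_sets()
        structured = concurrence_from_counts(categorize_sentences(corpus, set_a, set_b), 0.0)
        shuffled_q = []
        for seed in range(100):
            sh = shuffle_words(corpus, seed=seed)
            shuffled_q.append(
                concurrence_from_counts(categorize_sentences(sh, set_a, set_b), 0.0)
            )
        assert structured > 0.5
        assert np.mean(shuffled_q) < structured


def test_score_counts_bundles_consistent_report(counts_4321):
    report = score_counts(counts_4321, delta=math.pi)
    assert report.counts is counts_4321
    assert report.q_at_delta == pytest.approx(0.8899, abs=5e-5)
    assert report.concurrence_range.q_rand == pytest.approx(2 * math.sqrt(10) / 10)
    payload = report.to_dict()
    assert payload["counts"]["n00"] == 4
    assert payload["phi"] == pytest.approx(-0.08909, abs=5e-6)
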