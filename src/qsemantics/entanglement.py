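"""Concurrence measure of semantic connection and the classical phi baseline.

For a pure two-qubit state the concurrence is

    Q = |<Psi| sigma_y (x) sigma_y |Psi*>| = 2 |c01 c10 - c00 c11|,  0 <= Q <= 1.

Substituting the count-based amplitudes c_ij = sqrt(N_ij/N) e^{i phi_ij}
gives a closed form in the counts and the single phase combination Delta:

    Q(Delta) = 2 sqrt[ (N01 N10 + N00 N11)/N^2
                       - 2 sqrt(N01 N10 N00 N11)/N^2 * cos(Delta) ].

Varying Delta sweeps Q over the interval [q_min, q_max] attained at
cos(Delta) = +1 and -1; phase averaging nullifies the cosine term and
yields the phase-randomized value q_rand = 2 sqrt(N01 N10 + N00 N11)/N.
The phi coefficient (mean square contingency) of the same 2x2 table is the
classical counterpart: its numerator is exactly the concurrence difference
with amplitudes replaced by probabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import ContingencyCounts
from .states import (
    PhaseConfig,
    ProbabilityTable,
    TwoQubitState,
    ZeroTotalError,
    build_state,
    estimate_probabilities,
)

__all__ = [
    "NotNormalizedError",
    "SIGMA_Y",
    "SPIN_FLIP",
    "ConcurrenceRange",
    "ConnectivityReport",
    "concurrence",
    "spin_flip_concurrence",
    "concurrence_from_counts",
    "concurrence_range",
    "phi_coefficient",
    "is_defined",
    "score_counts",
]


class NotNormalizedError(ValueError):
    """Raised when concurrence is requested for a non-normalized state."""


#: Pauli Y in the computational basis. Applying it twice negates any qubit.
SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)

#: The two-qubit spin-flip operator sigma_y (x) sigma_y.
SPIN_FLIP = np.kron(SIGMA_Y, SIGMA_Y)


@dataclass(frozen=True)
class ConcurrenceRange:
    """Concurrence values attainable by varying the phase Delta.

    ``q_min``/``q_max`` are the extremes at cos(Delta) = +1/-1 and
    ``q_rand`` is the phase-randomized value. The interval collapses to a
    point whenever any of the four counts is zero.
    """

    q_min: float
    q_max: float
    q_rand: float

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (-eps <= self.q_min <= self.q_rand + eps and self.q_rand <= self.q_max + eps):
            raise ValueError("require 0 <= q_min <= q_rand <= q_max")
        if self.q_max > 1.0 + eps:
            raise ValueError("concurrence cannot exceed 1")

    @property
    def degenerate(self) -> bool:
        return self.q_max - self.q_min < 1e-15


def concurrence(state: TwoQubitState) -> float:
    """Concurrence 2|c01 c10 - c00 c11| of a normalized pure state."""
    if abs(state.norm_squared() - 1.0) > 1e-9:
        raise NotNormalizedError("state norm deviates from 1 by more than 1e-9")
    q = 2.0 * abs(state.c01 * state.c10 - state.c00 * state.c11)
    return float(min(q, 1.0))


def spin_flip_concurrence(state: TwoQubitState) -> float:
    """Concurrence via the explicit spin-flip overlap |<Psi|Y(x)Y|Psi*>|.

    Numerically identical to :func:`concurrence`; kept as the direct
    definition for cross-checking the closed form.
    """
    if abs(state.norm_squared() - 1.0) > 1e-9:
        raise NotNormalizedError("state norm deviates from 1 by more than 1e-9")
    psi = state.as_vector()
    return float(abs(psi.conj() @ (SPIN_FLIP @ psi.conj())))


def concurrence_from_counts(counts: ContingencyCounts, delta: float) -> float:
    """Concurrence of the count-based state at phase combination ``delta``."""
    n = counts.n_total
    if n < 1:
        raise ZeroTotalError("concurrence undefined for zero sentences")
    a = counts.n01 * counts.n10
    b = counts.n00 * counts.n11
    inner = (a + b) / n**2 - 2.0 * math.sqrt(a * b) / n**2 * math.cos(delta)
    return 2.0 * math.sqrt(max(inner, 0.0))


def concurrence_range(counts: ContingencyCounts) -> ConcurrenceRange:
    """Extremes and phase-randomized value of Q over Delta in [0, 2*pi)."""
    n = counts.n_total
    if n < 1:
        raise ZeroTotalError("concurrence undefined for zero sentences")
    ra = math.sqrt(counts.n01 * counts.n10)
    rb = math.sqrt(counts.n00 * counts.n11)
    return ConcurrenceRange(
        q_min=2.0 * abs(ra - rb) / n,
        q_max=min(2.0 * (ra + rb) / n, 1.0),
        q_rand=2.0 * math.hypot(ra, rb) / n,
    )


def phi_coefficient(counts: ContingencyCounts) -> float:
    """Mean square contingency C of the 2x2 table, in [-1, 1].

    Returns NaN (the undefined marker) when any row or column marginal is
    zero — one of the binary variables is then constant and correlation is
    meaningless. Use :func:`is_defined` to test the result.
    """
    if counts.n_total < 1:
        raise ZeroTotalError("phi undefined for zero sentences")
    r0 = counts.n00 + counts.n01
    r1 = counts.n10 + counts.n11
    c0 = counts.n00 + counts.n10
    c1 = counts.n01 + counts.n11
    denom = r0 * r1 * c0 * c1
    if denom == 0:
        return float("nan")
    num = counts.n00 * counts.n11 - counts.n10 * counts.n01
    return float(num / math.sqrt(denom))


def is_defined(value: float) -> bool:
    """True unless ``value`` is the NaN undefined-marker."""
    return not math.isnan(value)


@dataclass(frozen=True)
class ConnectivityReport:
    """Full connectivity measurement of one document for a concept pair."""

    counts: ContingencyCounts
    probabilities: ProbabilityTable
    concurrence_range: ConcurrenceRange
    phi: float
    q_at_delta: float | None = None

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "probabilities": self.probabilities.to_dict(),
            "concurrence": {
                "q_min": self.concurrence_range.q_min,
                "q_max": self.concurrence_range.q_max,
                "q_rand": self.concurrence_range.q_rand,
            },
            "phi": self.phi if is_defined(self.phi) else None,
            "q_at_delta": self.q_at_delta,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def score_counts(counts: ContingencyCounts, delta: float | None = None) -> ConnectivityReport:
    """Bundle probabilities, concurrence range and phi for one table."""
    return ConnectivityReport(
        counts=counts,
        probabilities=estimate_probabilities(counts),
        concurrence_range=concurrence_range(counts),
        phi=phi_coefficient(counts),
        q_at_delta=None if delta is None else concurrence_from_counts(counts, delta),
    )
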