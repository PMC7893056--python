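"""Qubit perception states built from sentence counts.

The four relative frequencies ``p_ij = N_ij / N`` are the squared moduli
of the amplitudes of a normalized two-qubit state

    |Psi> = c00|00> + c01|01> + c10|10> + c11|11>,   c_ij = sqrt(p_ij) e^{i phi_ij}.

The phases ``phi_ij`` cannot be inferred from the text; they are exogenous
parameters representing the subjective side of perception. Only the
combination ``Delta = phi01 + phi10 - phi00 - phi11`` affects the
entanglement of the state, so the canonical phase assignment puts the
whole of ``Delta`` on ``phi01`` and zeros elsewhere.

When word occurrences are statistically independent across sentences the
counts satisfy ``N01·N10 = N00·N11`` and the real-amplitude state is a
tensor product of the two marginal single-qubit models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .corpus import ContingencyCounts

__all__ = [
    "ZeroTotalError",
    "ProbabilityTable",
    "PhaseConfig",
    "SingleQubitState",
    "TwoQubitState",
    "MarginalAmplitudes",
    "estimate_probabilities",
    "build_state",
    "marginal_models",
    "factorization_check",
]

TWO_PI = 2.0 * math.pi
_NORM_TOL = 1e-12


class ZeroTotalError(ValueError):
    """Raised when a counts table with zero total is used for estimation."""


@dataclass(frozen=True)
class ProbabilityTable:
    """Joint activation probabilities of the four classes; sums to one."""

    p00: float
    p01: float
    p10: float
    p11: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(p < 0.0 or p > 1.0 for p in vals):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {sum(vals)!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p00, self.p01, self.p10, self.p11)

    def to_dict(self) -> dict[str, float]:
        return {"p00": self.p00, "p01": self.p01, "p10": self.p10, "p11": self.p11}


@dataclass(frozen=True)
class PhaseConfig:
    """Amplitude phases in radians, stored in [0, 2*pi)."""

    phi00: float = 0.0
    phi01: float = 0.0
    phi10: float = 0.0
    phi11: float = 0.0

    def __post_init__(self) -> None:
        for name in ("phi00", "phi01", "phi10", "phi11"):
            object.__setattr__(self, name, getattr(self, name) % TWO_PI)

    @property
    def delta(self) -> float:
        """The phase combination phi01 + phi10 - phi00 - phi11 (mod 2*pi)."""
        return (self.phi01 + self.phi10 - self.phi00 - self.phi11) % TWO_PI

    @classmethod
    def from_delta(cls, delta: float) -> "PhaseConfig":
        """Canonical assignment carrying the whole phase freedom on phi01."""
        return cls(phi01=delta % TWO_PI)


@dataclass(frozen=True)
class SingleQubitState:
    """Normalized amplitudes (c0, c1) over passive/active outcomes."""

    c0: complex
    c1: complex

    def __post_init__(self) -> None:
        norm = abs(self.c0) ** 2 + abs(self.c1) ** 2
        if abs(norm - 1.0) > _NORM_TOL:
            raise ValueError(f"single-qubit state not normalized: |c|^2 = {norm!r}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.c0, self.c1], dtype=complex)


@dataclass(frozen=True)
class TwoQubitState:
    """Normalized amplitudes over the |00>,|01>,|10>,|11> activation basis."""

    c00: complex
    c01: complex
    c10: complex
    c11: complex

    def __post_init__(self) -> None:
        if abs(self.norm_squared() - 1.0) > _NORM_TOL:
            raise ValueError(f"two-qubit state not normalized: |c|^2 = {self.norm_squared()!r}")

    def norm_squared(self) -> float:
        return float(sum(abs(c) ** 2 for c in self.as_vector()))

    def as_vector(self) -> np.ndarray:
        """Amplitudes in basis order |00>, |01>, |10>, |11>."""
        return np.array([self.c00, self.c01, self.c10, self.c11], dtype=complex)

    def probabilities(self) -> ProbabilityTable:
        p = np.abs(self.as_vector()) ** 2
        p = p / p.sum()
        return ProbabilityTable(*map(float, p))

    def to_json(self) -> str:
        labels = ("c00", "c01", "c10", "c11")
        return json.dumps(
            {k: {"re": c.real, "im": c.imag} for k, c in zip(labels, self.as_vector())}
        )

    @classmethod
    def from_json(cls, text: str) -> "TwoQubitState":
        obj = json.loads(text)
        return cls(*(complex(obj[k]["re"], obj[k]["im"]) for k in ("c00", "c01", "c10", "c11")))


@dataclass(frozen=True)
class MarginalAmplitudes:
    """Real amplitudes of the two marginal single-qubit models."""

    a0: float
    a1: float
    b0: float
    b1: float

    def __post_init__(self) -> None:
        if abs(self.a0**2 + self.a1**2 - 1.0) > _NORM_TOL:
            raise ValueError("marginal A not normalized")
        if abs(self.b0**2 + self.b1**2 - 1.0) > _NORM_TOL:
            raise ValueError("marginal B not normalized")

    def state_a(self) -> SingleQubitState:
        return SingleQubitState(complex(self.a0), complex(self.a1))

    def state_b(self) -> SingleQubitState:
        return SingleQubitState(complex(self.b0), complex(self.b1))

    def product_state(self) -> TwoQubitState:
        """Tensor product |psi_a> x |psi_b> with real amplitudes."""
        return TwoQubitState(
            c00=complex(self.a0 * self.b0),
            c01=complex(self.a0 * self.b1),
            c10=complex(self.a1 * self.b0),
            c11=complex(self.a1 * self.b1),
        )


def estimate_probabilities(counts: ContingencyCounts) -> ProbabilityTable:
    """Relative class frequencies p_ij = N_ij / N."""
    n = counts.n_total
    if n < 1:
        raise ZeroTotalError("cannot estimate probabilities from zero sentences")
    p = np.array(counts.as_tuple(), dtype=float) / n
    # renormalize away float rounding so the table invariant holds exactly
    p = p / p.sum()
    return ProbabilityTable(*map(float, p))


def build_state(p: ProbabilityTable, phases: PhaseConfig | None = None) -> TwoQubitState:
    """Assemble amplitudes c_ij = sqrt(p_ij) * exp(i*phi_ij)."""
    phases = phases or PhaseConfig()
    phis = (phases.phi00, phases.phi01, phases.phi10, phases.phi11)
    amps = [math.sqrt(pv) * complex(math.cos(ph), math.sin(ph)) for pv, ph in zip(p.as_tuple(), phis)]
    vec = np.array(amps, dtype=complex)
    vec = vec / np.linalg.norm(vec)
    return TwoQubitState(*vec)


def marginal_models(counts: ContingencyCounts) -> MarginalAmplitudes:
    """Single-concept models from the row/column marginals of the counts.

    a0^2 = (N00+N01)/N (concept A passive), a1^2 = (N10+N11)/N, and
    symmetrically for concept B over columns.
    """
    n = counts.n_total
    if n < 1:
        raise ZeroTotalError("cannot build marginals from zero sentences")
    a0 = math.sqrt((counts.n00 + counts.n01) / n)
    a1 = math.sqrt((counts.n10 + counts.n11) / n)
    b0 = math.sqrt((counts.n00 + counts.n10) / n)
    b1 = math.sqrt((counts.n01 + counts.n11) / n)
    # exact renormalization of each pair against sqrt rounding
    za = math.hypot(a0, a1)
    zb = math.hypot(b0, b1)
    return MarginalAmplitudes(a0 / za, a1 / za, b0 / zb, b1 / zb)


def factorization_check(counts: ContingencyCounts, tol: float = 0.0) -> bool:
    """Test the independence condition N01·N10 == N00·N11.

    The cross-product form is used so the test stays defined when a count
    vanishes; the tolerance is scaled by N^2 to make it a statement about
    the probability table rather than raw counts. When true (and phases are
    zero) the state is exactly the product of its marginal models.
    """
    if counts.n_total < 1:
        raise ZeroTotalError("factorization undefined for zero sentences")
    lhs = counts.n01 * counts.n10
    rhs = counts.n00 * counts.n11
    return abs(lhs - rhs) <= tol * counts.n_total**2
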