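"""Regression against reference relevance scores, phase tuning, and ranking.

Connectivity measures are compared with mean expert relevance scores via
the determination coefficient R^2 of simple linear regression (equal to
the squared Pearson correlation, hence symmetric in its arguments). The
quantum phase Delta gives each document one tunable degree of freedom: its
concurrence may lie anywhere in [q_min, q_max]. ``tune_concurrences``
jointly picks one value per document inside its interval so as to maximize
R^2 against the reference scores — the model's best agreement with the
expert ranking that the objective count statistics allow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .entanglement import ConcurrenceRange, ConnectivityReport, is_defined

__all__ = [
    "RegressionFit",
    "TuningResult",
    "r_squared",
    "tune_concurrences",
    "relevance_to_concurrence",
    "rank_documents",
]

_GOLDEN_TOL = 1e-10
_CONVERGENCE_TOL = 1e-9
_COARSE_GRID = 65


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares fit of y on x with its R^2."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class TuningResult:
    """Outcome of the joint phase tuning over all documents."""

    tuned_values: tuple[float, ...]
    achieved_r_squared: float
    iterations: int


def _validate_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 points for regression")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input; R^2 undefined")


def r_squared(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS of y on x; R^2 is the squared Pearson correlation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    _validate_pair(xa, ya)
    fit = stats.linregress(xa, ya)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(xa.size),
    )


def _r2_objective(values: np.ndarray, reference: np.ndarray) -> float:
    """Squared correlation, 0 when the candidate vector is constant."""
    sy = values.std()
    if sy == 0.0:
        return 0.0
    c = float(np.corrcoef(reference, values)[0, 1])
    return c * c


def _golden_max(f, lo: float, hi: float) -> float:
    """Golden-section maximization of f on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > _GOLDEN_TOL:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _best_coordinate(values: np.ndarray, i: int, lo: float, hi: float, reference: np.ndarray) -> float:
    """Best value of coordinate i on [lo, hi] with the others fixed.

    R^2 along one coordinate is a squared ratio of a linear to a
    root-quadratic form and can carry two local maxima, so a coarse grid
    locates the global basin before golden-section refinement.
    """

    def f(v: float) -> float:
        values[i] = v
        return _r2_objective(values, reference)

    grid = np.linspace(lo, hi, _COARSE_GRID)
    scores = np.array([f(v) for v in grid])
    k = int(np.argmax(scores))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, _COARSE_GRID - 1)]
    best = _golden_max(f, a, b)
    # keep whichever candidate actually scores highest
    candidates = [grid[k], best]
    vals = [f(v) for v in candidates]
    choice = candidates[int(np.argmax(vals))]
    values[i] = choice
    return choice


def tune_concurrences(
    ranges: Sequence[ConcurrenceRange], reference: Sequence[float]
) -> TuningResult:
    """Jointly maximize R^2 by picking one value inside each interval.

    Deterministic coordinate ascent: starting from the phase-randomized
    values, documents are visited in fixed order and each coordinate is
    set to its best response on [q_min, q_max] (coarse grid plus
    golden-section refinement); sweeps continue until the objective gains
    less than 1e-9, plus two confirmation sweeps. The objective never
    decreases, so the result is always at least the q_rand baseline.
    """
    ref = np.asarray(reference, dtype=float)
    if len(ranges) != ref.size:
        raise ValueError("ranges and reference must have equal length")
    if ref.size < 3:
        raise ValueError("need at least 3 documents for tuning")
    if np.ptp(ref) == 0:
        raise ValueError("zero-variance reference; R^2 undefined")
    values = np.array([r.q_rand for r in ranges], dtype=float)

    lo = np.array([r.q_min for r in ranges])
    hi = np.array([r.q_max for r in ranges])
    free = [i for i in range(values.size) if hi[i] - lo[i] > 0.0]

    best = _r2_objective(values, ref)
    sweeps = 0
    calm = 0
    while calm < 2 and sweeps < 200:
        sweeps += 1
        for i in free:
            prev_v = values[i]
            prev_obj = _r2_objective(values, ref)
            _best_coordinate(values, i, lo[i], hi[i], ref)
            if _r2_objective(values, ref) < prev_obj:  # monotone guard
                values[i] = prev_v
        now = _r2_objective(values, ref)
        calm = calm + 1 if now - best < _CONVERGENCE_TOL else 0
        best = max(best, now)
    return TuningResult(
        tuned_values=tuple(float(v) for v in values),
        achieved_r_squared=float(best),
        iterations=sweeps,
    )


def relevance_to_concurrence(score: float) -> float:
    """Map an expert relevance score on [0, 10] linearly onto [0, 1]."""
    if not 0.0 <= score <= 10.0:
        raise ValueError(f"relevance score must lie in [0, 10], got {score!r}")
    return score / 10.0


_MEASURES = {
    "q_rand": lambda r: r.concurrence_range.q_rand,
    "q_at_delta": lambda r: r.q_at_delta,
    "phi": lambda r: r.phi,
}


def rank_documents(
    reports: Sequence[tuple[str, ConnectivityReport]], mode: str = "q_rand"
) -> list[str]:
    """Order document ids by the selected measure, descending.

    Ties preserve input order; undefined values (NaN phi, missing
    q_at_delta) sort last.
    """
    if not reports:
        raise ValueError("cannot rank an empty document list")
    if mode not in _MEASURES:
        raise ValueError(f"unknown ranking mode: {mode!r}")
    extract = _MEASURES[mode]

    def key(item):
        idx, (doc_id, report) = item
        v = extract(report)
        undefined = v is None or not is_defined(v)
        return (1 if undefined else 0, 0.0 if undefined else -float(v), idx)

    ordered = sorted(enumerate(reports), key=key)
    return [doc_id for _, (doc_id, _) in ordered]
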