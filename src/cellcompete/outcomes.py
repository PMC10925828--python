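"""Phase-plane analysis of the two-line competition system.

Setting each line's net growth to zero gives its zero-growth isocline in
the (N1, N2) plane:

* line 1: ``N1 = K1 - alpha * N2``, intercepts ``[0, K1/alpha]`` and
  ``[K1, 0]``;
* line 2: ``N2 = K2 - beta * N1``, intercepts ``[0, K2]`` and
  ``[K2/beta, 0]``.

The relative position of the two isoclines determines the long-run
outcome: one line always excludes the other, the outcome depends on the
initial densities (bistability), or the lines coexist.  The classifier
implements the standard phase-plane rules, which agree with long-horizon
integration of the system:

* line 1 excludes line 2 when ``K1 > K2/beta`` and ``K2 < K1/alpha``
  (line 1's isocline lies wholly outside line 2's);
* line 2 excludes line 1 when the reverse holds;
* both inequalities "inward" (``K1 > K2/beta`` and ``K2 > K1/alpha``,
  strong mutual competition) give initial-condition dependence;
* both "outward" (weak competition) give coexistence.

A coefficient <= 0 removes the corresponding exclusion pathway (the
isocline does not cross the positive quadrant); the affected intercept
is reported as +inf by the limit convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .growth import CompetitionSystem, integrate_lv_scalar

__all__ = [
    "IsoclineSet",
    "OutcomeClass",
    "InteractionClass",
    "OutcomeResult",
    "isocline_intercepts",
    "classify_outcome",
    "classify_interaction",
    "simulate_outcome",
    "outcome_map",
    "estimate_separatrix",
]


class OutcomeClass(Enum):
    LINE1_EXCLUDES_LINE2 = "line1_excludes_line2"
    LINE2_EXCLUDES_LINE1 = "line2_excludes_line1"
    INITIAL_CONDITIONS_DEPENDENT = "initial_conditions_dependent"
    COEXISTENCE = "coexistence"
    BOUNDARY = "boundary"


class InteractionClass(Enum):
    COMPETITION = "competition"
    MUTUALISM = "mutualism"
    COMMENSALISM = "commensalism"
    PARASITISM = "parasitism"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class IsoclineSet:
    """Axis intercepts of the two zero-growth isoclines (cells).

    ``line1_n2_intercept`` is K1/alpha (the N2 level that halts line 1),
    ``line1_n1_intercept`` is K1; analogously for line 2.  Intercepts are
    +inf when the competition coefficient is zero (limit convention) or
    negative (the isocline never crosses the positive quadrant).
    """

    line1_n2_intercept: float
    line1_n1_intercept: float
    line2_n2_intercept: float
    line2_n1_intercept: float


def _positive_intercept(K: float, coef: float) -> float:
    if coef <= 0:
        return math.inf
    return K / coef


def isocline_intercepts(sys: CompetitionSystem) -> IsoclineSet:
    """Axis intercepts of both lines' zero-growth isoclines."""
    if sys.K1 <= 0 or sys.K2 <= 0:
        raise ValueError("carrying capacities must be positive")
    return IsoclineSet(
        line1_n2_intercept=_positive_intercept(sys.K1, sys.alpha),
        line1_n1_intercept=sys.K1,
        line2_n2_intercept=sys.K2,
        line2_n1_intercept=_positive_intercept(sys.K2, sys.beta),
    )


def classify_outcome(sys: CompetitionSystem, rel_tol: float = 0.0) -> OutcomeClass:
    """Long-run competition outcome from the isocline inequalities.

    Compares K1 with K2/beta and K2 with K1/alpha.  Equalities (within
    ``rel_tol`` relative tolerance) are measure-zero boundaries and are
    reported as ``BOUNDARY`` rather than forced into a regime.
    """
    iso = isocline_intercepts(sys)
    t1 = iso.line2_n1_intercept  # K2/beta: N1 level that halts line 2
    t2 = iso.line1_n2_intercept  # K1/alpha: N2 level that halts line 1

    def cmp(a: float, b: float) -> int:
        if math.isinf(b):
            return -1
        if abs(a - b) <= rel_tol * max(abs(a), abs(b)):
            return 0
        return 1 if a > b else -1

    c1 = cmp(sys.K1, t1)  # can line 1 push line 2 to zero growth?
    c2 = cmp(sys.K2, t2)  # can line 2 push line 1 to zero growth?
    if c1 == 0 or c2 == 0:
        return OutcomeClass.BOUNDARY
    if c1 > 0 and c2 < 0:
        return OutcomeClass.LINE1_EXCLUDES_LINE2
    if c1 < 0 and c2 > 0:
        return OutcomeClass.LINE2_EXCLUDES_LINE1
    if c1 > 0 and c2 > 0:
        return OutcomeClass.INITIAL_CONDITIONS_DEPENDENT
    return OutcomeClass.COEXISTENCE


def classify_interaction(alpha: float, beta: float, zero_band: float = 0.5) -> InteractionClass:
    """Sign-pattern interaction type of the coefficient pair.

    Positive/positive is competition, negative/negative mutualism, one
    negative with the other (near) zero commensalism, opposite signs
    parasitism.  ``|value| <= zero_band`` counts as zero (default half a
    grid step).
    """
    if zero_band < 0:
        raise ValueError("zero_band must be non-negative")

    def sign(v: float) -> int:
        if abs(v) <= zero_band:
            return 0
        return 1 if v > 0 else -1

    sa, sb = sign(alpha), sign(beta)
    if sa == 0 and sb == 0:
        return InteractionClass.NEUTRAL
    if sa < 0 and sb < 0:
        return InteractionClass.MUTUALISM
    if (sa < 0 and sb == 0) or (sa == 0 and sb < 0):
        return InteractionClass.COMMENSALISM
    if sa * sb < 0:
        return InteractionClass.PARASITISM
    # (+,+) and the undefined one-sided (+,0)/(0,+) amensal patterns both
    # report as competition: at least one line is harmed, none helped.
    return InteractionClass.COMPETITION


@dataclass(frozen=True)
class OutcomeResult:
    """Result of one outcome simulation."""

    winner: str  # "line1", "line2", "coexistence", or "divergent"
    n1_final: float
    n2_final: float
    t_final: float
    start_fraction_line1: float


def simulate_outcome(
    sys: CompetitionSystem,
    start_fraction_line1: float,
    total_cells: float = 1e5,
    horizon: float = 100.0,
    extinction_threshold: float = 1.0,
    step: float = 0.01,
    ceiling: float = 1e9,
) -> OutcomeResult:
    """Integrate the system from a starting split and call the winner.

    A line "wins" when the other falls below ``extinction_threshold``
    cells while it stays above; both persisting at the horizon is
    coexistence.  LV dynamics only reach zero asymptotically, so the
    threshold (default one whole cell per well) stands in for extinction.
    Divergent (blown-up) trajectories are flagged with no winner.
    """
    if not 0 <= start_fraction_line1 <= 1:
        raise ValueError("start_fraction_line1 must be in [0, 1]")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n0_1 = start_fraction_line1 * total_cells
    n0_2 = (1.0 - start_fraction_line1) * total_cells
    n1, n2, t, div = integrate_lv_scalar(
        sys, n0_1, n0_2, horizon, step, ceiling,
        stop_below=extinction_threshold,
    )
    if div:
        winner = "divergent"
    elif n2 < extinction_threshold <= n1:
        winner = "line1"
    elif n1 < extinction_threshold <= n2:
        winner = "line2"
    elif n1 < extinction_threshold and n2 < extinction_threshold:
        winner = "coexistence"  # joint collapse; treat as no exclusion
    else:
        winner = "coexistence"
    return OutcomeResult(winner, n1, n2, t, start_fraction_line1)


def estimate_separatrix(
    sys: CompetitionSystem,
    lo: float,
    hi: float,
    total_cells: float = 1e5,
    horizon: float = 100.0,
    extinction_threshold: float = 1.0,
    step: float = 0.01,
    tol: float = 1e-3,
) -> float:
    """Bisect the winner flip between starting fractions ``lo`` and ``hi``.

    Assumes the winner at ``lo`` differs from the winner at ``hi`` (the
    bistable regime's single separatrix); returns the flip fraction to
    within ``tol``.
    """
    w_lo = simulate_outcome(sys, lo, total_cells, horizon,
                            extinction_threshold, step).winner
    w_hi = simulate_outcome(sys, hi, total_cells, horizon,
                            extinction_threshold, step).winner
    if w_lo == w_hi:
        raise ValueError("no winner flip between lo and hi")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        w_mid = simulate_outcome(sys, mid, total_cells, horizon,
                                 extinction_threshold, step).winner
        if w_mid == w_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def outcome_map(
    sys: CompetitionSystem,
    fractions,
    total_cells: float = 1e5,
    horizon: float = 100.0,
    extinction_threshold: float = 1.0,
    step: float = 0.01,
) -> dict:
    """Winner per starting fraction, with a separatrix estimate at flips.

    Returns a dict with ``results`` (one OutcomeResult per fraction, in
    order) and ``separatrix`` (the bisected flip fraction, or None when
    the winner never flips between exclusion outcomes).
    """
    fractions = [float(f) for f in fractions]
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    results = [
        simulate_outcome(sys, f, total_cells, horizon, extinction_threshold, step)
        for f in fractions
    ]
    separatrix = None
    f1 = [r.start_fraction_line1 for r in results if r.winner == "line1"]
    f2 = [r.start_fraction_line1 for r in results if r.winner == "line2"]
    if f1 and f2:
        # bracket the flip between the two basins; undecided points right
        # on the separatrix may sit between them and are bisected across
        if max(f2) < min(f1):
            lo, hi = max(f2), min(f1)
        elif max(f1) < min(f2):
            lo, hi = max(f1), min(f2)
        else:  # non-monotone winners: fall back to first adjacent flip
            lo = hi = None
            for a, b in zip(results, results[1:]):
                if {a.winner, b.winner} == {"line1", "line2"}:
                    lo, hi = a.start_fraction_line1, b.start_fraction_line1
                    break
        if lo is not None:
            separatrix = estimate_separatrix(
                sys, lo, hi, total_cells, horizon, extinction_threshold, step,
            )
    return {"results": results, "separatrix": separatrix}
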