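"""Outcome classification of the 2x2 game and the interior equilibrium.

A viable game is classified by the strict sign pattern of
``pi_CC - pi_NC`` and ``pi_CN - pi_NN``:

====================================  =============================
``pi_CC > pi_NC`` and ``pi_CN > pi_NN``  cooperative dominance
``pi_CC < pi_NC`` and ``pi_CN < pi_NN``  non-cooperative dominance
``pi_CC > pi_NC`` and ``pi_CN < pi_NN``  bistability
``pi_CC < pi_NC`` and ``pi_CN > pi_NN``  coexistence
====================================  =============================

Coexistence is sub-labelled cooperative when the interior equilibrium
frequency of cooperators exceeds one half, non-cooperative otherwise.
Non-viable parameter combinations (cost above revenue) are a seventh,
prior outcome: nobody fishes.

The interior equilibrium, where both strategies earn equal fitness, is

    x_bar = (pi_NN - pi_CN) / (pi_CC - pi_CN - pi_NC + pi_NN)

It is the stable rest point of the replicator dynamics under coexistence
and the unstable separatrix under bistability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .errors import DegenerateGameError, NoInteriorEquilibriumError
from .penalty import PayoffMatrix

__all__ = ["OutcomeLabel", "GameOutcome", "classify_outcome", "interior_equilibrium"]

logger = logging.getLogger(__name__)

#: Absolute tolerance below which two compared payoffs count as tied.
TIE_TOL = 1e-12


class OutcomeLabel(str, Enum):
    COOPERATIVE_DOMINANCE = "cooperative_dominance"
    COOPERATIVE_COEXISTENCE = "cooperative_coexistence"
    NONCOOPERATIVE_COEXISTENCE = "noncooperative_coexistence"
    NONCOOPERATIVE_DOMINANCE = "noncooperative_dominance"
    BISTABILITY = "bistability"
    NO_FISHING = "no_fishing"


#: Labels for which an interior equilibrium frequency is defined.
INTERIOR_LABELS = frozenset(
    {
        OutcomeLabel.COOPERATIVE_COEXISTENCE,
        OutcomeLabel.NONCOOPERATIVE_COEXISTENCE,
        OutcomeLabel.BISTABILITY,
    }
)


@dataclass(frozen=True)
class GameOutcome:
    """Classified outcome: label plus interior equilibrium when defined."""

    label: OutcomeLabel
    x_bar: float | None = None

    def __post_init__(self) -> None:
        has_interior = self.label in INTERIOR_LABELS
        if has_interior and self.x_bar is None:
            raise ValueError(f"{self.label.value} requires x_bar")
        if not has_interior and self.x_bar is not None:
            raise ValueError(f"{self.label.value} admits no x_bar")


def interior_equilibrium(matrix: PayoffMatrix) -> float:
    """Frequency of cooperators at which both strategies earn equal fitness.

    Raises
    ------
    NoInteriorEquilibriumError
        If the equal-fitness equation is degenerate (zero denominator,
        e.g. a neutral game).
    """
    den = matrix.pi_CC - matrix.pi_CN - matrix.pi_NC + matrix.pi_NN
    if den == 0.0:
        raise NoInteriorEquilibriumError(
            "payoff differences cancel; no interior equilibrium"
        )
    return (matrix.pi_NN - matrix.pi_CN) / den


def classify_outcome(matrix: PayoffMatrix, viable: bool = True) -> GameOutcome:
    """Classify a payoff matrix into one of the six outcomes.

    Viability is decided first: a non-viable game is ``no_fishing``
    regardless of the matrix (the payoff formulas are undefined there, so
    the caller passes whatever placeholder it has). Comparisons are strict;
    payoffs tied to within :data:`TIE_TOL` raise
    :class:`~fisherygame.errors.DegenerateGameError` rather than being
    silently binned.
    """
    if not viable:
        return GameOutcome(OutcomeLabel.NO_FISHING)

    d_left = matrix.pi_CC - matrix.pi_NC  # payoff edge at all-cooperator end
    d_right = matrix.pi_CN - matrix.pi_NN  # payoff edge at all-cheater end
    if abs(d_left) <= TIE_TOL or abs(d_right) <= TIE_TOL:
        raise DegenerateGameError(
            f"tied payoffs (pi_CC-pi_NC={d_left:.3e}, pi_CN-pi_NN={d_right:.3e}); "
            "outcome undefined"
        )

    if d_left > 0 and d_right > 0:
        return GameOutcome(OutcomeLabel.COOPERATIVE_DOMINANCE)
    if d_left < 0 and d_right < 0:
        return GameOutcome(OutcomeLabel.NONCOOPERATIVE_DOMINANCE)

    x_bar = interior_equilibrium(matrix)
    if d_left > 0 and d_right < 0:
        return GameOutcome(OutcomeLabel.BISTABILITY, x_bar=x_bar)

    # d_left < 0 < d_right: stable coexistence
    if x_bar == 0.5:
        # measure-zero boundary; "cooperative" requires strictly higher freq
        logger.warning("x_bar is exactly 0.5; classified non-cooperative")
    label = (
        OutcomeLabel.COOPERATIVE_COEXISTENCE
        if x_bar > 0.5
        else OutcomeLabel.NONCOOPERATIVE_COEXISTENCE
    )
    return GameOutcome(label, x_bar=x_bar)
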