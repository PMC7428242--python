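"""Behaviour penalty combining control perception, risk tolerance and stock
growth, and its application to the payoff matrix.

The penalty ``delta = alpha / (1 + b*r)`` scales cooperator payoffs, while
``1 - delta`` scales cheater payoffs. ``alpha`` in [0, 1] is the fisher's
perceived certainty of being punished for a violation; ``b`` in [0, 1] is
risk tolerance encoded so that values near 0 mean high tolerance of stock
uncertainty (favouring cooperation) and values near 1 mean low tolerance.
Fast stock turnover (large ``r``) erodes the sense that restraint matters,
so ``delta`` decreases with ``r``: at ``delta = 1`` cheaters are maximally
penalized, at ``delta = 0`` cooperators are.

The two populations may hold different perceptions: cooperator payoffs are
scaled by ``delta_C = delta(alpha1, b1, r)`` and cheater payoffs by
``1 - delta_N`` with ``delta_N = delta(alpha2, b2, r)``; symmetric
parameter choices collapse the two.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bioeconomics import BasePayoffs, BioeconomicParams, StockState, base_payoffs
from .errors import ParameterError

__all__ = [
    "SocialParams",
    "PayoffMatrix",
    "behaviour_penalty",
    "penalized_matrix",
    "build_matrix",
]


@dataclass(frozen=True)
class SocialParams:
    """Per-population control perception and risk tolerance.

    Population 1 is the cooperators, population 2 the cheaters; all four
    values lie in [0, 1]. Use :meth:`symmetric` when both populations share
    the same perception, as in all the reported case-study scenarios.
    """

    alpha1: float
    alpha2: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "b1", "b2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def symmetric(cls, alpha: float, b: float) -> "SocialParams":
        return cls(alpha1=alpha, alpha2=alpha, b1=b, b2=b)

    @property
    def is_symmetric(self) -> bool:
        return self.alpha1 == self.alpha2 and self.b1 == self.b2


@dataclass(frozen=True)
class PayoffMatrix:
    """Penalized payoff matrix of the 2x2 game.

    ``pi_CC``/``pi_CN`` are the cooperator payoffs already scaled by
    ``delta_C``; ``pi_NC``/``pi_NN`` the cheater payoffs scaled by
    ``1 - delta_N``. ``pi_NN`` is identically zero in this model (rent
    dissipation survives any scaling).
    """

    pi_CC: float
    pi_CN: float
    pi_NC: float
    pi_NN: float = 0.0
    delta_C: float = 0.5
    delta_N: float = 0.5

    def __post_init__(self) -> None:
        for name in ("delta_C", "delta_N"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.pi_NN != 0.0:
            raise ParameterError(f"pi_NN must be exactly 0, got {self.pi_NN}")

    @property
    def delta(self) -> float:
        """The penalty value used (cooperator-side; equals the cheater-side
        value in symmetric scenarios)."""
        return self.delta_C


def behaviour_penalty(alpha: float, b: float, r: float) -> float:
    """Behaviour penalty ``delta = alpha / (1 + b*r)``.

    Bounded by ``0 <= delta <= alpha <= 1``; strictly increasing in
    ``alpha``, strictly decreasing in ``b`` and ``r`` whenever the other
    is positive.
    """
    if not 0 <= alpha <= 1:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    if not 0 <= b <= 1:
        raise ParameterError(f"b must be in [0, 1], got {b}")
    if not r >= 0:
        raise ParameterError(f"r must be non-negative, got {r}")
    return alpha / (1.0 + b * r)


def penalized_matrix(
    base: BasePayoffs, delta: float, delta_N: float | None = None
) -> PayoffMatrix:
    """Apply the behaviour penalty to unpenalized payoffs.

    Cooperator payoffs are multiplied by ``delta``, cheater payoffs by
    ``1 - delta_N`` (``delta_N`` defaults to ``delta``, the symmetric
    case). ``pi_NN`` stays zero for every penalty value.
    """
    if delta_N is None:
        delta_N = delta
    if not 0 <= delta <= 1:
        raise ParameterError(f"delta must be in [0, 1], got {delta}")
    if not 0 <= delta_N <= 1:
        raise ParameterError(f"delta_N must be in [0, 1], got {delta_N}")
    return PayoffMatrix(
        pi_CC=delta * base.Pi_CC,
        pi_CN=delta * base.Pi_CN,
        pi_NC=(1.0 - delta_N) * base.Pi_NC,
        pi_NN=(1.0 - delta_N) * base.Pi_NN,
        delta_C=delta,
        delta_N=delta_N,
    )


def build_matrix(
    econ: BioeconomicParams,
    state: StockState,
    social: SocialParams,
    disable_penalty: bool = False,
) -> PayoffMatrix:
    """Full pipeline: base payoffs for the stock state, then the penalty.

    ``disable_penalty=True`` fixes ``delta = 1 - delta = 0.5`` for both
    roles, removing the control/risk effects so that both strategies are
    scaled equally (the model's base state).

    Raises
    ------
    NotViableError
        If fishing is not viable at this stock state.
    """
    base = base_payoffs(econ, state)
    if disable_penalty:
        return penalized_matrix(base, 0.5)
    d_C = behaviour_penalty(social.alpha1, social.b1, state.r)
    d_N = behaviour_penalty(social.alpha2, social.b2, state.r)
    return penalized_matrix(base, d_C, d_N)
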