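"""Normalized Gordon-style economics of a single-species, effort-restricted
fishery.

The stock is a single species whose within-season removals follow the
classic exponential-mortality harvest relation ``H = B * (1 - exp(-q*f))``
(natural mortality folded out, season length one). All monetary quantities
are expressed per unit carrying capacity: stock biomass ``B`` and the raw
effort cost ``c`` are divided by the carrying capacity ``K``, giving the
relative stock size ``B' = B/K`` in (0, 1] and the normalized effort cost
``c' = c/K``. Results are then independent of the absolute stock scale.

Two fisher populations interact:

* **cooperators** fish the legally regulated effort ``f*``;
* **cheaters** fish to maximize individual season profit, which drives the
  total effort to the monopoly (profit-maximizing) level
  ``f_T = ln(B'*P*q / c') / q``.

Each pairwise encounter type has an unpenalized season profit per unit
carrying capacity (:class:`BasePayoffs`). When two cheaters meet they race
for the stock and dissipate the entire rent, so their payoff is exactly
zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import DegenerateEncounterWarning, NotViableError, ParameterError

__all__ = [
    "BioeconomicParams",
    "StockState",
    "BasePayoffs",
    "harvest",
    "is_viable",
    "monopoly_effort",
    "base_payoffs",
    "normalize",
]


@dataclass(frozen=True)
class BioeconomicParams:
    """Fixed economic and gear constants of the fishery.

    Parameters
    ----------
    P : float
        Market price per unit biomass (currency / kg).
    q : float
        Catchability: fraction of the stock removed per unit effort,
        in (0, 1).
    c_prime : float
        Cost of one effort unit per unit carrying capacity
        (currency / (effort * kg)), i.e. ``c' = c / K``.
    f_star : float
        Regulated fishing effort (effort units, e.g. nets).
    K : float, optional
        Carrying capacity (kg). Only needed to normalize raw ``c`` and
        ``B``; the model itself works on normalized quantities.

    Defaults are the Laguna (southern Brazil) shrimp fyke-net case study:
    ``P = 23``, ``q = 0.023``, ``c' = 2e-5``, ``f* = 18``.
    """

    P: float = 23.0
    q: float = 0.023
    c_prime: float = 2e-5
    f_star: float = 18.0
    K: float | None = None

    def __post_init__(self) -> None:
        if not self.P > 0:
            raise ParameterError(f"P must be positive, got {self.P}")
        if not 0 < self.q < 1:
            raise ParameterError(f"q must be in (0, 1), got {self.q}")
        if not self.c_prime > 0:
            raise ParameterError(f"c_prime must be positive, got {self.c_prime}")
        if not self.f_star > 0:
            raise ParameterError(f"f_star must be positive, got {self.f_star}")
        if self.K is not None and not self.K > 0:
            raise ParameterError(f"K must be positive when given, got {self.K}")


@dataclass(frozen=True)
class StockState:
    """Stock state for one game: relative size and growth rate.

    ``B_prime`` is the relative stock size ``B/K`` in (0, 1]; ``r`` is the
    intrinsic (logistic) growth rate per season, non-negative.
    """

    B_prime: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.B_prime <= 1:
            raise ParameterError(f"B_prime must be in (0, 1], got {self.B_prime}")
        if not self.r >= 0:
            raise ParameterError(f"r must be non-negative, got {self.r}")


@dataclass(frozen=True)
class BasePayoffs:
    """Unpenalized season profit per unit carrying capacity by encounter role.

    ``Pi_XY`` is the profit of an individual from population X meeting an
    individual from population Y (C = cooperator, N = non-cooperator).
    ``Pi_NN`` is identically zero (rent dissipation in the fishing race).
    ``degenerate`` flags the clipped case where the regulated effort already
    meets or exceeds the profit-maximizing total effort.
    """

    Pi_CC: float
    Pi_CN: float
    Pi_NC: float
    Pi_NN: float = 0.0
    degenerate: bool = field(default=False, compare=False)


def harvest(B_prime: float, q: float, f: float) -> float:
    """Biomass fraction harvested by effort ``f`` from relative stock ``B_prime``.

    Implements ``H = B' * (1 - exp(-q*f))``: strictly increasing and concave
    in effort, never exceeding the available stock.
    """
    if B_prime < 0:
        raise ParameterError(f"biomass must be non-negative, got {B_prime}")
    if f < 0:
        raise ParameterError(f"effort must be non-negative, got {f}")
    if not q > 0:
        raise ParameterError(f"catchability must be positive, got {q}")
    return B_prime * (1.0 - math.exp(-q * f))


def is_viable(params: BioeconomicParams, state: StockState) -> bool:
    """Whether fishing is economically viable: ``c' < B' * P * q``.

    Below this threshold the marginal revenue of the very first effort unit
    is already below its cost, so no rational agent fishes.
    """
    return params.c_prime < state.B_prime * params.P * params.q


def monopoly_effort(params: BioeconomicParams, state: StockState) -> float:
    """Profit-maximizing total effort ``f_T = -ln(rho)/q``, ``rho = c'/(B'Pq)``.

    This is the unique effort solving the first-order condition
    ``B'*P*q*exp(-q*f) = c'`` for the single-agent season profit
    ``B'*(1 - exp(-q*f))*P - c'*f``; a cheater drives total effort to it.

    Raises
    ------
    NotViableError
        If ``c' >= B'*P*q`` (no positive effort is profitable).
    """
    if not is_viable(params, state):
        raise NotViableError(
            f"fishing not viable: c'={params.c_prime} >= "
            f"B'*P*q={state.B_prime * params.P * params.q}"
        )
    rho = params.c_prime / (state.B_prime * params.P * params.q)
    return -math.log(rho) / params.q


def base_payoffs(params: BioeconomicParams, state: StockState) -> BasePayoffs:
    """Unpenalized payoffs for the four encounter types.

    With ``rho = c'/(B'Pq)`` and ``L = ln(rho) < 0`` when viable:

    * ``Pi_CC = B'(1 - e^(-q f*)) P - c' f*`` — both cooperators fish ``f*``;
    * ``Pi_CN = (c' - B'Pq) f*/L - c' f*`` — the cooperator's proportional
      share ``f*/f_T`` of the total-harvest revenue ``B'(1 - rho) P`` minus
      own cost;
    * ``Pi_NC = ((L + q f*)/L) B'(1 - rho) P - c'(f_T - f*)`` — the
      cheater's complementary revenue share minus the cheater's cost for
      effort ``f_T - f*``;
    * ``Pi_NN = 0`` — rent dissipation.

    In a mixed encounter the cheater expands total effort to ``f_T`` and
    revenue is split proportionally to contributed effort, so cooperator
    plus cheater revenue equals ``B'(1 - rho) P`` exactly.

    If ``f* >= f_T`` the cheater's effort is clipped at zero: the encounter
    is evaluated at total effort ``f*`` (``Pi_CN = Pi_CC``, ``Pi_NC = 0``)
    and flagged degenerate.

    Raises
    ------
    NotViableError
        If fishing is not viable (``c' >= B'Pq``).
    """
    if not is_viable(params, state):
        raise NotViableError(
            f"fishing not viable at B'={state.B_prime}: payoffs undefined"
        )
    P, q, cp, fs = params.P, params.q, params.c_prime, params.f_star
    Bp = state.B_prime
    rho = cp / (Bp * P * q)
    L = math.log(rho)
    f_T = -L / q

    Pi_CC = Bp * (1.0 - math.exp(-q * fs)) * P - cp * fs

    if f_T <= fs:
        warnings.warn(
            f"regulated effort f*={fs} >= profit-maximizing effort "
            f"f_T={f_T:.6g}; cheater effort clipped to zero",
            DegenerateEncounterWarning,
            stacklevel=2,
        )
        return BasePayoffs(Pi_CC=Pi_CC, Pi_CN=Pi_CC, Pi_NC=0.0, degenerate=True)

    Pi_CN = (cp - Bp * P * q) * fs / L - cp * fs
    Pi_NC = ((L + q * fs) / L) * Bp * (1.0 - rho) * P - cp * (f_T - fs)
    return BasePayoffs(Pi_CC=Pi_CC, Pi_CN=Pi_CN, Pi_NC=Pi_NC)


def normalize(c: float, B: float, K: float) -> tuple[float, float]:
    """Normalize raw cost and biomass by carrying capacity.

    Returns ``(c' = c/K, B' = B/K)``. Payoffs computed from normalized
    quantities equal ``1/K`` times the un-normalized payoffs, which is what
    makes the model independent of absolute stock scale.
    """
    if not K > 0:
        raise ParameterError(f"K must be positive, got {K}")
    if c < 0:
        raise ParameterError(f"cost must be non-negative, got {c}")
    if not 0 <= B <= K:
        raise ParameterError(f"B must be in [0, K]={K}, got {B}")
    return c / K, B / K
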