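"""Scenario machinery: outcome grids over (r, B'), equilibrium-frequency
curves, and critical growth rates separating outcome regions.

A scenario fixes the economics and the social parameters and scans the
stock growth rate ``r`` (default 0 to 2, step 0.01) and the relative stock
size ``B'`` (default 0.01 to 1, step 0.01). Each grid cell is an
independent game: build the base payoffs, apply the behaviour penalty,
classify. Because the base payoffs depend only on ``B'`` and the penalty
only on ``r``, the outcome boundaries along ``r`` solve closed-form sign
conditions and are refined by bracketed root finding rather than read off
the grid:

* dominance <-> coexistence: ``delta_C * Pi_CC = (1 - delta_N) * Pi_NC``;
* cooperative <-> non-cooperative coexistence: ``x_bar(r) = 0.5``.

Aggregating a boundary over the whole ``B'`` grid supports two readings
(``scope``): the largest ``r`` at which *every* viable column is still on
the cooperative side (``"every"`` — the point where the first
non-cooperative cell appears anywhere), or the largest ``r`` at which *any*
column still is (``"any"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bioeconomics import BasePayoffs, BioeconomicParams, StockState, base_payoffs, is_viable
from .errors import NoBoundaryError, ParameterError
from .game_analysis import OutcomeLabel, classify_outcome, interior_equilibrium
from .penalty import SocialParams, behaviour_penalty, penalized_matrix

__all__ = [
    "ScenarioConfig",
    "SweepResult",
    "default_r_grid",
    "default_B_grid",
    "sweep_scenario",
    "boundary_r",
    "band_boundary",
    "frequency_curves",
]

logger = logging.getLogger(__name__)

#: Transitions out of the cooperative-dominance region.
_DOMINANCE_PAIRS = {
    frozenset({OutcomeLabel.COOPERATIVE_DOMINANCE, OutcomeLabel.COOPERATIVE_COEXISTENCE}),
    frozenset({OutcomeLabel.COOPERATIVE_DOMINANCE, OutcomeLabel.NONCOOPERATIVE_COEXISTENCE}),
}
_COEXISTENCE_PAIR = frozenset(
    {OutcomeLabel.COOPERATIVE_COEXISTENCE, OutcomeLabel.NONCOOPERATIVE_COEXISTENCE}
)


def default_r_grid() -> np.ndarray:
    """Growth rate 0..2 in steps of 0.01 (201 points)."""
    return np.round(np.linspace(0.0, 2.0, 201), 10)


def default_B_grid() -> np.ndarray:
    """Relative stock size 0.01..1.00 in steps of 0.01 (100 points)."""
    return np.round(np.linspace(0.01, 1.0, 100), 10)


@dataclass(frozen=True, eq=False)
class ScenarioConfig:
    """A sweep scenario: social parameters, economics and the two grids."""

    social: SocialParams
    econ: BioeconomicParams = field(default_factory=BioeconomicParams)
    r_grid: np.ndarray = field(default_factory=default_r_grid)
    B_grid: np.ndarray = field(default_factory=default_B_grid)
    name: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_grid, dtype=float)
        B = np.asarray(self.B_grid, dtype=float)
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "B_grid", B)
        if r.size == 0 or B.size == 0:
            raise ParameterError("grids must be non-empty")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(B) <= 0):
            raise ParameterError("grids must be strictly increasing")
        if r[0] < 0 or r[-1] > 2:
            raise ParameterError(f"r_grid must lie in [0, 2], got [{r[0]}, {r[-1]}]")
        if B[0] <= 0 or B[-1] > 1:
            raise ParameterError(f"B_grid must lie in (0, 1], got [{B[0]}, {B[-1]}]")


@dataclass(frozen=True, eq=False)
class SweepResult:
    """Grid of classified outcomes; one record per (r, B') cell."""

    records: pd.DataFrame
    config: ScenarioConfig

    def outcome_counts(self) -> pd.Series:
        return self.records["label"].value_counts()


def _deltas(social: SocialParams, r: float) -> tuple[float, float]:
    return (
        behaviour_penalty(social.alpha1, social.b1, r),
        behaviour_penalty(social.alpha2, social.b2, r),
    )


def sweep_scenario(config: ScenarioConfig, disable_penalty: bool = False) -> SweepResult:
    """Classify every (r, B') grid cell of the scenario.

    Deterministic: identical configs yield identical result tables.
    ``disable_penalty`` fixes delta at 0.5 for both roles (control/risk
    effects removed). Cells where fishing is not viable are labelled
    ``no_fishing``.
    """
    rows = []
    for B in config.B_grid:
        state0 = StockState(B_prime=float(B), r=0.0)
        viable = is_viable(config.econ, state0)
        base = base_payoffs(config.econ, state0) if viable else None
        for r in config.r_grid:
            if disable_penalty:
                d_C = d_N = 0.5
            else:
                d_C, d_N = _deltas(config.social, float(r))
            if not viable:
                rows.append((float(r), float(B), d_C, d_N, False,
                             OutcomeLabel.NO_FISHING.value, np.nan))
                continue
            matrix = penalized_matrix(base, d_C, d_N)
            outcome = classify_outcome(matrix, viable=True)
            rows.append((
                float(r), float(B), d_C, d_N, True,
                outcome.label.value,
                np.nan if outcome.x_bar is None else outcome.x_bar,
            ))
    records = pd.DataFrame(
        rows,
        columns=["r", "B_prime", "delta_C", "delta_N", "viable", "label", "x_bar"],
    )
    result = SweepResult(records=records, config=config)
    counts = result.outcome_counts()
    logger.info(
        "sweep %s: %d x %d grid, outcome counts: %s",
        config.name or "<unnamed>",
        config.r_grid.size,
        config.B_grid.size,
        counts.to_dict(),
    )
    return result


def _dominance_gap(r: float, base: BasePayoffs, social: SocialParams) -> float:
    """Positive inside the cooperative-dominance region."""
    d_C, d_N = _deltas(social, r)
    return d_C * base.Pi_CC - (1.0 - d_N) * base.Pi_NC


def _xbar_gap(r: float, base: BasePayoffs, social: SocialParams) -> float:
    """x_bar - 0.5; positive on the cooperative side of the coexistence band."""
    d_C, d_N = _deltas(social, r)
    return interior_equilibrium(penalized_matrix(base, d_C, d_N)) - 0.5


def _column_crossing(
    config: ScenarioConfig,
    transition: frozenset,
    B_prime: float,
    xtol: float,
) -> tuple[str, float]:
    """Critical r for one viable B' column.

    Returns ``(status, value)`` with status ``"crossing"`` (value is the
    refined root), ``"below_range"`` (the column is already past the
    transition at the bottom of the r range; value is that bottom) or
    ``"above_range"`` (the column never reaches the transition; value is
    the top of the range).
    """
    state = StockState(B_prime=B_prime, r=0.0)
    base = base_payoffs(config.econ, state)
    r_lo, r_hi = float(config.r_grid[0]), float(config.r_grid[-1])

    if transition in _DOMINANCE_PAIRS:
        g = lambda r: _dominance_gap(r, base, config.social)
        lo = r_lo
    elif transition == _COEXISTENCE_PAIR:
        # x_bar is meaningful only past the dominance boundary: start there.
        g = lambda r: _xbar_gap(r, base, config.social)
        if _dominance_gap(r_lo, base, config.social) > 0:
            status, r_dom = _column_crossing(
                config,
                frozenset({OutcomeLabel.COOPERATIVE_DOMINANCE,
                           OutcomeLabel.COOPERATIVE_COEXISTENCE}),
                B_prime,
                xtol,
            )
            if status == "above_range":  # dominance throughout
                return "above_range", r_hi
            lo = r_dom + xtol
            if g(lo) <= 0:
                # no cooperative-coexistence band: the column leaves the
                # cooperative side at its dominance boundary
                return "crossing", r_dom
        else:
            lo = r_lo
    else:
        raise NoBoundaryError(
            f"unsupported transition {sorted(l.value for l in transition)}"
        )

    if g(lo) <= 0:
        return "below_range", r_lo
    if g(r_hi) > 0:
        return "above_range", r_hi
    return "crossing", float(brentq(g, lo, r_hi, xtol=xtol))


def boundary_r(
    config: ScenarioConfig,
    transition: tuple[OutcomeLabel, OutcomeLabel],
    B_prime: float,
    xtol: float = 1e-6,
) -> float:
    """Critical growth rate where the outcome changes along one B' column.

    ``transition`` names the two adjacent outcome labels, e.g.
    ``(COOPERATIVE_DOMINANCE, COOPERATIVE_COEXISTENCE)`` or
    ``(COOPERATIVE_COEXISTENCE, NONCOOPERATIVE_COEXISTENCE)``. The
    underlying sign condition is solved by bracketed bisection to ``xtol``.

    Raises
    ------
    NoBoundaryError
        If the transition does not occur along the scanned r interval, or
        fishing is not viable at this B'.
    """
    pair = frozenset(OutcomeLabel(t) for t in transition)
    if len(pair) != 2:
        raise NoBoundaryError("transition must name two distinct labels")
    state = StockState(B_prime=float(B_prime), r=0.0)
    if not is_viable(config.econ, state):
        raise NoBoundaryError(f"fishing not viable at B'={B_prime}")
    status, value = _column_crossing(config, pair, float(B_prime), xtol)
    if status != "crossing":
        raise NoBoundaryError(
            f"transition {sorted(l.value for l in pair)} does not occur at "
            f"B'={B_prime} within the r range ({status})"
        )
    return value


def band_boundary(
    config: ScenarioConfig,
    transition: tuple[OutcomeLabel, OutcomeLabel],
    scope: str = "every",
    xtol: float = 1e-6,
) -> float:
    """Boundary growth rate aggregated over the whole B' grid.

    ``scope="every"``: largest r at which every viable column is still on
    the cooperative ("from") side — equivalently, where the first cell of
    the "to" outcome appears anywhere on the grid (minimum of the
    per-column boundaries). ``scope="any"``: largest r at which at least
    one viable column remains on the "from" side (maximum).

    Columns that never leave the "from" side within the r range contribute
    the top of the range; columns already past the transition at the bottom
    contribute the bottom.

    Raises
    ------
    NoBoundaryError
        If no column is viable or no column ever exhibits the transition.
    """
    if scope not in ("every", "any"):
        raise ParameterError(f"scope must be 'every' or 'any', got {scope!r}")
    pair = frozenset(OutcomeLabel(t) for t in transition)
    bounds = []
    crossed = False
    for B in config.B_grid:
        state = StockState(B_prime=float(B), r=0.0)
        if not is_viable(config.econ, state):
            continue
        status, value = _column_crossing(config, pair, float(B), xtol)
        bounds.append(value)
        crossed = crossed or status == "crossing"
    if not bounds:
        raise NoBoundaryError("no viable B' column in the grid")
    if not crossed:
        raise NoBoundaryError(
            f"transition {sorted(l.value for l in pair)} never occurs on the grid"
        )
    return float(min(bounds) if scope == "every" else max(bounds))


def frequency_curves(config: ScenarioConfig) -> pd.DataFrame:
    """Equilibrium cooperator frequency versus growth rate, per B'.

    Returns a long-format frame with columns ``r``, ``B_prime``, ``x_bar``:
    the interior equilibrium where coexistence holds, 1.0 where cooperation
    dominates, and NaN elsewhere (no-fishing or non-cooperative dominance).
    """
    records = sweep_scenario(config).records.copy()
    x = records["x_bar"].to_numpy()
    label = records["label"].to_numpy()
    x = np.where(label == OutcomeLabel.COOPERATIVE_DOMINANCE.value, 1.0, x)
    keep = ~np.isin(
        label,
        [
            OutcomeLabel.COOPERATIVE_COEXISTENCE.value,
            OutcomeLabel.NONCOOPERATIVE_COEXISTENCE.value,
            OutcomeLabel.COOPERATIVE_DOMINANCE.value,
        ],
    )
    x = np.where(keep, np.nan, x)
    records["x_bar"] = x
    return records[["r", "B_prime", "x_bar"]]
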