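"""Continuous-time replicator dynamics on the two-strategy frequency simplex.

With cooperator frequency ``x`` (and cheater frequency ``1 - x``) the
population evolves by

    dx/dt = x * (1 - x) * [fit_C(x) - fit_N(x)]

where ``fit_C = x*pi_CC + (1-x)*pi_CN`` and ``fit_N = x*pi_NC +
(1-x)*pi_NN`` are the expected (fitness) payoffs of the two strategies
under random encounters. Generations map one-to-one onto integration time
units. The dynamics are one-dimensional and smooth, so a deterministic
fixed-step fourth-order Runge-Kutta scheme (default step 0.01) is used,
with early stopping once ``|dx/dt|`` falls below tolerance and clipping of
round-off excursions outside [0, 1]. The inner loop is JIT-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .bioeconomics import BioeconomicParams, StockState, is_viable
from .errors import IntegrationError, ParameterError
from .game_analysis import GameOutcome, classify_outcome
from .penalty import PayoffMatrix, SocialParams, build_matrix

__all__ = [
    "Trajectory",
    "InvasionResult",
    "fitnesses",
    "replicator_rhs",
    "integrate",
    "run_invasion",
]

#: Distance from a simplex boundary below which a trajectory counts as absorbed.
BOUNDARY_TOL = 1e-12

#: Looser boundary proximity used only to summarize an invasion's fate: a
#: run stopped by the |dx/dt| tolerance parks ~tol/rate away from the
#: boundary it converges to, not within round-off of it.
FATE_BOUNDARY_TOL = 1e-6


def fitnesses(x_C: float, matrix: PayoffMatrix) -> tuple[float, float]:
    """Expected payoffs ``(fit_C, fit_N)`` at cooperator frequency ``x_C``."""
    if not 0 <= x_C <= 1:
        raise ParameterError(f"x_C must be in [0, 1], got {x_C}")
    x_N = 1.0 - x_C
    fit_C = x_C * matrix.pi_CC + x_N * matrix.pi_CN
    fit_N = x_C * matrix.pi_NC + x_N * matrix.pi_NN
    return fit_C, fit_N


def replicator_rhs(x_C: float, matrix: PayoffMatrix) -> float:
    """Rate of change ``dx_C/dt`` of the cooperator frequency."""
    fit_C, fit_N = fitnesses(x_C, matrix)
    return x_C * (1.0 - x_C) * (fit_C - fit_N)


@njit(cache=True)
def _rhs(x, g_cc, g_cn):  # pragma: no cover - exercised through _rk4
    # g_cc = pi_CC - pi_NC, g_cn = pi_CN - pi_NN: fitness gap is linear in x
    return x * (1.0 - x) * (x * g_cc + (1.0 - x) * g_cn)


@njit(cache=True)
def _rk4(x0, g_cc, g_cn, dt, n_steps, tol, record_every):
    n_rec = n_steps // record_every + 2
    times = np.empty(n_rec)
    xs = np.empty(n_rec)
    times[0] = 0.0
    xs[0] = x0
    n_saved = 1
    x = x0
    t = 0.0
    converged = abs(_rhs(x, g_cc, g_cn)) < tol
    if not converged:
        for i in range(1, n_steps + 1):
            k1 = _rhs(x, g_cc, g_cn)
            k2 = _rhs(x + 0.5 * dt * k1, g_cc, g_cn)
            k3 = _rhs(x + 0.5 * dt * k2, g_cc, g_cn)
            k4 = _rhs(x + dt * k3, g_cc, g_cn)
            x = x + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            if x < 0.0:
                x = 0.0
            elif x > 1.0:
                x = 1.0
            t = i * dt
            if i % record_every == 0:
                times[n_saved] = t
                xs[n_saved] = x
                n_saved += 1
            if x <= 1e-12:
                x = 0.0
                converged = True
            elif x >= 1.0 - 1e-12:
                x = 1.0
                converged = True
            elif abs(_rhs(x, g_cc, g_cn)) < tol:
                converged = True
            if converged:
                break
    if times[n_saved - 1] != t:
        times[n_saved] = t
        xs[n_saved] = x
        n_saved += 1
    xs[n_saved - 1] = x
    return times[:n_saved], xs[:n_saved], converged, x


@dataclass(frozen=True)
class Trajectory:
    """Time course of the cooperator frequency.

    ``x_N`` is never stored; it is ``1 - x_C`` by construction.
    """

    times: np.ndarray
    x_C: np.ndarray
    converged: bool
    x_final: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "x_C": self.x_C})


def integrate(
    x0: float,
    matrix: PayoffMatrix,
    horizon: float = 1e4,
    dt: float = 0.01,
    tol: float = 1e-10,
    record_every: int | None = None,
) -> Trajectory:
    """Integrate the replicator equation from ``x0`` for up to ``horizon``
    time units (generations).

    Stops early once ``|dx/dt| < tol`` or the trajectory is absorbed at a
    boundary (within 1e-12 of 0 or 1). ``record_every`` thins the stored
    trajectory (every n-th step); by default it is chosen to keep at most
    ~10000 stored points.
    """
    if not 0 <= x0 <= 1:
        raise ParameterError(f"x0 must be in [0, 1], got {x0}")
    if not horizon > 0 or not dt > 0:
        raise ParameterError("horizon and dt must be positive")
    for v in (matrix.pi_CC, matrix.pi_CN, matrix.pi_NC, matrix.pi_NN):
        if not math.isfinite(v):
            raise IntegrationError(f"non-finite payoff {v} in matrix")

    n_steps = int(math.ceil(horizon / dt))
    if record_every is None:
        record_every = max(1, n_steps // 10_000)
    g_cc = matrix.pi_CC - matrix.pi_NC
    g_cn = matrix.pi_CN - matrix.pi_NN
    times, xs, converged, x_final = _rk4(
        float(x0), g_cc, g_cn, float(dt), n_steps, float(tol), int(record_every)
    )
    return Trajectory(times=times, x_C=xs, converged=bool(converged), x_final=float(x_final))


@dataclass(frozen=True)
class InvasionResult:
    """Outcome of an invasion experiment.

    ``invades`` is true when the cooperative strategy ends above its
    initial frequency; ``fate`` summarizes the terminal state:
    ``"fixed"`` (absorbed at 1), ``"extinct"`` (absorbed at 0) or
    ``"interior"``.
    """

    trajectory: Trajectory
    matrix: PayoffMatrix
    outcome: GameOutcome
    x0: float
    invades: bool
    fate: str


def run_invasion(
    econ: BioeconomicParams,
    state: StockState,
    social: SocialParams,
    x0: float = 0.10,
    **integrate_kwargs,
) -> InvasionResult:
    """Simulate a small cooperative population invading a resident
    non-cooperative one (default invader frequency 10%).

    Builds the penalized payoff matrix for the scenario, integrates the
    replicator dynamics and reports whether cooperation invades, is
    repelled, or stabilizes at an interior frequency.
    """
    matrix = build_matrix(econ, state, social)  # raises NotViableError
    outcome = classify_outcome(matrix, viable=is_viable(econ, state))
    traj = integrate(x0, matrix, **integrate_kwargs)
    xf = traj.x_final
    if xf >= 1.0 - FATE_BOUNDARY_TOL:
        fate = "fixed"
    elif xf <= FATE_BOUNDARY_TOL:
        fate = "extinct"
    else:
        fate = "interior"
    return InvasionResult(
        trajectory=traj,
        matrix=matrix,
        outcome=outcome,
        x0=x0,
        invades=xf > x0,
        fate=fate,
    )
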