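"""Deterministic competitive Lotka-Volterra dynamics.

For abundances ``x_i`` the community obeys

    dx_i/dT = (lambda_b - lambda_d) x_i - x_i * sum_j d_ij x_j,

with ``d_ij = alpha + exp(-A_ij)``. This module provides the right-hand
side, an adaptive integrator, and an ODE-based oracle for the two-type
outcome that must agree with the sign-pattern classifier
:func:`cyclodom.payoff_core.classify_pair`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .payoff_core import ModelParams, PairClass, death_rate_matrix

__all__ = ["LvSystem", "LvTrajectory", "lv_rhs", "integrate_lv", "two_type_outcome_by_ode"]

#: abundances below this fraction of total density count as extinct
EXTINCTION_FRACTION = 1e-9
#: relative tolerance of the adaptive integrator
RTOL = 1e-8


@dataclass(frozen=True)
class LvSystem:
    """Competition death-rate matrix plus demographic rates."""

    d: np.ndarray
    lambda_b: float
    lambda_d: float

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.d, dtype=float))
        object.__setattr__(self, "d", d)
        if d.shape[0] != d.shape[1]:
            raise ValueError(f"d must be square, got {d.shape}")
        if not np.all(d > 0):
            raise ValueError("all competition death rates must be positive")
        if not self.lambda_b > self.lambda_d:
            raise ValueError("require lambda_b > lambda_d")

    @classmethod
    def from_payoffs(cls, A: np.ndarray, params: ModelParams) -> "LvSystem":
        return cls(death_rate_matrix(A, params.alpha), params.lambda_b, params.lambda_d)

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def carrying_capacity(self, i: int) -> float:
        """Single-type equilibrium ``(lambda_b - lambda_d) / d_ii``."""
        return (self.lambda_b - self.lambda_d) / self.d[i, i]


@dataclass(frozen=True)
class LvTrajectory:
    times: np.ndarray
    x: np.ndarray  # (len(times), n)
    converged: bool
    extinct: np.ndarray  # bool per type, at the terminal state


def lv_rhs(x: np.ndarray, sys: LvSystem) -> np.ndarray:
    """Time derivative of the abundance vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (sys.n,):
        raise ValueError(f"abundance vector shape {x.shape} != ({sys.n},)")
    return (sys.lambda_b - sys.lambda_d) * x - x * (sys.d @ x)


def integrate_lv(
    sys: LvSystem,
    x0: np.ndarray,
    horizon: float,
    tol: float = RTOL,
) -> LvTrajectory:
    """Integrate to ``horizon`` with an adaptive explicit scheme.

    ``converged`` is set when the terminal relative derivative norm is small
    (an equilibrium was reached); non-convergence is flagged, never raised.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(
        lambda _t, x: lv_rhs(np.maximum(x, 0.0), sys),
        (0.0, horizon),
        x0,
        method="LSODA",
        rtol=tol,
        atol=tol * max(1.0, float(np.max(x0))),
    )
    x = np.maximum(sol.y.T, 0.0)
    xf = x[-1]
    scale = max(float(np.sum(xf)), 1e-300)
    converged = bool(np.linalg.norm(lv_rhs(xf, sys)) <= 1e-6 * scale)
    extinct = xf < EXTINCTION_FRACTION * scale
    return LvTrajectory(sol.t, x, converged, extinct)


#: an abundance fraction above this counts as clearly persistent
SETTLED_FRACTION = 1e-4


def _asymptotic_alive(
    sys: LvSystem, x0: np.ndarray, horizon: float, max_chunks: int = 8
) -> np.ndarray:
    """Integrate in growing chunks until every type is clearly extinct or
    clearly persistent; marginal invasion rates just mean more time."""
    x = x0
    h = horizon
    for _ in range(max_chunks):
        traj = integrate_lv(sys, x, h)
        x = traj.x[-1]
        frac = x / max(float(x.sum()), 1e-300)
        settled = (frac < EXTINCTION_FRACTION) | (frac > SETTLED_FRACTION)
        if traj.converged and settled.all():
            return frac > SETTLED_FRACTION
        h *= 4.0
    raise RuntimeError("ODE oracle did not settle; outcome indeterminate")


def two_type_outcome_by_ode(
    aii: float,
    aij: float,
    aji: float,
    ajj: float,
    params: ModelParams,
    horizon: float = 2000.0,
) -> PairClass:
    """Two-type outcome decided by integrating the ODE, not by sign rules.

    Integrates from a grid of initial fractions of the single-type
    carrying capacities, including tiny-invader starts (fraction 1e-6)
    that probe the local stability of each single-type state — a bistable
    pair can have a basin far thinner than any percent-scale start. All
    starts fixing the same type -> dominance; start-dependent winner ->
    bistable; a surviving interior state -> coexistence. Near-degenerate
    payoffs that do not settle raise ``RuntimeError`` (an indeterminate
    flag, never a silently wrong class).
    """
    A = np.array([[aii, aij], [aji, ajj]], dtype=float)
    sys = LvSystem.from_payoffs(A, params)
    k = np.array([sys.carrying_capacity(0), sys.carrying_capacity(1)])
    outcomes = []
    for f in (1.0 - 1e-6, 0.99, 0.5, 0.01, 1e-6):
        x0 = np.array([f * k[0], (1.0 - f) * k[1]])
        alive = _asymptotic_alive(sys, x0, horizon)
        if alive.all():
            outcomes.append("both")
        elif alive[0]:
            outcomes.append("first")
        elif alive[1]:
            outcomes.append("second")
        else:
            raise RuntimeError("both types extinct in ODE oracle")
    if "first" in outcomes and "second" in outcomes:
        # a symmetric middle start may sit on the saddle's stable manifold
        # and report "both"; opposite winners from the extremes decide it
        return PairClass.BISTABLE
    if all(o == "both" for o in outcomes):
        return PairClass.COEXIST
    if all(o == "first" for o in outcomes):
        return PairClass.DOM_FIRST
    if all(o == "second" for o in outcomes):
        return PairClass.DOM_SECOND
    raise RuntimeError(f"mixed ODE outcomes {outcomes}; indeterminate")
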