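"""Exact stochastic simulation of the individual-based dynamics.

Reactions (per individual of type ``i``, with ``x_j`` copies of type ``j``):

* clonal birth at rate ``lambda_b (1 - mu) x_i``
* mutant birth at rate ``lambda_b mu x_i`` (the offspring is a new type
  with inherited-plus-noise payoffs; the mutation-event clock advances)
* background death at rate ``lambda_d x_i``
* competition death at rate ``d_ij x_i x_j`` for ``j != i`` and
  ``d_ii x_i (x_i - 1)`` within a type (an individual cannot kill itself)

The direct (exact) Gillespie method is used. Mutation is resolved at
birth: a birth event is drawn at total rate ``lambda_b x_i`` and the
newborn is a mutant with probability ``mu`` — the same factorization of
the rates, with one fewer reaction channel to book-keep.

Time ``t`` of all analyses is the cumulative number of mutation events;
continuous reaction time is accumulated separately as ``wall_time``.
A snapshot of the population (abundances plus payoff matrix) is recorded
at every mutation event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .payoff_core import (
    ModelParams,
    PayoffMatrix,
    death_rate_matrix,
    mutate_payoffs,
    remove_types,
)

__all__ = [
    "ExtinctError",
    "PopulationState",
    "Snapshot",
    "RunResult",
    "initial_state",
    "event_rates",
    "step",
    "run",
]

INITIAL_PAYOFF_MEAN = np.log(1000.0)  # mean of the founder's self-payoff
INITIAL_PAYOFF_SD = 1.0


class ExtinctError(RuntimeError):
    """Raised when a reaction is requested from an empty population."""


@dataclass
class PopulationState:
    """Mutable simulation state.

    ``abundances`` is aligned with ``matrix.type_ids``; ``d`` caches the
    competition death-rate matrix and is refreshed whenever the payoff
    matrix changes. ``genealogy_log`` records ``(t_mut, parent_id,
    child_id)`` for every mutant ever born (the founder is ``(0, -1, 0)``).
    """

    abundances: np.ndarray
    matrix: PayoffMatrix
    d: np.ndarray
    t_mut: int = 0
    wall_time: float = 0.0
    next_id: int = 1
    genealogy_log: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def N(self) -> int:
        return int(self.abundances.sum())

    @property
    def n(self) -> int:
        return self.matrix.n

    @property
    def extinct(self) -> bool:
        return self.matrix.n == 0


@dataclass(frozen=True)
class Snapshot:
    """Population state recorded at one mutation event."""

    t_mut: int
    type_ids: tuple[int, ...]
    abundances: np.ndarray
    A: np.ndarray

    @property
    def N(self) -> int:
        return int(self.abundances.sum())

    @property
    def n(self) -> int:
        return len(self.type_ids)

    def mean_payoff(self) -> float:
        """Abundance-weighted mean self-payoff of the extant types."""
        return float(np.average(np.diag(self.A), weights=self.abundances))


@dataclass
class RunResult:
    params: ModelParams
    seed: int | None
    t_mut_max: int
    snapshots: list[Snapshot]
    genealogy_log: list[tuple[int, int, int]]
    extinct: bool
    final_wall_time: float


@dataclass(frozen=True)
class RateTable:
    """Per-type reaction rates (birth pooled over clonal/mutant)."""

    birth: np.ndarray        # lambda_b * x_i
    bg_death: np.ndarray     # lambda_d * x_i
    competition: np.ndarray  # x_i * (sum_j d_ij x_j - d_ii)

    @property
    def total(self) -> float:
        return float(self.birth.sum() + self.bg_death.sum() + self.competition.sum())


def initial_state(
    params: ModelParams,
    rng: np.random.Generator,
    initial_abundance: int | str = "equilibrium",
) -> PopulationState:
    """Found the population with a single type.

    The founder's self-payoff is drawn from ``Normal(ln 1000, 1)``; its
    abundance is the rounded deterministic one-type equilibrium
    ``(lambda_b - lambda_d) / d_11`` (or a fixed integer if requested).
    """
    a11 = rng.normal(INITIAL_PAYOFF_MEAN, INITIAL_PAYOFF_SD)
    matrix = PayoffMatrix((0,), np.array([[a11]]))
    d = death_rate_matrix(matrix.A, params.alpha)
    if initial_abundance == "equilibrium":
        x0 = max(1, round((params.lambda_b - params.lambda_d) / d[0, 0]))
    else:
        x0 = int(initial_abundance)
        if x0 < 1:
            raise ValueError("initial abundance must be >= 1")
    return PopulationState(
        abundances=np.array([x0], dtype=np.int64),
        matrix=matrix,
        d=d,
        genealogy_log=[(0, -1, 0)],
    )


def event_rates(state: PopulationState, params: ModelParams) -> RateTable:
    """Per-type rates of the three reaction families."""
    x = state.abundances.astype(float)
    load = state.d @ x
    comp = x * (load - np.diag(state.d))
    return RateTable(params.lambda_b * x, params.lambda_d * x, comp)


def _remove_extinct(state: PopulationState, pos: int) -> None:
    dead_id = state.matrix.type_ids[pos]
    state.matrix = remove_types(state.matrix, {dead_id})
    state.abundances = np.delete(state.abundances, pos)
    state.d = np.delete(np.delete(state.d, pos, axis=0), pos, axis=1)


def step(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Apply one exact-Gillespie reaction in place and return the state."""
    if state.extinct or state.N == 0:
        raise ExtinctError("cannot step an extinct population")
    rates = event_rates(state, params)
    total = rates.total
    state.wall_time += rng.exponential(1.0 / total)
    u = rng.random() * total
    b_tot = rates.birth.sum()
    d_tot = rates.bg_death.sum()
    if u < b_tot:
        pos = int(np.searchsorted(np.cumsum(rates.birth), u))
        if rng.random() < params.mu:  # mutant birth
            parent_id = state.matrix.type_ids[pos]
            child_id = state.next_id
            state.matrix = mutate_payoffs(
                state.matrix, parent_id, params.sigma, rng, new_id=child_id
            )
            state.d = death_rate_matrix(state.matrix.A, params.alpha)
            state.abundances = np.append(state.abundances, np.int64(1))
            state.next_id += 1
            state.t_mut += 1
            state.genealogy_log.append((state.t_mut, parent_id, child_id))
        else:
            state.abundances[pos] += 1
    else:
        u -= b_tot
        if u < d_tot:
            pos = int(np.searchsorted(np.cumsum(rates.bg_death), u))
        else:
            u -= d_tot
            pos = int(np.searchsorted(np.cumsum(rates.competition), u))
        state.abundances[pos] -= 1
        if state.abundances[pos] == 0:
            _remove_extinct(state, pos)
    return state


def _snapshot(state: PopulationState) -> Snapshot:
    return Snapshot(
        t_mut=state.t_mut,
        type_ids=state.matrix.type_ids,
        abundances=state.abundances.copy(),
        A=state.matrix.A.copy(),
    )


def run(
    params: ModelParams,
    t_mut_max: int,
    rng: np.random.Generator | int | None = None,
    initial_abundance: int | str = "equilibrium",
    snapshot_thinning: int = 1,
    max_reactions: int | None = None,
) -> RunResult:
    """Simulate until ``t_mut_max`` mutation events or extinction.

    Snapshots are recorded at ``t_mut = 0`` and after every
    ``snapshot_thinning``-th mutation event (and at the last one).
    ``max_reactions`` is a safety valve for parameter regimes where
    mutations are vanishingly rare; hitting it truncates the run without
    flagging extinction.
    """
    if t_mut_max < 1:
        raise ValueError("t_mut_max must be >= 1")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = rng
        rng = np.random.default_rng(rng)
    state = initial_state(params, rng, initial_abundance)
    snapshots = [_snapshot(state)]
    extinct = False
    reactions = 0
    while state.t_mut < t_mut_max:
        t_before = state.t_mut
        try:
            step(state, params, rng)
        except ExtinctError:  # pragma: no cover - guarded below
            break
        reactions += 1
        if state.t_mut > t_before and (
            state.t_mut % snapshot_thinning == 0 or state.t_mut == t_mut_max
        ):
            snapshots.append(_snapshot(state))
        if state.extinct or state.N == 0:
            extinct = True
            break
        if max_reactions is not None and reactions >= max_reactions:
            break
    return RunResult(
        params=params,
        seed=None if seed is None else int(seed),
        t_mut_max=t_mut_max,
        snapshots=snapshots,
        genealogy_log=list(state.genealogy_log),
        extinct=extinct,
        final_wall_time=state.wall_time,
    )
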