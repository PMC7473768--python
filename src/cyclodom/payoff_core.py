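"""Payoff matrices, competition death rates, the mutation kernel, and
pair/triplet classifiers.

The model describes a well-mixed community in which each extant type ``i``
carries a payoff ``A[i][j]`` against every type ``j`` (including itself).
Payoffs map to competition death rates ``d_ij = alpha + exp(-A_ij)``, so a
larger payoff means a lower chance of dying from a competitive encounter.
New types arise by mutation: the offspring inherits the parental row,
column, and diagonal entries, each perturbed by independent Gaussian noise
of standard deviation ``sigma``.

Pairwise competitive outcomes (dominance, bistability, coexistence) are
decided by the sign pattern of ``(A_ii - A_ji, A_ij - A_jj)``; triplets of
types are classified by whether their three dominance links form a directed
3-cycle (rock-paper-scissors), a transitive tournament, or contain a
non-dominance link.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TieError",
    "PairClass",
    "TripletClass",
    "TripletOutcome",
    "ModelParams",
    "PayoffMatrix",
    "competition_death_rate",
    "classify_pair",
    "classify_triplet",
    "classify_triplet_batch",
    "mutate_payoffs",
    "remove_types",
]

#: payoffs above this make exp(-A) underflow to exactly 0 rather than raise
EXP_CLAMP = 700.0


class TieError(ValueError):
    """An exact payoff tie makes the competitive outcome undefined.

    Ties have probability zero under continuous payoffs; silently breaking
    them would corrupt enumeration oracles, so callers must decide.
    """


class PairClass(enum.Enum):
    """Outcome of two-type competitive Lotka-Volterra dynamics."""

    DOM_FIRST = "dom_first"    # first type excludes the second from any start
    DOM_SECOND = "dom_second"  # second type excludes the first
    BISTABLE = "bistable"      # winner depends on initial condition
    COEXIST = "coexist"        # stable interior equilibrium

    def swapped(self) -> "PairClass":
        """The class seen after exchanging the two types."""
        if self is PairClass.DOM_FIRST:
            return PairClass.DOM_SECOND
        if self is PairClass.DOM_SECOND:
            return PairClass.DOM_FIRST
        return self

    @property
    def is_dominance(self) -> bool:
        return self in (PairClass.DOM_FIRST, PairClass.DOM_SECOND)


class TripletClass(enum.Enum):
    CYCLIC = "cyclic"        # three dominance links forming a directed 3-cycle
    NONCYCLIC = "noncyclic"  # three dominance links, transitive tournament
    MIXED = "mixed"          # at least one bistable or coexistence link


@dataclass(frozen=True)
class TripletOutcome:
    """Classification of a 3-type payoff submatrix.

    ``orientation`` is the cyclic order as a tuple of positions (only for
    CYCLIC); ``source``/``sink`` are positions of the type beating both /
    beaten by both (only for NONCYCLIC). Positions refer to the order in
    which the three types were supplied.
    """

    kind: TripletClass
    orientation: tuple[int, int, int] | None = None
    source: int | None = None
    sink: int | None = None


@dataclass(frozen=True)
class ModelParams:
    """Demographic and mutational parameters of the individual-based model.

    lambda_b
        Per-capita birth rate (1/time). Must exceed ``lambda_d`` or the
        population collapses.
    lambda_d
        Per-capita background death rate (1/time).
    alpha
        Baseline competition death rate; the floor of ``d_ij`` that bounds
        the population near ``(lambda_b - lambda_d)/alpha``.
    mu
        Probability that a birth produces a mutant type.
    sigma
        Standard deviation of the Gaussian payoff noise of the mutation
        kernel.
    """

    lambda_b: float = 0.9
    lambda_d: float = 0.4
    alpha: float = 5e-6
    mu: float = 1e-5
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lambda_b > self.lambda_d > 0):
            raise ValueError(
                f"require lambda_b > lambda_d > 0, got "
                f"lambda_b={self.lambda_b}, lambda_d={self.lambda_d}"
            )
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0 <= self.mu <= 1:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class PayoffMatrix:
    """Square payoff matrix over the currently extant types.

    ``type_ids`` are persistent non-negative integer identifiers, never
    reused within a run; ``A[r, c]`` is the payoff of the type at row
    position ``r`` against the type at column position ``c``.
    """

    type_ids: tuple[int, ...]
    A: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        n = len(self.type_ids)
        if A.shape != (n, n):
            raise ValueError(f"matrix shape {A.shape} != ({n}, {n})")
        if len(set(self.type_ids)) != n:
            raise ValueError("type_ids must be unique")
        if n and not np.all(np.isfinite(A)):
            raise ValueError("payoff entries must be finite")

    @property
    def n(self) -> int:
        return len(self.type_ids)

    def index_of(self, type_id: int) -> int:
        try:
            return self.type_ids.index(type_id)
        except ValueError:
            raise KeyError(f"type id {type_id} not extant") from None

    def payoff(self, i: int, j: int) -> float:
        """Payoff of type ``i`` against type ``j`` (by persistent ID)."""
        return float(self.A[self.index_of(i), self.index_of(j)])

    def submatrix(self, ids: Sequence[int]) -> np.ndarray:
        idx = [self.index_of(t) for t in ids]
        return self.A[np.ix_(idx, idx)]

    # -- CSV round trip: header row of type IDs, entries row-major ---------
    def to_csv(self, path) -> None:
        header = ",".join(str(t) for t in self.type_ids)
        np.savetxt(path, self.A, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "PayoffMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            ids = tuple(int(t) for t in header.split(",")) if header else ()
            A = np.loadtxt(fh, delimiter=",", ndmin=2) if ids else np.empty((0, 0))
        return cls(ids, A)


def competition_death_rate(
    a_ij: float, alpha: float, clamp: float = EXP_CLAMP
) -> float:
    """Death rate of the row type from a competitive encounter.

    ``d_ij = alpha + exp(-A_ij)``, with ``exp(-A)`` clamped to 0 for
    ``A > clamp`` so extreme payoffs never underflow into invalid rates.
    """
    if not math.isfinite(a_ij):
        raise ValueError(f"payoff must be finite, got {a_ij}")
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return alpha + (0.0 if a_ij > clamp else math.exp(-a_ij))


def death_rate_matrix(A: np.ndarray, alpha: float, clamp: float = EXP_CLAMP) -> np.ndarray:
    """Vectorized ``d = alpha + exp(-A)`` with the same overflow clamp."""
    A = np.asarray(A, dtype=float)
    if A.size and not np.all(np.isfinite(A)):
        raise ValueError("payoff entries must be finite")
    out = np.where(A > clamp, 0.0, np.exp(-np.minimum(A, clamp)))
    return alpha + out


def classify_pair(aii: float, aij: float, aji: float, ajj: float) -> PairClass:
    """Two-type outcome from the sign pattern of within-column comparisons.

    The first type dominates iff ``A_ii > A_ji`` and ``A_ij > A_jj``; the
    reversed signs give dominance of the second; mixed signs give
    bistability (own-type advantage) or coexistence (cross-type advantage).
    """
    for v in (aii, aij, aji, ajj):
        if not math.isfinite(v):
            raise ValueError("payoffs must be finite")
    if aii == aji or aij == ajj:
        raise TieError(
            f"exact payoff tie: A_ii={aii} vs A_ji={aji}, A_ij={aij} vs A_jj={ajj}"
        )
    first_col_i = aii > aji   # i beats j in i's column
    first_col_j = aij > ajj   # i beats j in j's column
    if first_col_i and first_col_j:
        return PairClass.DOM_FIRST
    if not first_col_i and not first_col_j:
        return PairClass.DOM_SECOND
    if first_col_i:
        return PairClass.BISTABLE
    return PairClass.COEXIST


def classify_triplet(sub: np.ndarray) -> TripletOutcome:
    """Classify a 3-type payoff submatrix.

    CYCLIC / NONCYCLIC require all three pairwise links to be dominance;
    the two cases are told apart by the win pattern of the resulting
    3-tournament. Anything containing a bistable or coexistence link is
    MIXED.
    """
    sub = np.asarray(sub, dtype=float)
    if sub.shape != (3, 3):
        raise ValueError(f"expected a 3x3 submatrix, got shape {sub.shape}")
    beats = np.zeros((3, 3), dtype=bool)
    for p in range(3):
        for q in range(p + 1, 3):
            cls = classify_pair(sub[p, p], sub[p, q], sub[q, p], sub[q, q])
            if cls is PairClass.DOM_FIRST:
                beats[p, q] = True
            elif cls is PairClass.DOM_SECOND:
                beats[q, p] = True
            else:
                return TripletOutcome(TripletClass.MIXED)
    wins = beats.sum(axis=1)
    if set(wins) == {1}:  # each type beats exactly one other: 3-cycle
        nxt = {p: int(np.flatnonzero(beats[p])[0]) for p in range(3)}
        orientation = (0, nxt[0], nxt[nxt[0]])
        return TripletOutcome(TripletClass.CYCLIC, orientation=orientation)
    source = int(np.flatnonzero(wins == 2)[0])
    sink = int(np.flatnonzero(wins == 0)[0])
    return TripletOutcome(TripletClass.NONCYCLIC, source=source, sink=sink)


# integer codes used by the batch classifier
CODE_CYCLIC, CODE_NONCYCLIC, CODE_MIXED = 0, 1, 2


def classify_triplet_batch(mats: np.ndarray) -> np.ndarray:
    """Vectorized triplet classification for a stack of 3x3 matrices.

    Returns an int array with codes ``CODE_CYCLIC``, ``CODE_NONCYCLIC``,
    ``CODE_MIXED``. Exact ties are not detected here (they occur with
    probability zero for the continuous ensembles this services); the
    scalar :func:`classify_triplet` is the tie-checking reference.
    """
    mats = np.asarray(mats, dtype=float)
    if mats.ndim != 3 or mats.shape[1:] != (3, 3):
        raise ValueError(f"expected shape (n, 3, 3), got {mats.shape}")
    # beats[:, p, q]: p dominates q, i.e. A_pp > A_qp and A_pq > A_qq
    beats = np.zeros(mats.shape, dtype=bool)
    for p in range(3):
        for q in range(3):
            if p != q:
                beats[:, p, q] = (mats[:, p, p] > mats[:, q, p]) & (
                    mats[:, p, q] > mats[:, q, q]
                )
    link_dom = np.ones(len(mats), dtype=bool)
    for p in range(3):
        for q in range(p + 1, 3):
            link_dom &= beats[:, p, q] | beats[:, q, p]
    wins = beats.sum(axis=2)
    cyclic = link_dom & (wins == 1).all(axis=1)
    out = np.full(len(mats), CODE_MIXED, dtype=np.int8)
    out[link_dom] = CODE_NONCYCLIC
    out[cyclic] = CODE_CYCLIC
    return out


def mutate_payoffs(
    m: PayoffMatrix,
    parent_id: int,
    sigma: float,
    rng: np.random.Generator,
    new_id: int | None = None,
) -> PayoffMatrix:
    """Append a mutant of ``parent_id`` with inherited-plus-noise payoffs.

    Every entry of the new row, new column, and new diagonal equals the
    parent's corresponding entry plus an independent ``Normal(0, sigma^2)``
    draw; pre-existing entries are untouched. The new type gets a fresh ID
    (``max(type_ids) + 1`` unless given).
    """
    p = m.index_of(parent_id)
    n = m.n
    if new_id is None:
        new_id = max(m.type_ids) + 1
    elif new_id in m.type_ids:
        raise ValueError(f"new_id {new_id} already in use")
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = m.A
    A[n, :n] = m.A[p, :] + rng.normal(0.0, sigma, size=n)
    A[:n, n] = m.A[:, p] + rng.normal(0.0, sigma, size=n)
    A[n, n] = m.A[p, p] + rng.normal(0.0, sigma)
    return PayoffMatrix(m.type_ids + (new_id,), A)


def remove_types(m: PayoffMatrix, dead_ids: Iterable[int]) -> PayoffMatrix:
    """Restrict the matrix to survivors; surviving entries are bit-identical.

    Removing every type returns an empty (0x0) matrix, which flags
    population extinction to the caller.
    """
    dead = set(dead_ids)
    unknown = dead - set(m.type_ids)
    if unknown:
        raise KeyError(f"cannot remove unknown type ids {sorted(unknown)}")
    keep = [k for k, t in enumerate(m.type_ids) if t not in dead]
    ids = tuple(m.type_ids[k] for k in keep)
    return PayoffMatrix(ids, m.A[np.ix_(keep, keep)])
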