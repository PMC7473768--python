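"""Interaction networks, triplet censuses, chi, and triplet lifespans.

From a payoff matrix we build the complete pairwise interaction network
(one link class per unordered pair), census every 3-type subset into
cyclic dominance / non-cyclic dominance / mixed, and compute

    chi = (# cyclic) / (# cyclic + # non-cyclic),

the fraction of rock-paper-scissors motifs among all-dominance triplets.
Across a sequence of per-mutation-event snapshots the module also tracks
how long each dominance triplet persists (its lifespan, in mutation
events) and summarizes lifespans as a complementary cumulative
distribution function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .gillespie_sim import Snapshot
from .payoff_core import (
    CODE_CYCLIC,
    CODE_MIXED,
    CODE_NONCYCLIC,
    PairClass,
    PayoffMatrix,
    TripletClass,
    classify_pair,
    classify_triplet_batch,
)

__all__ = [
    "UndefinedStatisticError",
    "InteractionNetwork",
    "TripletCounts",
    "TripletRecord",
    "build_network",
    "link_type_proportions",
    "count_triplets",
    "census_matrix",
    "link_proportions_matrix",
    "chi",
    "snapshot_networks",
    "track_lifespans",
    "Ccdf",
    "ccdf",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (e.g. n < 3, or no
    dominance triplets); callers exclude such snapshots from averages
    rather than recording a silent zero."""


@dataclass(frozen=True)
class InteractionNetwork:
    """Complete graph over extant types with one :class:`PairClass` per pair.

    ``links[(i, j)]`` with ``i < j`` holds ``classify_pair`` evaluated with
    ``i`` as the first type, so orientation is recoverable.
    """

    nodes: tuple[int, ...]
    links: dict[tuple[int, int], PairClass]

    def link(self, i: int, j: int) -> PairClass:
        """Link class for the ordered pair ``(i, j)``."""
        if i < j:
            return self.links[(i, j)]
        return self.links[(j, i)].swapped()

    def dominates(self, i: int, j: int) -> bool:
        return self.link(i, j) is PairClass.DOM_FIRST


@dataclass(frozen=True)
class TripletCounts:
    cyclic: int
    noncyclic: int
    mixed: int

    @property
    def total(self) -> int:
        return self.cyclic + self.noncyclic + self.mixed

    @property
    def proportions(self) -> tuple[float, float, float]:
        t = self.total
        return (self.cyclic / t, self.noncyclic / t, self.mixed / t)


@dataclass
class TripletRecord:
    """One contiguous stretch of existence of a dominance triplet.

    Identity is the unordered member set *plus* motif class (and cycle
    orientation): a link flip that changes the motif closes the record and
    opens a fresh one. ``t_destroyed`` is the first snapshot at which the
    motif is gone; lifespan = ``t_destroyed - t_formed``. Records still
    open at the final snapshot are right-censored (``t_destroyed`` is the
    last time observed, cause "censored").
    """

    members: frozenset[int]
    kind: TripletClass
    signature: tuple
    t_formed: int
    t_destroyed: int | None = None
    cause: str | None = None  # "extinction" | "link-flip" | "censored"

    @property
    def censored(self) -> bool:
        return self.cause == "censored"

    @property
    def lifespan(self) -> int:
        if self.t_destroyed is None:
            raise ValueError("record still open")
        return self.t_destroyed - self.t_formed


def build_network(m: PayoffMatrix) -> InteractionNetwork:
    """Classify every unordered pair of extant types."""
    if m.n < 2:
        raise UndefinedStatisticError("need at least two types for a network")
    ids = sorted(m.type_ids)
    links: dict[tuple[int, int], PairClass] = {}
    for i, j in itertools.combinations(ids, 2):
        pi, pj = m.index_of(i), m.index_of(j)
        try:
            links[(i, j)] = classify_pair(
                m.A[pi, pi], m.A[pi, pj], m.A[pj, pi], m.A[pj, pj]
            )
        except ValueError as err:
            raise type(err)(f"pair ({i}, {j}): {err}") from None
    return InteractionNetwork(tuple(ids), links)


def link_type_proportions(net: InteractionNetwork) -> dict[str, float]:
    """Proportions of dominance (both orientations pooled), bistability,
    and coexistence links; they sum to one."""
    if not net.links:
        raise UndefinedStatisticError("network has no links")
    counts = {"dominance": 0, "bistability": 0, "coexistence": 0}
    for cls in net.links.values():
        if cls.is_dominance:
            counts["dominance"] += 1
        elif cls is PairClass.BISTABLE:
            counts["bistability"] += 1
        else:
            counts["coexistence"] += 1
    total = len(net.links)
    return {k: v / total for k, v in counts.items()}


def _triplet_signature(net: InteractionNetwork, trip: tuple[int, int, int]):
    """(kind, canonical orientation / source-sink) for one triplet."""
    i, j, k = trip
    dom_links = []
    for a, b in ((i, j), (i, k), (j, k)):
        cls = net.link(a, b)
        if not cls.is_dominance:
            return TripletClass.MIXED, None
        dom_links.append((a, b) if cls is PairClass.DOM_FIRST else (b, a))
    wins = {t: 0 for t in trip}
    for a, _b in dom_links:
        wins[a] += 1
    if set(wins.values()) == {1}:
        nxt = {a: b for a, b in dom_links}
        start = min(trip)
        orientation = (start, nxt[start], nxt[nxt[start]])
        return TripletClass.CYCLIC, orientation
    source = next(t for t, w in wins.items() if w == 2)
    sink = next(t for t, w in wins.items() if w == 0)
    return TripletClass.NONCYCLIC, (source, sink)


def count_triplets(net: InteractionNetwork) -> TripletCounts:
    """Census all C(n, 3) triplets of the network."""
    if len(net.nodes) < 3:
        raise UndefinedStatisticError("triplet census needs n >= 3")
    c = {TripletClass.CYCLIC: 0, TripletClass.NONCYCLIC: 0, TripletClass.MIXED: 0}
    for trip in itertools.combinations(net.nodes, 3):
        kind, _ = _triplet_signature(net, trip)
        c[kind] += 1
    return TripletCounts(c[TripletClass.CYCLIC], c[TripletClass.NONCYCLIC], c[TripletClass.MIXED])


def census_matrix(A: np.ndarray) -> TripletCounts:
    """Vectorized triplet census straight from an n x n payoff matrix.

    Equivalent to ``count_triplets(build_network(...))`` (the network route
    is the tie-checking reference; this path serves per-snapshot time
    series where n can be large enough that C(n, 3) matters).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n < 3:
        raise UndefinedStatisticError("triplet census needs n >= 3")
    combos = np.array(list(itertools.combinations(range(n), 3)))
    subs = A[combos[:, :, None], combos[:, None, :]]
    codes = classify_triplet_batch(subs)
    return TripletCounts(
        int((codes == CODE_CYCLIC).sum()),
        int((codes == CODE_NONCYCLIC).sum()),
        int((codes == CODE_MIXED).sum()),
    )


def link_proportions_matrix(A: np.ndarray) -> dict[str, float]:
    """Vectorized link-type proportions from an n x n payoff matrix."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n < 2:
        raise UndefinedStatisticError("need at least two types for links")
    diag = np.diag(A)
    # c1[i, j]: A_ii > A_ji (i wins in its own column); c2[i, j]: A_ij > A_jj
    c1 = diag[:, None] > A.T
    c2 = A > diag[None, :]
    dom_ij = c1 & c2
    iu, ju = np.triu_indices(n, k=1)
    dominance = int((dom_ij[iu, ju] | dom_ij[ju, iu]).sum())
    bistable = int((c1[iu, ju] & ~c2[iu, ju]).sum())
    coexist = int((~c1[iu, ju] & c2[iu, ju]).sum())
    total = len(iu)
    return {
        "dominance": dominance / total,
        "bistability": bistable / total,
        "coexistence": coexist / total,
    }


def chi(counts: TripletCounts) -> float:
    """Fraction of cyclic among all-dominance triplets."""
    dom = counts.cyclic + counts.noncyclic
    if dom == 0:
        raise UndefinedStatisticError("no dominance triplets; chi undefined")
    return counts.cyclic / dom


def snapshot_networks(snapshots: list[Snapshot]):
    """Yield ``(t_mut, network)`` for snapshots with at least two types."""
    for snap in snapshots:
        if snap.n >= 2:
            m = PayoffMatrix(snap.type_ids, snap.A)
            yield snap.t_mut, build_network(m)


def track_lifespans(
    snapshots: list[tuple[int, InteractionNetwork]],
) -> list[TripletRecord]:
    """Open/close lifespan records of dominance triplets across snapshots.

    A record opens at the first snapshot where an ID-set forms a cyclic
    (resp. non-cyclic) dominance triplet and closes at the first later
    snapshot where that exact motif is gone — because a member went
    extinct ("extinction") or a link changed class or orientation
    ("link-flip"). Records open at the last snapshot are right-censored.
    """
    times = [t for t, _ in snapshots]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("snapshots must be strictly ordered by t_mut")
    open_records: dict[tuple, TripletRecord] = {}
    closed: list[TripletRecord] = []
    for t, net in snapshots:
        active: dict[tuple, TripletRecord] = {}
        nodes = set(net.nodes)
        if len(net.nodes) >= 3:
            for trip in itertools.combinations(net.nodes, 3):
                kind, sig = _triplet_signature(net, trip)
                if kind is TripletClass.MIXED:
                    continue
                key = (frozenset(trip), kind, sig)
                rec = open_records.pop(
                    key, None
                ) or TripletRecord(frozenset(trip), kind, sig, t_formed=t)
                active[key] = rec
        for key, rec in open_records.items():
            rec.t_destroyed = t
            rec.cause = (
                "extinction" if not rec.members <= nodes else "link-flip"
            )
            closed.append(rec)
        open_records = active
    last_t = times[-1] if times else 0
    for rec in open_records.values():
        rec.t_destroyed = last_t
        rec.cause = "censored"
        closed.append(rec)
    return sorted(closed, key=lambda r: (r.t_formed, sorted(r.members)))


@dataclass(frozen=True)
class Ccdf:
    """Complementary CDF of integer lifespans: ``P(lifespan > x)``."""

    support: np.ndarray  # sorted unique lifespans
    values: np.ndarray   # CCDF evaluated at each support point

    def __call__(self, x: float) -> float:
        n = np.searchsorted(self.support, x, side="right")
        if n == 0:
            return 1.0
        return float(self.values[n - 1])


def ccdf(lifespans) -> Ccdf:
    """Empirical CCDF of a multiset of non-negative integer lifespans."""
    arr = np.sort(np.asarray(list(lifespans)))
    if arr.size == 0:
        raise UndefinedStatisticError("no lifespans")
    support, counts = np.unique(arr, return_counts=True)
    above = arr.size - np.cumsum(counts)
    return Ccdf(support, above / arr.size)
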