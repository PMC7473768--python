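"""Genealogy-conditioned payoff sampling and the chi extremes.

A rooted 3-leaf genealogy is reduced to five per-branch mutation counts.
With ``o`` the last common ancestor of the triplet, ``n`` the more recent
common ancestor of the cherry pair (j, k), and ``td`` the moment the last
two lineages diverge:

* ``w1`` — mutations on the outgroup lineage (toward i) between ``o`` and ``td``
* ``w2`` — mutations on i's lineage after ``td``
* ``x``  — mutations on the shared j/k stem between ``o`` and ``n``
* ``y``, ``z`` — mutations on the private j and k branches after ``td``

Replaying the genealogy with the inheritance kernel (each mutation adds an
independent ``Normal(0, sigma^2)`` draw to every entry of the mutating
lineage's row, column, and diagonal; a lineage split copies the current
entries) yields the joint Gaussian distribution of the 3x3 payoff matrix,
hence a Monte-Carlo estimate of chi conditioned on the genealogy. The
fraction of mutations accumulated after ``td``,

    Fl = (w2 + y + z) / (w2 + y + z + w1 + x),

controls how decorrelated the leaf payoffs are: large ``Fl`` promotes
cyclic dominance, small ``Fl`` suppresses it. Searching over genealogies
locates the maximizer (chi -> 1/6) and minimizer (chi < 0.001) structures.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .payoff_core import CODE_CYCLIC, CODE_NONCYCLIC, classify_triplet_batch
from .triplet_stats import UndefinedStatisticError

__all__ = [
    "GenealogyTriplet",
    "ChiEstimate",
    "fl",
    "extract_genealogy",
    "sample_matrix_given_genealogy",
    "genealogy_covariance",
    "chi_given_genealogy",
    "search_extreme_chi",
    "to_newick",
    "from_newick",
    "sidecar_json",
]


@dataclass(frozen=True)
class GenealogyTriplet:
    """Five branch mutation counts plus (optionally) the leaf labels.

    ``leaves`` orders the triplet as (outgroup i, cherry j, cherry k); the
    cherry pair is the one sharing the more recent common ancestor, which
    is the genealogy's topology flag.
    """

    w1: int
    w2: int
    x: int
    y: int
    z: int
    leaves: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "x", "y", "z"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.w1 + self.w2 + self.x + self.y + self.z

    @property
    def pre_td(self) -> int:
        return self.w1 + self.x

    @property
    def post_td(self) -> int:
        return self.w2 + self.y + self.z


@dataclass(frozen=True)
class ChiEstimate:
    """Monte-Carlo chi with its binomial standard error."""

    chi: float
    se: float
    n_samples: int
    n_dominance: int
    genealogy: GenealogyTriplet | None = None


def fl(g: GenealogyTriplet) -> float:
    """Fraction of mutations accumulated after the last divergence."""
    if g.total == 0:
        raise UndefinedStatisticError("genealogy has no mutations; Fl undefined")
    return g.post_td / g.total


# --------------------------------------------------------------------------
# extraction from a simulation genealogy log
# --------------------------------------------------------------------------

def _root_path(parent_map: dict[int, tuple[int, int]], leaf: int) -> list[tuple[int, int]]:
    """Path root -> leaf as (type, birth_time); the root has birth_time 0."""
    path = []
    node = leaf
    while node in parent_map:
        parent, t = parent_map[node]
        path.append((node, t))
        node = parent
        if node == -1:
            break
    else:
        raise KeyError(f"type {leaf} does not appear in the genealogy log")
    return path[::-1]


def _divergence(pa: list, pb: list) -> tuple[int, float]:
    """(common-prefix length, divergence time) of two root paths.

    Two lineages stay merged while they run along the same type's
    timeline; they diverge when the first of them leaves the last common
    type via a mutation.
    """
    k = 0
    while k < min(len(pa), len(pb)) and pa[k][0] == pb[k][0]:
        k += 1
    ta = pa[k][1] if k < len(pa) else np.inf  # leaf may *be* the common type
    tb = pb[k][1] if k < len(pb) else np.inf
    return k, min(ta, tb)


def extract_genealogy(
    log: list[tuple[int, int, int]], triplet
) -> GenealogyTriplet:
    """Reduce a simulation genealogy log to the five branch counts.

    ``log`` holds ``(t_mut, parent_id, child_id)`` records (the founder
    with parent -1). Every mutation along a leaf's ancestral path counts,
    including mutations of intermediaries that later went extinct; a
    mutation is pre-``td`` if its birth time is at most the divergence
    time of the last two lineages.
    """
    parent_map: dict[int, tuple[int, int]] = {}
    for t, parent, child in log:
        parent_map[child] = (parent, t)
    i0, j0, k0 = triplet
    paths = {t: _root_path(parent_map, t) for t in (i0, j0, k0)}
    # the cherry is the pair that diverges last
    pairs = list(itertools.combinations((i0, j0, k0), 2))
    divs = {p: _divergence(paths[p[0]], paths[p[1]]) for p in pairs}
    cherry = max(pairs, key=lambda p: (divs[p][1], p))
    td = divs[cherry][1]
    if not np.isfinite(td):
        raise ValueError("degenerate genealogy: two identical lineages")
    j, k = cherry
    (i,) = [t for t in (i0, j0, k0) if t not in cherry]
    # o = last common type of all three paths; n = last common type of cherry
    o_depth = min(
        _divergence(paths[a], paths[b])[0] for a, b in pairs
    )
    n_depth = divs[cherry][0]
    i_edges = [t for _node, t in paths[i][o_depth:]]
    w1 = sum(1 for t in i_edges if t <= td)
    w2 = sum(1 for t in i_edges if t > td)
    x = len(paths[j][o_depth:n_depth])
    y = len(paths[j]) - n_depth
    z = len(paths[k]) - n_depth
    return GenealogyTriplet(w1, w2, x, y, z, leaves=(i, j, k))


# --------------------------------------------------------------------------
# forward sampling
# --------------------------------------------------------------------------

def _mutate_lineage(A: np.ndarray, idx: int, alive: list[int], sigma: float,
                    rng: np.random.Generator) -> None:
    """One mutation on lineage ``idx``: independent noise on every entry of
    its row, column, and diagonal against the lineages alive right now."""
    for l in alive:
        if l != idx:
            A[idx, l] += rng.normal(0.0, sigma)
            A[l, idx] += rng.normal(0.0, sigma)
    A[idx, idx] += rng.normal(0.0, sigma)


def sample_matrix_given_genealogy(
    g: GenealogyTriplet,
    sigma: float,
    rng: np.random.Generator,
    shuffle_order: bool = False,
) -> np.ndarray:
    """Replay the genealogy event by event and return one 3x3 matrix.

    The ancestral self-payoff is fixed at 0: triplet classification
    compares entries that all share the ancestral level, so it cancels.
    A lineage split is an exact copy — a mutant's founding mutation is
    booked as the first ordinary mutation of its branch — and epochs are
    replayed in chronological order. Because the Gaussian increments of
    independent lineages commute, any event interleaving consistent with
    the branch counts yields the same distribution (``shuffle_order``
    exercises that).
    """
    A = np.zeros((3, 3))  # lineages I=0, J=1, K=2; J doubles as the j/k stem
    # epoch 1: lineages I and stem(=1) alive; K mirrors the stem implicitly
    epoch1 = [0] * g.w1 + [1] * g.x
    if shuffle_order:
        epoch1 = list(rng.permutation(epoch1))
    for idx in epoch1:
        _mutate_lineage(A, idx, [0, 1], sigma, rng)
    # second split: K copies the stem
    A[2, 0] = A[1, 0]
    A[0, 2] = A[0, 1]
    A[2, 2] = A[1, 1]
    A[1, 2] = A[1, 1]
    A[2, 1] = A[1, 1]
    # epoch 2: all three lineages alive
    epoch2 = [0] * g.w2 + [1] * g.y + [2] * g.z
    if shuffle_order:
        epoch2 = list(rng.permutation(epoch2))
    for idx in epoch2:
        _mutate_lineage(A, idx, [0, 1, 2], sigma, rng)
    return A


def genealogy_covariance(g: GenealogyTriplet, sigma: float = 1.0) -> np.ndarray:
    """Closed-form covariance of the 9 payoff entries (flattened 3x3).

    Each mutation event contributes an independent draw per touched entry,
    so two entries only covary through draws they inherited from the same
    pre-split entry: the outgroup's cross entries share the epoch-1 row
    (resp. column) sum of ``w1 + x`` draws, and the four cherry-block
    entries all inherit the stem diagonal's ``x`` draws.
    """
    w1, w2, x, y, z = g.w1, g.w2, g.x, g.y, g.z
    e = {(a, b): 3 * a + b for a in range(3) for b in range(3)}
    S = np.zeros((9, 9))
    var = {
        (0, 0): w1 + w2,
        (0, 1): w1 + x + w2 + y, (1, 0): w1 + x + w2 + y,
        (0, 2): w1 + x + w2 + z, (2, 0): w1 + x + w2 + z,
        (1, 1): x + y, (2, 2): x + z,
        (1, 2): x + y + z, (2, 1): x + y + z,
    }
    for key, v in var.items():
        S[e[key], e[key]] = v
    S[e[0, 1], e[0, 2]] = S[e[0, 2], e[0, 1]] = w1 + x
    S[e[1, 0], e[2, 0]] = S[e[2, 0], e[1, 0]] = w1 + x
    cherry_block = [(1, 1), (2, 2), (1, 2), (2, 1)]
    for a in cherry_block:
        for b in cherry_block:
            if a != b:
                S[e[a], e[b]] = x
    return sigma**2 * S


def _covariance_factor(S: np.ndarray) -> np.ndarray:
    """A factor L with L L^T = S, robust to singular covariances."""
    vals, vecs = np.linalg.eigh(S)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def sample_matrices_given_genealogy(
    g: GenealogyTriplet, sigma: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Batch of ``n`` matrices drawn from the closed-form joint Gaussian."""
    L = _covariance_factor(genealogy_covariance(g, sigma))
    return (rng.standard_normal((n, 9)) @ L.T).reshape(n, 3, 3)


def chi_given_genealogy(
    g: GenealogyTriplet,
    sigma: float = 1.0,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
    method: str = "covariance",
) -> ChiEstimate:
    """Monte-Carlo estimate of chi conditioned on a genealogy.

    ``method="covariance"`` samples the closed-form joint Gaussian in one
    vectorized batch; ``method="replay"`` replays the genealogy per sample
    (the slow reference path — the two must agree, which the test suite
    checks). Samples whose triplet is not all-dominance are excluded from
    the denominator, per the definition of chi.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if method == "covariance":
        mats = sample_matrices_given_genealogy(g, sigma, n_samples, rng)
    elif method == "replay":
        mats = np.stack(
            [sample_matrix_given_genealogy(g, sigma, rng) for _ in range(n_samples)]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    codes = classify_triplet_batch(mats)
    n_cyc = int((codes == CODE_CYCLIC).sum())
    n_dom = n_cyc + int((codes == CODE_NONCYCLIC).sum())
    if n_dom == 0:
        raise UndefinedStatisticError("no dominance triplets sampled; chi undefined")
    est = n_cyc / n_dom
    se = float(np.sqrt(est * (1.0 - est) / n_dom))
    return ChiEstimate(est, se, n_samples, n_dom, g)


# --------------------------------------------------------------------------
# extremizer search
# --------------------------------------------------------------------------

#: logarithmic grid of per-branch mutation counts explored by the search
SEARCH_GRID = (0, 1, 3, 10, 30, 100, 300, 1000)
#: large-count stand-ins for the asymptotic all-pre / all-post regimes
ASYMPTOTIC = 1_000_000


def _candidate_genealogies(budget: int) -> list[GenealogyTriplet]:
    """Deterministic candidate list: the full grid (subsampled evenly if it
    exceeds the budget) plus the asymptotic corner configurations."""
    grid = []
    for w1, w2, x, y in itertools.product(SEARCH_GRID, repeat=4):
        for z in SEARCH_GRID:
            if z < y:  # chi is invariant under swapping the cherry leaves
                continue
            if w1 + x == 0 or y + z == 0:
                continue
            grid.append(GenealogyTriplet(w1, w2, x, y, z))
    corners = [
        # nearly all mutations after every divergence
        GenealogyTriplet(0, ASYMPTOTIC, 1, 1, 1),
        GenealogyTriplet(1, ASYMPTOTIC, 0, 1, 1),
        GenealogyTriplet(0, ASYMPTOTIC, 1, 1, ASYMPTOTIC),
        GenealogyTriplet(0, 1, 1, ASYMPTOTIC, ASYMPTOTIC),
        # nearly all mutations before td
        GenealogyTriplet(ASYMPTOTIC, 0, ASYMPTOTIC, 0, 1),
        GenealogyTriplet(0, 0, ASYMPTOTIC, 0, 1),
        GenealogyTriplet(ASYMPTOTIC, 0, 1, 0, 1),
        GenealogyTriplet(0, 0, ASYMPTOTIC, 1, 1),
    ]
    n_grid = max(0, budget - len(corners))
    if n_grid < len(grid):
        stride = max(1, len(grid) // max(1, n_grid))
        grid = grid[::stride][:n_grid]
    return grid + corners


def search_extreme_chi(
    direction: str,
    total_budget: int = 25_000,
    sigma: float = 1.0,
    rng: np.random.Generator | int | None = None,
    coarse_samples: int = 3_000,
    refine_samples: int = 200_000,
    final_samples: int = 1_000_000,
    top_k: int = 25,
) -> ChiEstimate:
    """Locate the genealogy minimizing or maximizing chi.

    Successive halving against Monte-Carlo noise: every candidate is
    screened with ``coarse_samples`` draws; survivors are re-screened in
    rounds with four times the samples and a quarter of the field (down
    to ``top_k`` candidates at ``refine_samples`` draws) so a true
    optimum cannot be crowded out by lucky noisy screens; the winner then
    gets a fresh independent estimate with ``final_samples`` draws (free
    of selection bias). Deterministic given the seed and budget.
    """
    if direction not in ("min", "max"):
        raise ValueError("direction must be 'min' or 'max'")
    if total_budget < 1:
        raise ValueError("total_budget must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sign = 1.0 if direction == "max" else -1.0

    def screen(cands: list[GenealogyTriplet], n_samples: int):
        scored: list[tuple[float, GenealogyTriplet]] = []
        for g in cands:
            try:
                est = chi_given_genealogy(g, sigma, n_samples, rng)
            except UndefinedStatisticError:
                continue
            scored.append((sign * est.chi, g))
        scored.sort(key=lambda s: -s[0])
        return scored

    survivors = _candidate_genealogies(total_budget)
    n_samples = coarse_samples
    scored = screen(survivors, n_samples)
    while len(scored) > top_k and n_samples < refine_samples:
        keep = max(top_k, len(scored) // 4)
        n_samples = min(4 * n_samples, refine_samples)
        scored = screen([g for _, g in scored[:keep]], n_samples)
    scored = screen([g for _, g in scored[:top_k]], refine_samples)
    assert scored, "search produced no valid candidate"
    return chi_given_genealogy(scored[0][1], sigma, final_samples, rng)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def to_newick(g: GenealogyTriplet) -> str:
    """Newick string with integer branch lengths equal to mutation counts.

    The outgroup branch carries a unary node ``m`` marking ``td``, so the
    pre/post-divergence split ``w1/w2`` survives the round trip:
    ``((i:w2)m:w1,(j:y,k:z)n:x)o;``
    """
    i, j, k = g.leaves if g.leaves is not None else ("i", "j", "k")
    return f"(({i}:{g.w2})m:{g.w1},({j}:{g.y},{k}:{g.z})n:{g.x})o;"


def from_newick(newick: str) -> GenealogyTriplet:
    """Parse a rooted 3-leaf genealogy with integer branch mutation counts.

    The cherry (two-leaf clade) provides ``y``, ``z`` and its stem ``x``;
    on the outgroup side the leaf-adjacent edge is ``w2`` and any edges
    above it (the unary ``td`` marker written by :func:`to_newick`) sum
    into ``w1``. A plain two-level tree therefore reads as ``w1 = 0``.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = tree.leaf_nodes()
    if len(leaves) != 3:
        raise ValueError(f"expected 3 leaves, found {len(leaves)}")

    def count(edge) -> int:
        if edge.length is None:
            return 0
        v = float(edge.length)
        if v != int(v) or v < 0:
            raise ValueError(f"branch lengths must be non-negative integers, got {v}")
        return int(v)

    cherry = None
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(c.is_leaf() for c in kids):
            cherry = node
            break
    if cherry is None:
        raise ValueError("no two-leaf cherry found; not a 3-leaf genealogy")
    (jn, kn) = cherry.child_nodes()
    y, z = count(jn.edge), count(kn.edge)
    x = 0
    node = cherry
    while node.parent_node is not None:
        x += count(node.edge)
        node = node.parent_node
    out_leaf = next(l for l in leaves if l not in (jn, kn))
    w2 = count(out_leaf.edge)
    w1 = 0
    node = out_leaf.parent_node
    while node is not None and node.parent_node is not None:
        w1 += count(node.edge)
        node = node.parent_node

    def label(leaf):
        return leaf.taxon.label if leaf.taxon is not None else None

    labels = (label(out_leaf), label(jn), label(kn))
    leaves_ids = None
    if all(s is not None and s.isdigit() for s in labels):
        leaves_ids = tuple(int(s) for s in labels)
    return GenealogyTriplet(w1, w2, x, y, z, leaves=leaves_ids)


def sidecar_json(g: GenealogyTriplet) -> str:
    """JSON sidecar with the topology, branch counts, and Fl."""
    payload = {
        "topology": {"cherry": list(g.leaves[1:]) if g.leaves else ["j", "k"]},
        "w1": g.w1, "w2": g.w2, "x": g.x, "y": g.y, "z": g.z,
        "Fl": fl(g) if g.total > 0 else None,
    }
    return json.dumps(payload, indent=2)
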