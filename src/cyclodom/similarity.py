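"""Trait-vector similarity of triplet members.

For a triplet {i, j, k}, each member ``l`` is summarized by the 6-entry
trait vector

    T_l = (A_li, A_lj, A_lk, A_il, A_jl, A_kl)

— its payoff row against the triplet plus the column of the others'
payoffs against it (the diagonal entry appears in both halves). A single
shift constant (the mean of the 18 entries pooled over the triplet's
three vectors) is subtracted so the average payoff is zero, each vector
is scaled to unit norm, and the three pairwise scalar products measure
how similar the members are. Cyclic-dominance triplets are made of less
similar members than random matrices; non-cyclic ones of more similar
members.
"""

from __future__ import annotations

import numpy as np

from .payoff_core import PayoffMatrix

__all__ = [
    "DegenerateVectorError",
    "trait_vector",
    "center_and_normalize",
    "pairwise_similarities",
    "triplet_similarity_stats",
    "trait_vectors_from_submatrix",
    "batch_similarity_stats",
]


class DegenerateVectorError(ValueError):
    """All entries of a trait vector equal the shift constant, leaving a
    zero vector that cannot be normalized."""


def trait_vector(m: PayoffMatrix, triplet, l: int) -> np.ndarray:
    """Raw (uncentered) trait vector of member ``l`` of ``triplet``."""
    i, j, k = triplet
    if l not in (i, j, k):
        raise ValueError(f"type {l} is not a member of triplet {tuple(triplet)}")
    pl = m.index_of(l)
    pi, pj, pk = (m.index_of(t) for t in (i, j, k))
    return np.array(
        [
            m.A[pl, pi], m.A[pl, pj], m.A[pl, pk],
            m.A[pi, pl], m.A[pj, pl], m.A[pk, pl],
        ]
    )


def trait_vectors_from_submatrix(sub: np.ndarray) -> np.ndarray:
    """The three trait vectors of a 3x3 payoff submatrix, stacked (3, 6).

    Row ``l`` is the trait vector of the type at position ``l``; together
    they cover all nine payoffs, with the diagonals duplicated.
    """
    sub = np.asarray(sub, dtype=float)
    if sub.shape != (3, 3):
        raise ValueError(f"expected 3x3, got {sub.shape}")
    return np.hstack([sub, sub.T])


def center_and_normalize(vectors: np.ndarray) -> np.ndarray:
    """Shift by the pooled mean of all entries, then scale each vector to
    unit norm.

    One shift constant is used for the whole triplet, so adding any global
    constant to all payoffs (the drift toward ever-larger payoffs) leaves
    the result unchanged, as does any global positive rescaling.
    """
    v = np.asarray(vectors, dtype=float)
    shifted = v - v.mean()
    norms = np.linalg.norm(shifted, axis=-1, keepdims=True)
    if np.any(norms <= 0):
        raise DegenerateVectorError("zero trait vector after shifting")
    return shifted / norms


def pairwise_similarities(sub: np.ndarray) -> np.ndarray:
    """The three pairwise scalar products of the processed trait vectors."""
    u = center_and_normalize(trait_vectors_from_submatrix(sub))
    return np.array([u[0] @ u[1], u[0] @ u[2], u[1] @ u[2]])


def triplet_similarity_stats(m: PayoffMatrix, triplet) -> tuple[float, float]:
    """Mean and standard deviation of the three pairwise similarities.

    Invariant under relabeling of the triplet; the mean lies in [-1, 1].
    """
    sims = pairwise_similarities(m.submatrix(list(triplet)))
    return float(sims.mean()), float(sims.std())


def batch_similarity_stats(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (mean, std) of pairwise similarities for (n, 3, 3) stacks."""
    mats = np.asarray(mats, dtype=float)
    v = np.concatenate([mats, mats.transpose(0, 2, 1)], axis=2)  # (n, 3, 6)
    v = v - v.mean(axis=(1, 2), keepdims=True)
    norms = np.linalg.norm(v, axis=2, keepdims=True)
    if np.any(norms <= 0):
        raise DegenerateVectorError("zero trait vector after shifting")
    u = v / norms
    sims = np.stack(
        [
            np.einsum("ni,ni->n", u[:, 0], u[:, 1]),
            np.einsum("ni,ni->n", u[:, 0], u[:, 2]),
            np.einsum("ni,ni->n", u[:, 1], u[:, 2]),
        ],
        axis=1,
    )
    return sims.mean(axis=1), sims.std(axis=1)
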