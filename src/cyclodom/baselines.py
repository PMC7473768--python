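"""Reference values of chi for unstructured null models.

Three nulls bracket what the eco-evolutionary simulation produces:

* random network — the three links of a triplet drawn independently and
  uniformly over the four link types: chi = 2/8 = 0.25 exactly;
* random matrix — 3x3 payoffs i.i.d. from any continuous distribution:
  chi = 2/26 = 1/13, computed exactly by enumerating the 216 equally
  likely combinations of within-column orderings (the classifier only
  ever compares entries within a column);
* mutant-from-pair — a random resident pair extended by a mutant of the
  first resident through the inheritance kernel: chi ~ 0.02, showing how
  parent-offspring payoff correlation suppresses cyclic dominance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .payoff_core import (
    CODE_CYCLIC,
    CODE_NONCYCLIC,
    classify_triplet_batch,
)
from .triplet_stats import UndefinedStatisticError

__all__ = [
    "BaselineResult",
    "chi_random_network",
    "chi_random_matrix_exact",
    "chi_random_matrix_mc",
    "chi_mutant_from_pair",
]


@dataclass(frozen=True)
class BaselineResult:
    name: str
    chi: float
    method: str  # "exact-enumeration" | "monte-carlo"
    n: int       # enumeration size or Monte-Carlo sample count
    stderr: float = 0.0
    exact: Fraction | None = None
    detail: dict | None = None


def chi_random_network() -> BaselineResult:
    """Exact chi when the three links are independent and uniform.

    Each unordered pair is dominance-one-way, dominance-the-other-way,
    bistable, or coexisting with probability 1/4; of the 4^3 = 64
    assignments, 8 are all-dominance, of which 2 are cyclic.
    """
    # link states per pair (p beats q, q beats p, or neither)
    states = ["pq", "qp", "bistable", "coexist"]
    pairs = [(0, 1), (0, 2), (1, 2)]
    n_cyclic = n_noncyclic = 0
    for combo in itertools.product(states, repeat=3):
        if any(s in ("bistable", "coexist") for s in combo):
            continue
        wins = [0, 0, 0]
        for (p, q), s in zip(pairs, combo):
            wins[p if s == "pq" else q] += 1
        if wins == [1, 1, 1]:
            n_cyclic += 1
        else:
            n_noncyclic += 1
    exact = Fraction(n_cyclic, n_cyclic + n_noncyclic)
    return BaselineResult(
        name="random-network",
        chi=float(exact),
        method="exact-enumeration",
        n=4**3,
        exact=exact,
        detail={
            "cyclic_configs": n_cyclic,
            "noncyclic_configs": n_noncyclic,
            "p_all_dominance": float(Fraction(n_cyclic + n_noncyclic, 64)),
        },
    )


def chi_random_matrix_exact() -> BaselineResult:
    """Exact chi for i.i.d. continuous payoff entries.

    The triplet classifier compares payoffs only within columns, so for
    i.i.d. continuous entries the class is a function of the three
    within-column orderings alone — 6^3 = 216 equally likely cases.
    Representative rank matrices are fed through the real classifier.
    """
    ranks = list(itertools.permutations([0.0, 1.0, 2.0]))
    mats = np.array(
        [np.column_stack(cols) for cols in itertools.product(ranks, repeat=3)]
    )
    codes = classify_triplet_batch(mats)
    n_cyclic = int((codes == CODE_CYCLIC).sum())
    n_noncyclic = int((codes == CODE_NONCYCLIC).sum())
    exact = Fraction(n_cyclic, n_cyclic + n_noncyclic)
    return BaselineResult(
        name="random-matrix-exact",
        chi=float(exact),
        method="exact-enumeration",
        n=len(mats),
        exact=exact,
        detail={
            "cyclic_configs": n_cyclic,
            "noncyclic_configs": n_noncyclic,
            "p_all_dominance": float(Fraction(n_cyclic + n_noncyclic, len(mats))),
        },
    )


def _mc_result(name: str, codes: np.ndarray, n_samples: int) -> BaselineResult:
    n_cyc = int((codes == CODE_CYCLIC).sum())
    n_dom = n_cyc + int((codes == CODE_NONCYCLIC).sum())
    if n_dom == 0:
        raise UndefinedStatisticError("no dominance triplets sampled; chi undefined")
    est = n_cyc / n_dom
    se = float(np.sqrt(est * (1 - est) / n_dom))
    return BaselineResult(
        name=name, chi=est, method="monte-carlo", n=n_samples, stderr=se,
        detail={"n_dominance": n_dom},
    )


def chi_random_matrix_mc(
    n_samples: int,
    rng: np.random.Generator | int | None = None,
    distribution: str = "normal",
) -> BaselineResult:
    """Monte-Carlo chi for i.i.d. 3x3 payoff matrices.

    Any continuous i.i.d. entry law gives the same answer (the class
    depends only on within-column orderings); ``distribution`` may be
    "normal" or "uniform" to exercise that invariance.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if distribution == "normal":
        mats = rng.standard_normal((n_samples, 3, 3))
    elif distribution == "uniform":
        mats = rng.random((n_samples, 3, 3))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return _mc_result("random-matrix-mc", classify_triplet_batch(mats), n_samples)


def chi_mutant_from_pair(
    n_samples: int,
    sigma: float = 1.0,
    rng: np.random.Generator | int | None = None,
    parent: str = "first",
) -> BaselineResult:
    """Chi when the third type is a mutant of a random resident pair.

    Residents get i.i.d. standard-normal payoffs; the mutant inherits the
    parent's row, column, and diagonal entries plus independent
    ``Normal(0, sigma^2)`` noise. By exchangeability the parent choice is
    irrelevant; ``parent="random"`` averages over it as a check.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    A = np.zeros((n_samples, 3, 3))
    A[:, :2, :2] = rng.standard_normal((n_samples, 2, 2))
    xi = rng.normal(0.0, sigma, size=(n_samples, 5))
    if parent == "first":
        p = np.zeros(n_samples, dtype=int)
    elif parent == "random":
        p = rng.integers(0, 2, size=n_samples)
    else:
        raise ValueError(f"unknown parent {parent!r}")
    rows = np.arange(n_samples)
    q = 1 - p  # the other resident
    A[rows, 2, p] = A[rows, p, p] + xi[:, 0]
    A[rows, 2, q] = A[rows, p, q] + xi[:, 1]
    A[rows, p, 2] = A[rows, p, p] + xi[:, 2]
    A[rows, q, 2] = A[rows, q, p] + xi[:, 3]
    A[rows, 2, 2] = A[rows, p, p] + xi[:, 4]
    return _mc_result("mutant-from-pair", classify_triplet_batch(A), n_samples)
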