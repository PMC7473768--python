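"""Shared fixtures: a scaled-down simulation ensemble reused by the
physics and acceptance tests, plus derived triplet data."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cyclodom import cli_io, triplet_stats
from cyclodom.payoff_core import (
    CODE_CYCLIC,
    CODE_NONCYCLIC,
    classify_triplet_batch,
)

#: desk-scale study conditions: same demographic rates as the full-scale
#: study (lambda_b=0.9, lambda_d=0.4, sigma=1) but a richer mutation supply
#: (alpha=1e-3 -> N ~ 500, mu=5e-3) so the rapid-mutation regime is reached
#: within a few hundred mutation events.
ENSEMBLE_CONFIG = cli_io.ExperimentConfig(
    lambda_b=0.9,
    lambda_d=0.4,
    alpha=1e-3,
    mu=5e-3,
    sigma=1.0,
    t_mut_max=400,
    n_realizations=12,
    seed=20,
    steady_state_window=0.5,
)

#: start of the steady-state window used by the fixture-based tests
TAIL_START = 200


@pytest.fixture(scope="session")
def scaled_ensemble() -> cli_io.EnsembleSummary:
    return cli_io.run_ensemble(ENSEMBLE_CONFIG, keep_results=True)


@pytest.fixture(scope="session")
def tail_triplet_submatrices(scaled_ensemble):
    """Cyclic and non-cyclic 3x3 payoff submatrices harvested from the
    steady-state window (every 5th snapshot, to thin autocorrelation)."""
    cyc, non = [], []
    for res in scaled_ensemble.results:
        if res.extinct:
            continue
        for snap in res.snapshots:
            if snap.t_mut < TAIL_START or snap.t_mut % 5 or snap.n < 3:
                continue
            combos = np.array(list(itertools.combinations(range(snap.n), 3)))
            subs = snap.A[combos[:, :, None], combos[:, None, :]]
            codes = classify_triplet_batch(subs)
            cyc.append(subs[codes == CODE_CYCLIC])
            non.append(subs[codes == CODE_NONCYCLIC])
    return np.concatenate(cyc), np.concatenate(non)


@pytest.fixture(scope="session")
def tail_lifespan_records(scaled_ensemble):
    """Lifespan records of dominance triplets in the steady-state window
    of the first three surviving realizations."""
    all_records = []
    n_used = 0
    for res in scaled_ensemble.results:
        if res.extinct:
            continue
        nets = [
            (t, net)
            for t, net in triplet_stats.snapshot_networks(res.snapshots)
            if t >= TAIL_START
        ]
        all_records.append(triplet_stats.track_lifespans(nets))
        n_used += 1
        if n_used == 3:
            break
    return all_records
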