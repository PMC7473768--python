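"""Payoff map, mutation kernel, and pair/triplet classifiers."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclodom.payoff_core import (
    CODE_CYCLIC,
    CODE_MIXED,
    CODE_NONCYCLIC,
    ModelParams,
    PairClass,
    PayoffMatrix,
    TieError,
    TripletClass,
    classify_pair,
    classify_triplet,
    classify_triplet_batch,
    competition_death_rate,
    death_rate_matrix,
    mutate_payoffs,
    remove_types,
)

finite_payoff = st.floats(
    min_value=-50, max_value=50, allow_nan=False, allow_infinity=False
)


class TestCompetitionDeathRate:
    @pytest.mark.parametrize(
        "a, alpha, expected",
        [
            (0.0, 5e-6, 1.000005),
            (math.log(1000), 5e-6, 0.001005),
            (0.0, 1.0, 2.0),
        ],
    )
    def test_values(self, a, alpha, expected):
        assert competition_death_rate(a, alpha) == pytest.approx(expected, rel=1e-9)

    def test_huge_payoff_clamps_to_alpha(self):
        # the exp(-A) term underflows to exactly 0 beyond the clamp
        assert competition_death_rate(1e6, 5e-6) == 5e-6
        assert competition_death_rate(800.0, 1e-3) == 1e-3

    def test_monotone_decreasing_and_above_alpha(self):
        rates = [competition_death_rate(a, 5e-6) for a in np.linspace(-5, 100, 50)]
        assert all(r > 0 for r in rates)
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert all(r >= 5e-6 for r in rates)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_payoff_rejected(self, bad):
        with pytest.raises(ValueError):
            competition_death_rate(bad, 1e-3)

    def test_matrix_form_matches_scalar(self):
        A = np.array([[0.0, 3.0], [-2.0, 1000.0]])
        d = death_rate_matrix(A, 1e-4)
        for i in range(2):
            for j in range(2):
                assert d[i, j] == competition_death_rate(A[i, j], 1e-4)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "payoffs, expected",
        [
            ((1, 2, 0, 0), PairClass.DOM_FIRST),
            ((0, 0, 1, 2), PairClass.DOM_SECOND),
            ((1, 0, 0, 1), PairClass.BISTABLE),
            ((0, 1, 1, 0), PairClass.COEXIST),
        ],
    )
    def test_sign_rules(self, payoffs, expected):
        assert classify_pair(*payoffs) is expected

    def test_exact_tie_raises(self):
        with pytest.raises(TieError):
            classify_pair(1.0, 2.0, 1.0, 0.0)
        with pytest.raises(TieError):
            classify_pair(1.0, 2.0, 0.0, 2.0)

    @given(finite_payoff, finite_payoff, finite_payoff, finite_payoff)
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetry(self, aii, aij, aji, ajj):
        if aii == aji or aij == ajj:
            return  # ties are handled by their own test
        forward = classify_pair(aii, aij, aji, ajj)
        backward = classify_pair(ajj, aji, aij, aii)
        assert backward is forward.swapped()


CYCLIC_EXAMPLE = np.array([[3, 5, 0], [1, 4, 6], [4, 2, 5]], dtype=float)
NONCYCLIC_EXAMPLE = np.array([[5, 5, 5], [1, 4, 6], [1, 2, 3]], dtype=float)
MIXED_EXAMPLE = np.array([[2, 0, 0], [1, 1, 0], [0, 0.5, 3]], dtype=float)


class TestClassifyTriplet:
    def test_cyclic_example_with_orientation(self):
        out = classify_triplet(CYCLIC_EXAMPLE)
        assert out.kind is TripletClass.CYCLIC
        # type 0 beats 1, 1 beats 2, 2 beats 0
        assert out.orientation == (0, 1, 2)

    def test_noncyclic_example_source_sink(self):
        out = classify_triplet(NONCYCLIC_EXAMPLE)
        assert out.kind is TripletClass.NONCYCLIC
        assert out.source == 0 and out.sink == 2

    def test_mixed_example(self):
        assert classify_triplet(MIXED_EXAMPLE).kind is TripletClass.MIXED

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            A = rng.standard_normal((3, 3))
            kind = classify_triplet(A).kind
            for perm in itertools.permutations(range(3)):
                p = list(perm)
                assert classify_triplet(A[np.ix_(p, p)]).kind is kind

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(2)
        mats = rng.standard_normal((500, 3, 3))
        codes = classify_triplet_batch(mats)
        lookup = {
            TripletClass.CYCLIC: CODE_CYCLIC,
            TripletClass.NONCYCLIC: CODE_NONCYCLIC,
            TripletClass.MIXED: CODE_MIXED,
        }
        for m, c in zip(mats, codes):
            assert lookup[classify_triplet(m).kind] == c

    def test_class_depends_only_on_column_orderings(self):
        # replacing each column by its within-column ranks preserves the class
        rng = np.random.default_rng(3)
        mats = rng.standard_normal((10_000, 3, 3))
        ranks = np.argsort(np.argsort(mats, axis=1), axis=1).astype(float)
        assert np.array_equal(
            classify_triplet_batch(mats), classify_triplet_batch(ranks)
        )


class TestMutatePayoffs:
    def setup_method(self):
        self.rng = np.random.default_rng(7)
        self.m = PayoffMatrix((3, 5), np.array([[1.0, 2.0], [3.0, 4.0]]))

    def test_grows_by_one_and_preserves_old_block(self):
        out = mutate_payoffs(self.m, 5, sigma=1.0, rng=self.rng)
        assert out.n == 3
        assert out.type_ids == (3, 5, 6)
        assert np.array_equal(out.A[:2, :2], self.m.A)

    def test_zero_noise_limit_copies_parent(self):
        out = mutate_payoffs(self.m, 3, sigma=1e-300, rng=self.rng)
        assert out.A[2, :2] == pytest.approx([1.0, 2.0])
        assert out.A[:2, 2] == pytest.approx([1.0, 3.0])
        assert out.A[2, 2] == pytest.approx(1.0)

    def test_unknown_parent_rejected(self):
        with pytest.raises(KeyError):
            mutate_payoffs(self.m, 99, sigma=1.0, rng=self.rng)

    def test_new_entry_moments(self):
        # parent row (0, 0): new entries are Normal(0, sigma^2) draws
        sigma = 1.5
        base = PayoffMatrix((0, 1), np.zeros((2, 2)))
        rng = np.random.default_rng(11)
        draws = []
        for _ in range(10_000):
            out = mutate_payoffs(base, 0, sigma, rng)
            draws.extend([*out.A[2, :], *out.A[:2, 2]])
        draws = np.asarray(draws)
        n = draws.size
        assert abs(draws.mean()) < 3 * sigma / np.sqrt(n)
        assert draws.var() == pytest.approx(sigma**2, rel=0.05)

    def test_mutate_then_remove_is_identity(self):
        out = mutate_payoffs(self.m, 3, sigma=2.0, rng=self.rng)
        back = remove_types(out, {out.type_ids[-1]})
        assert back.type_ids == self.m.type_ids
        assert np.array_equal(back.A, self.m.A)


class TestRemoveTypes:
    def test_survivor_entries_bit_identical(self):
        m = PayoffMatrix((1, 2, 3), np.arange(9, dtype=float).reshape(3, 3))
        out = remove_types(m, {2})
        assert out.type_ids == (1, 3)
        assert np.array_equal(out.A, m.A[np.ix_([0, 2], [0, 2])])

    def test_remove_none_is_identity(self):
        m = PayoffMatrix((1, 2), np.eye(2))
        out = remove_types(m, set())
        assert out.type_ids == m.type_ids and np.array_equal(out.A, m.A)

    def test_remove_all_flags_extinction(self):
        m = PayoffMatrix((1, 2), np.eye(2))
        out = remove_types(m, {1, 2})
        assert out.n == 0

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            remove_types(PayoffMatrix((1,), np.eye(1)), {9})


class TestPayoffMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PayoffMatrix((1, 1), np.eye(2))  # duplicate ids
        with pytest.raises(ValueError):
            PayoffMatrix((1, 2), np.eye(3))  # shape mismatch
        with pytest.raises(ValueError):
            PayoffMatrix((1,), np.array([[np.nan]]))

    def test_csv_round_trip(self, tmp_path):
        m = PayoffMatrix((0, 4, 7), np.random.default_rng(0).standard_normal((3, 3)))
        path = tmp_path / "payoffs.csv"
        m.to_csv(path)
        back = PayoffMatrix.from_csv(path)
        assert back.type_ids == m.type_ids
        assert np.allclose(back.A, m.A)

    def test_explicit_new_id_collision_rejected(self):
        m = PayoffMatrix((0, 1), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            mutate_payoffs(m, 0, 1.0, np.random.default_rng(0), new_id=1)


class TestModelParams:
    def test_defaults_are_the_study_conditions(self):
        p = ModelParams()
        assert (p.lambda_b, p.lambda_d) == (0.9, 0.4)
        assert (p.alpha, p.mu, p.sigma) == (5e-6, 1e-5, 1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_b": 0.3, "lambda_d": 0.4},  # birth below death
            {"alpha": 0.0},
            {"mu": 1.5},
            {"sigma": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
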