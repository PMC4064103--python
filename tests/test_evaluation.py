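import itertools
import math
import random

import numpy as np
import pytest

from hierfold import (
    SecondaryStructure,
    accuracy,
    bootstrap_ci,
    extract_gbig,
    permutation_test,
    robustness_experiment,
    sample_substructure,
)
from hierfold.evaluation import DEFAULT_ALPHAS
from hierfold.fixtures import generate_fixtures
from hierfold.structures import crosses, is_pseudoknot_free


class TestAccuracy:
    def test_perfect_prediction(self):
        s = SecondaryStructure([(1, 10), (2, 9)])
        rec = accuracy(s, s)
        assert rec.sensitivity == rec.ppv == rec.f_measure == 1.0

    def test_zero_denominator_rule(self):
        ref = SecondaryStructure([(1, 10)])
        rec = accuracy(SecondaryStructure(), ref)
        assert rec.ppv == 0.0 and rec.f_measure == 0.0
        rec2 = accuracy(ref, SecondaryStructure())
        assert rec2.sensitivity == 0.0 and rec2.f_measure == 0.0

    def test_half_overlap(self):
        ref = SecondaryStructure([(1, 10), (2, 9), (3, 8), (4, 7)])
        pred = SecondaryStructure([(1, 10), (2, 9), (12, 20), (13, 19)])
        rec = accuracy(pred, ref)
        assert rec.sensitivity == rec.ppv == rec.f_measure == 0.5

    def test_swap_symmetry_at_equal_sizes(self):
        rng = random.Random(41)
        for _ in range(20):
            a = SecondaryStructure([(1, 10), (2, 9), (15, 25)])
            b = SecondaryStructure([(1, 10), (3, 8), (15, 25)])
            ra, rb = accuracy(a, b), accuracy(b, a)
            assert ra.f_measure == rb.f_measure
            assert ra.sensitivity == rb.ppv and ra.ppv == rb.sensitivity


class TestExtractGbig:
    def test_pk_free_reference_unchanged(self):
        ref = SecondaryStructure([(1, 10), (2, 9)])
        gbig, gsmall = extract_gbig(ref)
        assert gbig == ref and len(gsmall) == 0

    def test_h_type_keeps_larger_stem(self):
        ref = SecondaryStructure([(1, 12), (2, 11), (3, 10), (6, 16), (7, 15)])
        gbig, gsmall = extract_gbig(ref)
        assert set(map(tuple, gbig.pairs)) == {(1, 12), (2, 11), (3, 10)}
        assert set(map(tuple, gsmall.pairs)) == {(6, 16), (7, 15)}

    def test_tie_prefers_smallest_five_prime_index(self):
        ref = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14)])
        gbig, _ = extract_gbig(ref)
        assert len(gbig) == 2
        assert set(map(tuple, gbig.pairs)) == {(1, 10), (2, 9)}

    def _brute_max_pkfree(self, ref):
        best = 0
        for r in range(len(ref.pairs), -1, -1):
            for subset in itertools.combinations(ref.pairs, r):
                if not any(
                    crosses(p, q) for p, q in itertools.combinations(subset, 2)
                ):
                    return r
        return best

    def test_maximum_cardinality_vs_brute_force(self):
        rng = random.Random(42)
        fixtures = generate_fixtures(15, (20, 40), rng=rng)
        for f in fixtures:
            ref = f.reference
            if len(ref) > 12:
                ref = SecondaryStructure(list(ref.pairs)[:12])
            gbig, gsmall = extract_gbig(ref)
            assert is_pseudoknot_free(gbig)
            assert gbig.union(gsmall) == ref
            assert len(gbig) == self._brute_max_pkfree(ref)


class TestSampleSubstructure:
    def setup_method(self):
        self.gbig = SecondaryStructure([(i, 50 - i) for i in range(1, 21)])

    def test_alpha_extremes(self):
        rng = np.random.default_rng(0)
        assert len(sample_substructure(self.gbig, 0.0, rng)) == 0
        assert sample_substructure(self.gbig, 1.0, rng) == self.gbig

    def test_mean_size_within_binomial_bounds(self):
        rng = np.random.default_rng(7)
        draws = 10_000
        sizes = [len(sample_substructure(self.gbig, 0.3, rng)) for _ in range(draws)]
        mean = sum(sizes) / draws
        # mean of `draws` Binomial(20, 0.3) draws: 99% normal bounds around 6
        sd = math.sqrt(20 * 0.3 * 0.7 / draws)
        assert abs(mean - 6.0) < 2.576 * sd * 1.5

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            sample_substructure(self.gbig, 1.5, np.random.default_rng(0))


class TestBootstrap:
    def test_constant_vector_collapses(self):
        ci = bootstrap_ci([0.7] * 12, seed=1)
        assert ci.lower == ci.upper == pytest.approx(0.7)

    def test_ordering(self):
        rng = random.Random(43)
        f = [rng.random() for _ in range(30)]
        ci = bootstrap_ci(f, seed=2)
        assert ci.lower <= sum(f) / len(f) + 0.05
        assert ci.lower <= ci.upper

    def test_reproducible_under_seed(self):
        f = [0.1, 0.4, 0.9, 0.3, 0.6]
        a = bootstrap_ci(f, seed=99)
        b = bootstrap_ci(f, seed=99)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_two_point_vector_matches_exhaustive_enumeration(self):
        f = np.array([0.0, 0.0, 1.0, 1.0])
        # exhaustive: all 4^4 resamples of size 4
        means = [
            np.mean([f[i] for i in pick])
            for pick in itertools.product(range(4), repeat=4)
        ]
        exact_lo, exact_hi = np.percentile(means, [2.5, 97.5])
        ci = bootstrap_ci(f, resamples=200_000, seed=3)
        assert ci.lower == pytest.approx(exact_lo, abs=0.05)
        assert ci.upper == pytest.approx(exact_hi, abs=0.05)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestPermutation:
    def test_identical_samples_give_p_one(self):
        assert permutation_test([0.2, 0.5, 0.9], [0.9, 0.2, 0.5]) == 1.0

    def test_fully_separated_3v3_exact(self):
        assert permutation_test([1, 1, 1], [0, 0, 0]) == pytest.approx(0.1)

    def test_two_sidedness_swap_invariance(self):
        a, b = [0.9, 0.8, 0.85, 0.7], [0.5, 0.55, 0.6, 0.4]
        assert permutation_test(a, b) == permutation_test(b, a)

    def test_p_in_unit_interval_sampled_path(self):
        rng_a = np.random.default_rng(5)
        a = rng_a.random(12)
        b = rng_a.random(12)
        p = permutation_test(a, b, permutations=500, seed=6, exhaustive_limit=10)
        assert 0.0 <= p <= 1.0

    def test_sampled_path_reproducible(self):
        a = [0.8, 0.7, 0.9, 0.6, 0.75]
        b = [0.5, 0.4, 0.6, 0.3, 0.45]
        p1 = permutation_test(a, b, permutations=2000, seed=8, exhaustive_limit=1)
        p2 = permutation_test(a, b, permutations=2000, seed=8, exhaustive_limit=1)
        assert p1 == p2


class TestRobustnessDriver:
    def test_default_grid_has_21_values(self):
        assert len(DEFAULT_ALPHAS) == 21
        assert DEFAULT_ALPHAS[0] == 0.01 and DEFAULT_ALPHAS[-1] == 0.99
        assert DEFAULT_ALPHAS[1:-1] == tuple(round(0.05 * k, 2) for k in range(1, 20))

    def test_default_replicates_is_100(self):
        import inspect

        sig = inspect.signature(robustness_experiment)
        assert sig.parameters["replicates"].default == 100

    def test_driver_table_shape_and_failure_handling(self, model):
        rng = random.Random(44)
        fixtures = generate_fixtures(2, (25, 35), rng=rng, kinds=("htype",))
        dataset = [(f.name, f.sequence, f.reference) for f in fixtures]
        calls = {"n": 0}

        def flaky_predictor(seq, g):
            calls["n"] += 1
            if calls["n"] == 3:
                raise RuntimeError("boom")
            return g  # echo the input structure

        with pytest.warns(UserWarning, match="boom"):
            grid = robustness_experiment(
                dataset,
                flaky_predictor,
                alphas=(0.5, 1.0),
                replicates=3,
                seed=11,
            )
        assert len(grid.table) == 2 * 2 * 3
        assert set(grid.table.columns) == {"molecule", "alpha", "replicate", "f_measure"}
        assert len(grid.summary) == 2
        # echoing G_big at alpha=1 scores its fraction of the reference
        at_one = grid.table[grid.table.alpha == 1.0]
        assert (at_one.f_measure > 0).all()
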