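import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casmi import (
    ContingencyTable,
    DiscreteDistribution,
    FrequencyVector,
    casmi_score,
    coverage_t1,
    entropy_pmf,
    entropy_plugin,
    entropy_z,
    kappa_z,
    mi_z,
    triangle_pmf,
)

from conftest import make_table


def fv(counts):
    return FrequencyVector(counts)


def exact_entropy_z(counts):
    """Brute-force bias-corrected entropy in exact rational arithmetic.

    Evaluates the defining double sum, factorial weights and all, with
    Fraction; independent of the package's iterative product scheme.
    """
    n = sum(counts)
    total = Fraction(0)
    for v in range(1, n):
        w = Fraction(n ** (1 + v) * math.factorial(n - 1 - v), math.factorial(n))
        inner = Fraction(0)
        for f in counts:
            pk = Fraction(f, n)
            prod = Fraction(1)
            for j in range(v):
                prod *= 1 - pk - Fraction(j, n)
            inner += pk * prod
        total += Fraction(1, v) * w * inner
    return float(total)


def partitions(n, max_part=None):
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in partitions(n - first, first):
            yield (first,) + rest


class TestEntropyPmf:
    def test_uniform_closed_form(self):
        assert entropy_pmf([1 / 8] * 8) == pytest.approx(math.log(8))

    def test_point_mass(self):
        assert entropy_pmf(DiscreteDistribution({"a": 1.0})) == 0.0

    def test_triangle_distribution(self):
        assert entropy_pmf(triangle_pmf()) == pytest.approx(7.408005, abs=1e-5)

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError):
            entropy_pmf([0.5, 0.6])
        with pytest.raises(ValueError):
            DiscreteDistribution({"a": 0.0, "b": 1.0})


class TestEntropyPlugin:
    def test_two_singletons(self):
        assert entropy_plugin(fv({"a": 1, "b": 1})) == pytest.approx(math.log(2))

    def test_constant_sample(self):
        assert entropy_plugin(fv({"a": 5})) == 0.0

    def test_bounded_by_log_cardinality(self, rng):
        for _ in range(20):
            counts = {i: int(c) for i, c in enumerate(rng.integers(1, 10, 6))}
            assert entropy_plugin(fv(counts)) <= math.log(len(counts)) + 1e-12


class TestEntropyZ:
    def test_two_singletons_hand_value(self):
        # n=2: single v=1 term, weight 2, inner sum 1/2
        assert entropy_z(fv({"a": 1, "b": 1})) == pytest.approx(1.0)

    def test_n1_empty_sum(self):
        assert entropy_z(fv({"a": 1})) == 0.0

    def test_constant_sample(self):
        assert entropy_z(fv({"a": 9})) == 0.0

    def test_matches_exact_oracle_for_all_small_samples(self):
        """Every count multiset with n <= 12 agrees with exact rational
        evaluation of the defining formula to 1e-10."""
        for n in range(2, 13):
            for part in partitions(n):
                counts = {i: f for i, f in enumerate(part)}
                got = entropy_z(fv(counts))
                want = exact_entropy_z(part)
                assert got == pytest.approx(want, abs=1e-10), part

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=15))
    def test_nonnegative_and_above_plugin_for_spread_samples(self, counts):
        v = fv({i: c for i, c in enumerate(counts)})
        assert entropy_z(v) >= 0.0


class TestCoverageT1:
    def test_letters_example(self):
        assert coverage_t1(FrequencyVector.from_labels(list("aaabccdeef"))) == pytest.approx(0.3)

    def test_all_repeated(self):
        assert coverage_t1(fv({"a": 2, "b": 3})) == 0.0

    def test_all_distinct(self):
        assert coverage_t1(fv({i: 1 for i in range(7)})) == 1.0


def build_pair(x_labels, y_labels):
    fx = FrequencyVector.from_labels(x_labels)
    fy = FrequencyVector.from_labels(y_labels)
    joint = FrequencyVector.from_labels(list(zip(x_labels, y_labels)))
    ct = ContingencyTable(dict(joint.counts))
    return fx, fy, ct


class TestMiZ:
    def test_constant_feature_gives_zero(self):
        fx, fy, ct = build_pair(["a"] * 6, ["p", "q", "p", "q", "p", "q"])
        assert mi_z(fx, fy, ct) == pytest.approx(0.0, abs=1e-12)

    def test_identical_variables_equal_their_entropy(self):
        x = ["a", "a", "b", "b", "c", "c"]
        fx, fy, ct = build_pair(x, x)
        assert mi_z(fx, fy, ct) == pytest.approx(entropy_z(fx))

    def test_symmetric_in_arguments(self, rng):
        x = [str(v) for v in rng.integers(0, 3, 40)]
        y = [str(v) for v in rng.integers(0, 4, 40)]
        fx, fy, ct = build_pair(x, y)
        fyx_ct = ContingencyTable({(b, a): c for (a, b), c in ct.joint_counts.items()})
        assert mi_z(fx, fy, ct) == pytest.approx(mi_z(fy, fx, fyx_ct))

    def test_near_zero_under_independence(self, rng):
        x = [str(v) for v in rng.integers(0, 2, 1000)]
        y = [str(v) for v in rng.integers(0, 2, 1000)]
        fx, fy, ct = build_pair(x, y)
        assert abs(mi_z(fx, fy, ct)) < 0.01

    def test_inconsistent_n_rejected(self):
        fx, fy, ct = build_pair(["a", "b"] * 3, ["p", "q"] * 3)
        with pytest.raises(ValueError, match="inconsistent"):
            mi_z(FrequencyVector({"a": 1}), fy, ct)


class TestKappaZ:
    def test_determinate_outcome_scores_one(self):
        x = ["a", "a", "b", "b"]
        fx, fy, ct = build_pair(x, x)
        assert kappa_z(fx, fy, ct) == pytest.approx(1.0)

    def test_constant_feature_scores_zero(self):
        fx, fy, ct = build_pair(["a"] * 6, ["p", "q"] * 3)
        assert kappa_z(fx, fy, ct) == 0.0

    def test_constant_outcome_is_an_error(self):
        fx, fy, ct = build_pair(["a", "b"] * 3, ["p"] * 6)
        with pytest.raises(ValueError, match="constant"):
            kappa_z(fx, fy, ct)

    def test_clamped_to_unit_interval(self, rng):
        # small noisy samples drive the raw estimate outside [0, 1]
        for _ in range(50):
            x = [str(v) for v in rng.integers(0, 4, 12)]
            y = [str(v) for v in rng.integers(0, 3, 12)]
            fx, fy, ct = build_pair(x, y)
            if entropy_z(fy) <= 0:
                continue
            assert 0.0 <= kappa_z(fx, fy, ct) <= 1.0


class TestCasmiScore:
    def test_id_like_feature_scores_zero(self):
        t = make_table({"id": range(8), "y": [0, 1] * 4})
        s = casmi_score(t, ["id"])
        assert s.score == 0.0 and s.coverage == 0.0

    def test_full_coverage_score_equals_kappa(self):
        t = make_table({"f": ["a", "a", "b", "b"] * 3, "y": [0, 0, 1, 1] * 3})
        s = casmi_score(t, ["f"])
        assert s.coverage == 1.0 and s.score == pytest.approx(s.kappa_z)

    def test_u_squares_the_coverage_factor(self, rng):
        labels = [str(v) for v in rng.integers(0, 6, 24)]
        t = make_table({"f": labels, "y": [str(v) for v in rng.integers(0, 2, 24)]})
        s1 = casmi_score(t, ["f"], u=1.0)
        s2 = casmi_score(t, ["f"], u=2.0)
        assert s2.score == pytest.approx(s1.kappa_z * s1.coverage**2)

    def test_monotone_nonincreasing_in_u_below_full_coverage(self, rng):
        labels = [str(v) for v in rng.integers(0, 10, 30)]
        t = make_table({"f": labels, "y": [str(v) for v in rng.integers(0, 2, 30)]})
        scores = [casmi_score(t, ["f"], u=u).score for u in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_invalid_arguments(self, small_table):
        with pytest.raises(ValueError):
            casmi_score(small_table, ["f1"], u=0.0)
        with pytest.raises(ValueError):
            casmi_score(small_table, [])


class TestBiasOrdering:
    def test_plugin_below_hz_below_truth_on_triangle_samples(self, rng):
        """The plug-in estimator underestimates harder than the corrected
        one: over triangle samples at n=100, mean(H_plugin) < mean(H_z) by
        a wide margin and mean(H_z) stays below the true 7.408 + 0.1."""
        pmf = triangle_pmf()
        reps, n = 1000, 100
        counts = rng.multinomial(n, pmf, size=reps)
        hp = np.empty(reps)
        hz = np.empty(reps)
        for i, c in enumerate(counts):
            v = fv({int(j): int(cj) for j, cj in enumerate(c) if cj > 0})
            hp[i] = entropy_plugin(v)
            hz[i] = entropy_z(v)
        H = 7.408005
        assert hz.mean() - hp.mean() > 0.3
        assert hp.mean() < hz.mean() < H + 0.1
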