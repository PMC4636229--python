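"""Beta power moments, pattern probabilities and parameter transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ebeirt as eb
from ebeirt.core import EnumerationCapError, log_beta_power_moment


class TestBetaPowerMoment:
    @pytest.mark.parametrize(
        "a,b,k,expected",
        [
            (3.0223, 1.7173, 0.0, 1.0),                 # y^0 = 1
            (1.112, 0.598, 1.0, 1.112 / (1.112 + 0.598)),  # E[y] = a/(a+b)
            (2.0, 1.0, 2.0, 0.5),                        # int 2y * y^2 dy = 1/2
        ],
    )
    def test_closed_forms(self, a, b, k, expected):
        assert eb.beta_power_moment(eb.TraitDistribution(a, b), k) == pytest.approx(
            expected, abs=1e-14
        )

    def test_fractional_moment_matches_gauss_legendre(self, gl_moment):
        # fixed-order GL is limited to ~1e-10 here by the Beta density's
        # algebraic endpoint behaviour ((1-y)^{b-1} with non-integer b)
        got = eb.beta_power_moment(eb.TraitDistribution(3.0223, 1.7173), 4.0879)
        assert got == pytest.approx(gl_moment(3.0223, 1.7173, 4.0879), abs=1e-9)

    def test_strictly_decreasing_in_k(self):
        dist = eb.TraitDistribution(2.3, 0.9)
        vals = [eb.beta_power_moment(dist, k) for k in (0.1, 0.5, 1, 2, 5, 20)]
        assert all(u > v for u, v in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            eb.TraitDistribution(-1.0, 2.0)
        with pytest.raises(ValueError):
            log_beta_power_moment(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            eb.beta_power_moment(eb.TraitDistribution(1, 1), -0.5)


class TestPatternProb:
    def test_all_ones_is_single_moment(self):
        items = eb.ItemParams([4.0879, 3.4005, 2.5674, 1.0])
        dist = eb.TraitDistribution(3.0223, 1.7173)
        expected = eb.beta_power_moment(dist, sum(items.k))
        assert eb.pattern_prob((1, 1, 1, 1), items, dist) == pytest.approx(
            expected, rel=1e-14
        )

    def test_single_negative_item_is_complement_of_mean(self):
        dist = eb.TraitDistribution(1.7, 2.9)
        p0 = eb.pattern_prob([0], eb.ItemParams([1.0]), dist)
        assert p0 == pytest.approx(dist.b / (dist.a + dist.b), rel=1e-14)

    def test_mixed_pattern_matches_quadrature(self, oracle):
        items = eb.ItemParams([4.0879, 3.4005, 2.5674, 1.0])
        dist = eb.TraitDistribution(3.0223, 1.7173)
        got = eb.pattern_prob((1, 0, 1, 0), items, dist)
        assert got == pytest.approx(oracle((1, 0, 1, 0), items, dist), abs=1e-10)
        assert eb.pattern_log_prob((1, 0, 1, 0), items, dist) == pytest.approx(
            math.log(got)
        )

    def test_oracle_equivalence_over_random_draws(self, oracle, random_params):
        rng = np.random.default_rng(20259)
        for _ in range(200):
            items, dist = random_params(rng)
            x = tuple(rng.integers(0, 2, size=len(items)))
            got = eb.pattern_prob(x, items, dist)
            assert got == pytest.approx(oracle(x, items, dist), abs=1e-8)

    def test_marginal_monotone_in_hardness(self):
        # Pr[x_i = 1] = E[y^k] falls as the item gets harder
        dist = eb.TraitDistribution(3.0, 1.7)
        probs = [
            eb.pattern_prob([1], eb.ItemParams([k]), dist) for k in (0.2, 1, 3, 9)
        ]
        assert all(u > v for u, v in zip(probs, probs[1:]))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            eb.pattern_prob((1, 0), eb.ItemParams([1.0]), eb.TraitDistribution(1, 1))


class TestAllPatternProbs:
    def test_uniform_trait_two_unit_items(self):
        # Under Uniform(0,1): Pr[11] = E[y^2] = 1/3, Pr[10] = Pr[01] = 1/6
        probs = eb.all_pattern_probs(
            eb.ItemParams([1.0, 1.0]), eb.TraitDistribution(1, 1)
        )
        assert probs[(1, 1)] == pytest.approx(1 / 3, abs=1e-14)
        assert probs[(1, 0)] == pytest.approx(1 / 6, abs=1e-14)
        assert probs[(0, 1)] == pytest.approx(1 / 6, abs=1e-14)
        assert probs[(0, 0)] == pytest.approx(1 / 3, abs=1e-14)

    def test_single_item_beta21_square(self):
        probs = eb.all_pattern_probs(eb.ItemParams([2.0]), eb.TraitDistribution(2, 1))
        assert probs[(1,)] == pytest.approx(0.5, abs=1e-14)
        assert probs[(0,)] == pytest.approx(0.5, abs=1e-14)

    def test_normalization_over_random_draws(self, random_params):
        rng = np.random.default_rng(77)
        for _ in range(25):
            M = int(rng.integers(1, 11))
            items, dist = random_params(rng, M=M)
            total = sum(eb.all_pattern_probs(items, dist).values())
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_cap_refused(self):
        items = eb.ItemParams([1.0] * 21)
        with pytest.raises(EnumerationCapError):
            eb.all_pattern_probs(items, eb.TraitDistribution(1, 1))


class TestB1ClosedForm:
    """With b = 1, Pr[x_i=1] = a/(a+k) and k/a = (1-P)/P exactly."""

    @pytest.mark.parametrize("a,k", [(0.7, 0.3), (2.0, 1.0), (5.5, 12.0)])
    def test_marginal_and_odds(self, a, k):
        dist = eb.TraitDistribution(a, 1.0)
        p = eb.beta_power_moment(dist, k)
        assert p == pytest.approx(a / (a + k), rel=1e-13)
        assert k / a == pytest.approx((1 - p) / p, rel=1e-13)


class TestTransforms:
    def test_reference_points(self):
        assert eb.to_unbounded(math.exp(-1), "trait") == pytest.approx(0.0, abs=1e-15)
        assert eb.to_unbounded(1.0, "item") == 0.0

    @given(st.floats(0.01, 0.99), st.floats(0.05, 20.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_double_exponential_identity_and_round_trip(self, y, k):
        # Pr[x=1|xi] = exp(-exp(-(xi - chi))) equals y^k on matched pairs
        xi = eb.to_unbounded(y, "trait")
        chi = eb.to_unbounded(k, "item")
        assert math.exp(-math.exp(-(xi - chi))) == pytest.approx(y**k, abs=1e-12)
        assert eb.from_unbounded(xi, "trait") == pytest.approx(y, abs=1e-12)
        assert eb.from_unbounded(chi, "item") == pytest.approx(k, rel=1e-12)

    def test_half_probability_offset_sign(self):
        # the response function passes 0.5 at xi - chi = -log(log 2) > 0
        offset = -math.log(math.log(2.0))
        assert math.exp(-math.exp(-offset)) == pytest.approx(0.5, abs=1e-15)
        assert offset == pytest.approx(0.3665, abs=5e-5)

    def test_unfolding_trait_map_round_trip(self):
        y = 0.37
        xi = eb.to_unbounded(y, "trait_unfolding")
        assert eb.from_unbounded(xi, "trait_unfolding") == pytest.approx(y, abs=1e-14)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                eb.to_unbounded(bad, "trait")
        with pytest.raises(ValueError):
            eb.to_unbounded(-1.0, "item")


class TestPatternTable:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="empty"):
            eb.PatternTable([], np.array([]), ("A",), (2,))
        with pytest.raises(ValueError, match="duplicate"):
            eb.PatternTable([(0,), (0,)], np.array([1, 2]), ("A",), (2,))
        with pytest.raises(ValueError, match="out of range"):
            eb.PatternTable([(3,)], np.array([1.0]), ("A",), (2,))
        with pytest.raises(ValueError, match="negative"):
            eb.PatternTable([(0,)], np.array([-1.0]), ("A",), (2,))

    def test_group_slicing_and_margins(self, italian):
        g = italian.group_table("African")
        assert g.N == 1007
        assert italian.group_table("EastEuropean").N == 994
        assert 0 < g.marginal(0) < 1
        assert g.joint(0, 1) <= min(g.marginal(0), g.marginal(1))
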