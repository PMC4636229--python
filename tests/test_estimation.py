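"""Start values, likelihood, ML fitting, standard errors and nested tests."""

import math

import numpy as np
import pytest

import ebeirt as eb
from ebeirt.estimation import ParameterIndex, _theta_root

TRUE_K = [4.0879, 3.4005, 2.5674, 1.0]
TRUE_DIST = eb.TraitDistribution(3.0223, 1.7173)


class TestStartValues:
    def test_exact_on_population_table(self):
        # proportions generated exactly from the model invert to Theta = a + b
        items = eb.ItemParams(TRUE_K)
        table = eb.population_table(items, TRUE_DIST, item_labels="ABCD")
        sv = eb.start_values(table, ref_item="D")
        theta = TRUE_DIST.a + TRUE_DIST.b
        assert sv["a"] + sv["b"] == pytest.approx(theta, rel=1e-9)
        assert sv["a"] == pytest.approx(TRUE_DIST.a, rel=1e-9)
        for lab, k in zip("ABCD", TRUE_K):
            assert sv[f"k:{lab}"] == pytest.approx(k, rel=1e-8)

    def test_theta_root_recovers_a_plus_b(self):
        a, b, kj = 3.0223, 1.7173, 2.5674
        p_ref = eb.beta_power_moment(TRUE_DIST, 1.0)
        p_j = eb.beta_power_moment(TRUE_DIST, kj)
        s_j = kj / (a + b)
        assert _theta_root(p_ref, p_j, s_j) == pytest.approx(a + b, rel=1e-9)

    def test_independent_items_excluded_with_fallback(self):
        # exact independence makes every S_j nonpositive -> marginal-odds seeds
        p1, p2 = 0.6, 0.3
        pats, cnts = [], []
        for x1 in (0, 1):
            for x2 in (0, 1):
                pats.append((x1, x2))
                cnts.append((p1 if x1 else 1 - p1) * (p2 if x2 else 1 - p2))
        table = eb.PatternTable(pats, np.array(cnts), ("A", "B"), (2, 2))
        with pytest.warns(UserWarning, match="association"):
            sv = eb.start_values(table, ref_item="B")
        assert sv["k:B"] == 1.0
        assert sv["k:A"] == pytest.approx(sv["a"] * (1 - p1) / p1)

    def test_multi_group_table_rejected(self, italian):
        with pytest.raises(ValueError, match="single-group"):
            eb.start_values(italian)


class TestNegativeLoglik:
    def test_doubling_counts_doubles_value(self, army):
        spec = eb.ModelSpec.from_table(army, anchor="D")
        doubled = eb.PatternTable(
            army.patterns, army.counts * 2, army.item_labels, army.n_categories
        )
        theta = np.array([1.2, 1.0, 0.8, 1.0, 0.5])
        v1 = eb.negative_loglik(theta, spec, army)
        v2 = eb.negative_loglik(theta, spec, doubled)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_value_at_published_estimates_matches_converged_fit(self, army, army_fit):
        index = ParameterIndex(army_fit.spec)
        theta = index.pack(
            {"k:A": 4.0879, "k:B": 3.4005, "k:C": 2.5674, "a": 3.0223, "b": 1.7173}
        )
        assert eb.negative_loglik(theta, army_fit.spec, army) == pytest.approx(
            -army_fit.loglik, abs=0.01
        )

    def test_saturated_single_item_model(self):
        # one free parameter (a, with k = b = 1) saturates a 2-cell table
        table = eb.PatternTable([(0,), (1,)], np.array([60.0, 40.0]), ("A",), (2,))
        spec = eb.ModelSpec.from_table(table, fixed={"k:A": 1.0, "b": 1.0})
        fit = eb.fit_ml(table, spec, eb.FitOptions(compute_se=False))
        # E[y] = a/(a+1) must equal the observed marginal 0.4
        assert fit.estimates["all"]["a"] == pytest.approx(2.0 / 3.0, rel=1e-5)
        expected = 100 * (0.6 * math.log(0.6) + 0.4 * math.log(0.4))
        assert fit.loglik == pytest.approx(expected, abs=1e-8)
        assert fit.lr_chisq == pytest.approx(0.0, abs=1e-7)


class TestFitML:
    def test_population_table_recovery_is_noise_free(self):
        items = eb.ItemParams(TRUE_K)
        table = eb.population_table(items, TRUE_DIST, item_labels="ABCD")
        spec = eb.ModelSpec.from_table(table, anchor="D")
        fit = eb.fit_ml(table, spec, eb.FitOptions(compute_se=False))
        est = fit.estimates["all"]
        for lab, k in zip("ABCD", TRUE_K):
            assert est[f"k:{lab}"] == pytest.approx(k, abs=1e-4)
        assert est["a"] == pytest.approx(TRUE_DIST.a, abs=1e-4)
        assert est["b"] == pytest.approx(TRUE_DIST.b, abs=1e-4)
        assert fit.lr_chisq == pytest.approx(0.0, abs=1e-8)

    def test_unanchored_model_rejected(self, army):
        spec = eb.ModelSpec(
            variant="dichotomous",
            item_labels=army.item_labels,
            n_categories=(2,) * 4,
        )
        with pytest.raises(ValueError, match="not identified"):
            eb.fit_ml(army, spec)

    def test_b1_submodel_satisfies_marginal_odds_relation(self, army):
        spec = eb.ModelSpec.from_table(army, fixed={"k:D": 1.0, "b": 1.0})
        fit = eb.fit_ml(army, spec, eb.FitOptions(compute_se=False))
        est = fit.estimates["all"]
        a = est["a"]
        dist = eb.TraitDistribution(a, 1.0)
        for lab in "ABCD":
            k = est[f"k:{lab}"]
            p = eb.beta_power_moment(dist, k)  # fitted marginal
            assert k / a == pytest.approx((1 - p) / p, rel=1e-10)

    def test_anchor_choice_rescales_estimates(self, army_anchor_fits):
        # k_i^(j) ~= k_i^(h) / k_j^(h): estimates under one normalization map
        # onto any other by dividing through the new anchor's old estimate
        ref = army_anchor_fits["D"].estimates["all"]
        for anchor in "ABC":
            est = army_anchor_fits[anchor].estimates["all"]
            scale = ref[f"k:{anchor}"]
            for lab in "ABCD":
                assert est[f"k:{lab}"] == pytest.approx(
                    ref[f"k:{lab}"] / scale, rel=1e-2
                )

    def test_anchor_choice_barely_moves_fit(self, army_anchor_fits):
        # the model family is not exactly scale invariant (a power of a Beta
        # variable is not Beta), so L^2 varies slightly with the anchor
        l2s = [f.lr_chisq for f in army_anchor_fits.values()]
        assert max(l2s) - min(l2s) < 1.0
        assert all(f.df == 10 for f in army_anchor_fits.values())


class TestMultiGroup:
    def test_df_bookkeeping_across_constraint_ladder(self, italian):
        shared_sets = {
            20: [],
            23: ["k:item1", "k:item2", "k:item4"],
            22: ["a", "b"],
        }
        for df, shared in shared_sets.items():
            spec = eb.ModelSpec.from_table(italian, fixed={"k:item3": 1.0}, shared=shared)
            index = ParameterIndex(spec)
            assert 2 * (italian.n_cells - 1) - index.n_free == df

    def test_likelihood_never_decreases_when_constraints_released(self, italian_ladder):
        m = italian_ladder
        # model 1 nests every other model in the ladder
        for other in (2, 3, 4, 5, 6):
            assert m[other].loglik <= m[1].loglik + 1e-6
        # and within the a,b-shared chain 3 ⊃ 4 ⊃ 5 ⊃ 6
        assert m[4].loglik <= m[3].loglik + 1e-6
        assert m[5].loglik <= m[4].loglik + 1e-6
        assert m[6].loglik <= m[5].loglik + 1e-6

    def test_nested_lr_identical_specs_gives_zero(self, italian_ladder):
        delta, ddf, _ = eb.nested_lr_test(italian_ladder[1], italian_ladder[1])
        assert delta == 0.0 and ddf == 0

    def test_non_nested_specs_rejected(self, italian_ladder):
        # model 2 (hardnesses shared, traits free) vs model 3 (traits shared,
        # hardnesses free): neither constraint set contains the other
        with pytest.raises(ValueError, match="not nested|frees"):
            eb.nested_lr_test(italian_ladder[2], italian_ladder[3])

    def test_different_data_rejected(self, italian_ladder, army_fit):
        with pytest.raises(ValueError, match="different data"):
            eb.nested_lr_test(italian_ladder[1], army_fit)


class TestStandardErrors:
    def test_fixed_parameter_gets_no_se(self, army_fit):
        assert army_fit.standard_errors["all"]["k:D"] is None

    def test_free_parameter_ses_positive(self, army_fit):
        for name, se in army_fit.standard_errors["all"].items():
            if name == "k:D":
                continue
            assert se is not None and se > 0

    def test_recompute_matches_fit(self, army, army_fit):
        ses = eb.standard_errors(army_fit, table=army)
        for name, se in army_fit.standard_errors["all"].items():
            if se is None:
                assert ses["all"][name] is None
            else:
                assert ses["all"][name] == pytest.approx(se, rel=1e-6)


class TestLrFitStats:
    def test_recompute_matches_stored(self, army, army_fit):
        l2, df, p, bic = eb.lr_fit_stats(army_fit, army)
        assert l2 == pytest.approx(army_fit.lr_chisq, abs=1e-10)
        assert df == army_fit.df
        assert p == pytest.approx(army_fit.p_value, abs=1e-12)
        assert bic == pytest.approx(army_fit.bic, abs=1e-10)

    def test_perfect_fit_gives_zero_chisq(self):
        table = eb.population_table(
            eb.ItemParams([2.0, 1.0]), eb.TraitDistribution(2, 1), item_labels="AB"
        )
        spec = eb.ModelSpec.from_table(table, anchor="B")
        fit = eb.fit_ml(table, spec, eb.FitOptions(compute_se=False))
        assert fit.lr_chisq == pytest.approx(0.0, abs=1e-8)
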