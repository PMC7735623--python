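"""Closed-form layer: effective utilities, Luce probabilities, limits,
transformed utility, inflection points, and the structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srdt import (
    ChoiceSet,
    DegenerateDistributionError,
    Lottery,
    SRDTParams,
    UtilitySpec,
    choice_distribution,
    generate_random_lotteries,
    inflection_points,
    limit_choice_probabilities,
    log_effective_utility,
    log_effective_utility_timed,
    lottery_log_weight,
    subjective_probability,
    transformed_utility,
    utility,
)


class TestEffectiveUtility:
    def test_frozen_gain_value(self):
        # u/(1 - e^{-2u/(pD)}) at u=10, p=0.5, D=10
        expect = math.log(10.0 / (1.0 - math.exp(-4.0)))
        assert math.isclose(log_effective_utility(10.0, 0.5, 10.0), expect,
                            rel_tol=1e-14)

    def test_zero_drift_removable_singularity(self):
        assert math.isclose(log_effective_utility(0.0, 0.5, 10.0),
                            math.log(2.5), rel_tol=1e-12)

    def test_series_switch_is_continuous(self):
        lo = log_effective_utility(1e-9, 0.5, 10.0)
        hi = log_effective_utility(1.1e-8 * 2.5, 0.5, 10.0)
        assert abs(lo - math.log(2.5)) < 1e-9
        assert abs(hi - math.log(2.5)) < 1e-8

    def test_tiny_p_limit_is_raw_utility(self):
        # the singular-perturbation limit: lim_{p->0} U_p(o) = u(o) for gains
        assert math.isclose(log_effective_utility(5.0, 1e-9, 10.0),
                            math.log(5.0), rel_tol=1e-12)

    def test_loss_side_is_positive_and_suppressed(self):
        lw = log_effective_utility(-8.0, 0.5, 10.0)
        # |u| e^{-2|u|/(pD)} / (1 - e^{-2|u|/(pD)})
        expect = math.log(8.0) - 3.2 - math.log1p(-math.exp(-3.2))
        assert math.isclose(lw, expect, rel_tol=1e-12)

    def test_deep_loss_finite_log_weight(self):
        lw = log_effective_utility(-1e6, 0.5, 10.0)
        assert np.isfinite(lw) and lw < -1e5

    @pytest.mark.parametrize("bad", [0.0, -0.1])
    def test_zero_probability_is_domain_error(self, bad):
        with pytest.raises(ValueError, match="p = 0|\\(0, 1\\]"):
            log_effective_utility(1.0, bad, 10.0)

    def test_nonpositive_D_rejected(self):
        with pytest.raises(ValueError):
            log_effective_utility(1.0, 0.5, 0.0)


class TestTimedEffectiveUtility:
    def test_frozen_timed_value(self):
        # lam = sqrt(1.2): sqrt(1.2) e^2 / sinh(2 sqrt(1.2))
        lam = math.sqrt(1.2)
        expect = lam * math.exp(2.0) / math.sinh(2 * lam)
        got = math.exp(log_effective_utility_timed(10.0, 0.5, 10.0, 1.0))
        assert math.isclose(got, expect, rel_tol=1e-12)
        assert math.isclose(got, 1.8330837, rel_tol=1e-7)

    def test_large_T_recovers_untimed(self):
        timed = log_effective_utility_timed(10.0, 0.5, 10.0, 1e12)
        untimed = log_effective_utility(10.0, 0.5, 10.0) + math.log(2.0 / 10.0)
        assert abs(timed - untimed) < 1e-6

    def test_T_inf_sentinel_is_exact(self):
        timed = log_effective_utility_timed(10.0, 0.5, 10.0, math.inf)
        untimed = log_effective_utility(10.0, 0.5, 10.0) + math.log(0.2)
        assert timed == pytest.approx(untimed, abs=0)

    def test_small_p_suppression_grows_without_bound(self):
        # finite T removes the singular p -> 0 overweighting
        vals = [log_effective_utility_timed(10.0, p, 10.0, 100.0)
                for p in (1e-2, 1e-4, 1e-6, 1e-8)]
        assert all(np.diff(vals) < 0)
        assert vals[-1] < -1e4

    def test_log_sinh_asymptotic_regime(self):
        # lam/p = 2e6: well past the switch, still finite and accurate
        lw = log_effective_utility_timed(0.0, 1e-6, 2.0, 1.0)
        lam = 1.0
        expect = math.log(lam) + 0.0 - (lam / 1e-6 - math.log(2.0))
        assert math.isclose(lw, expect, rel_tol=1e-12)


class TestLotteryWeight:
    def test_single_sure_branch(self, linear_params):
        L = Lottery("s", [(7.0, 1.0)])
        tot, logs = lottery_log_weight(L, linear_params)
        assert math.isclose(tot, log_effective_utility(7.0, 1.0, 10.0),
                            rel_tol=1e-14)

    def test_equal_branches_double_weight(self, linear_params):
        L = Lottery("d", [(10.0, 0.5), (10.0, 0.5)])
        tot, _ = lottery_log_weight(L, linear_params)
        single = log_effective_utility(10.0, 0.5, 10.0)
        assert math.isclose(tot, single + math.log(2.0), rel_tol=1e-12)

    def test_small_D_limit_is_log_sum_of_utilities(self, birnbaum):
        params = SRDTParams(utility=UtilitySpec(family="linear"), D=0.01)
        tot, _ = lottery_log_weight(birnbaum.lotteries[1], params)
        assert math.isclose(tot, math.log(96 + 90 + 12), rel_tol=1e-10)


class TestChoiceDistribution:
    def test_identical_lotteries_split_evenly(self, linear_params):
        cs = ChoiceSet([
            Lottery("a", [(5.0, 0.5), (1.0, 0.5)]),
            Lottery("b", [(5.0, 0.5), (1.0, 0.5)]),
        ])
        dist = choice_distribution(cs, linear_params)
        np.testing.assert_allclose(dist.probabilities, [0.5, 0.5], atol=1e-14)

    def test_birnbaum_small_D_sequence(self, birnbaum):
        # the D -> 0 closed form: P(L2) -> (96+90+12)/(122+198)
        vals = []
        for D in (10.0, 1.0, 0.1, 0.01):
            params = SRDTParams(utility=UtilitySpec(family="linear"), D=D)
            vals.append(choice_distribution(birnbaum, params)["L2"])
        assert math.isclose(vals[-1], 198.0 / 320.0, rel_tol=1e-9)
        assert all(v > 0.5 for v in vals)

    def test_time_pressure_pair_infinite_time(self, pressure_pair, linear_params):
        dist = choice_distribution(pressure_pair, linear_params)
        assert math.isclose(dist["L1"], 0.4705965, abs_tol=1e-6)

    def test_conditional_weights_sum_to_one(self, birnbaum, linear_params):
        dist = choice_distribution(birnbaum, linear_params)
        for cond in dist.conditional:
            assert math.isclose(cond.sum(), 1.0, abs_tol=1e-12)

    def test_degenerate_weights_raise(self, simple_pair):
        # a pathological time budget makes lambda overflow and every branch
        # weight degenerate; this must surface as a domain error, not NaN
        params = SRDTParams(utility=UtilitySpec(family="linear"),
                            D=1e-300, T=1e-300)
        with pytest.raises(DegenerateDistributionError):
            choice_distribution(simple_pair, params)


class TestSubjectiveProbability:
    def test_huge_D_recovers_objective(self):
        params = SRDTParams(utility=UtilitySpec(family="linear"), D=1e9)
        assert abs(subjective_probability(0.3, 30.0, 30.0, params) - 0.3) < 1e-6

    def test_symmetry_at_half(self, linear_params):
        assert subjective_probability(0.5, 30.0, 30.0, linear_params) == pytest.approx(0.5)

    def test_strong_overweighting_frozen_value(self):
        params = SRDTParams(utility=UtilitySpec(family="linear"), D=20.0)
        assert math.isclose(
            subjective_probability(0.3, 30.0, 30.0, params), 0.4965466,
            abs_tol=1e-6,
        )

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_endpoints_rejected(self, p, linear_params):
        with pytest.raises(ValueError):
            subjective_probability(p, 1.0, 1.0, linear_params)


class TestLimits:
    def test_birnbaum_D_to_0(self, birnbaum, linear_params):
        dist = limit_choice_probabilities(birnbaum, linear_params, "D_to_0")
        assert math.isclose(dist["L2"], 198.0 / 320.0, rel_tol=1e-14)

    def test_D_to_inf_is_uniform(self, birnbaum, linear_params):
        dist = limit_choice_probabilities(birnbaum, linear_params, "D_to_inf")
        np.testing.assert_allclose(dist.probabilities, [0.5, 0.5], atol=0)

    def test_all_loss_limit_concentrates_on_slowest_decay(self, linear_params):
        cs = ChoiceSet([
            Lottery("a", [(-1.0, 0.5), (-20.0, 0.5)]),
            Lottery("b", [(-5.0, 0.5), (-30.0, 0.5)]),
        ])
        dist = limit_choice_probabilities(cs, linear_params, "D_to_0")
        # decay rates 2|u|/p: branch (-1, .5) is slowest -> all mass on a
        assert dist["a"] == pytest.approx(1.0)
        # and the tiny-D closed form agrees
        small = choice_distribution(
            cs, SRDTParams(utility=UtilitySpec(family="linear"), D=1e-3)
        )
        assert small["a"] > 0.999

    def test_gain_limit_matches_small_D_evaluation(self):
        sets = generate_random_lotteries(
            seed=5, n_sets=20, outcome_range=(0.5, 50.0)
        )
        for cs in sets:
            lim = limit_choice_probabilities(
                cs, SRDTParams(utility=UtilitySpec(family="linear"), D=1.0),
                "D_to_0",
            )
            small = choice_distribution(
                cs, SRDTParams(utility=UtilitySpec(family="linear"), D=1e-4)
            )
            np.testing.assert_allclose(
                lim.probabilities, small.probabilities, atol=1e-6
            )


class TestTransformedUtility:
    def test_frozen_value(self):
        # r=1, o=1, p=.5, D=4 (D_p = 1): u = 1-1/e
        u = 1 - math.exp(-1)
        expect = u / (1 - math.exp(-u))
        got = transformed_utility(1.0, 0.5, 1.0, 4.0)
        assert math.isclose(got, expect, rel_tol=1e-14)
        assert math.isclose(got, 1.3491386, rel_tol=1e-7)

    def test_large_gain_approaches_identity(self):
        # "large positive u" means u >> D_p; here u ~ 1 and D_p = 0.01
        o = 5.0
        got = transformed_utility(o, 0.5, 1.0, 0.04)
        u = (1 - math.exp(-o))
        assert math.isclose(got, u, rel_tol=1e-10)

    def test_large_loss_flattens_to_zero(self):
        assert 0.0 <= transformed_utility(-30.0, 0.5, 1.0, 4.0) < 1e-8

    def test_identity_with_log_route(self):
        # the exponent-convention pin: direct form and log route must agree
        os_ = np.linspace(-3.0, 3.0, 25)
        for r in (0.5, 1.0, 2.0, 4.0):
            for p in (0.1, 0.5, 1.0):
                for D in (0.5, 2.0, 10.0, 100.0):
                    direct = transformed_utility(os_, p, r, D)
                    via_log = np.exp(log_effective_utility(
                        utility(UtilitySpec("cara", r=r), os_), p, D
                    ))
                    np.testing.assert_allclose(
                        direct, via_log, rtol=1e-10, atol=1e-300
                    )


class TestInflectionPoints:
    def test_equal_utilities_give_half(self):
        p_star, _ = inflection_points(2.0, 2.0, 1.0, 2.0)
        assert p_star == pytest.approx(0.5)

    def test_three_to_one_ratio(self):
        # choose outcomes with u(oA) = 3 u(oB) under CARA r=1
        oB = -math.log(0.8)   # u = 0.2
        oA = -math.log(0.4)   # u = 0.6
        p_star, _ = inflection_points(oA, oB, 1.0, 2.0)
        assert p_star == pytest.approx(0.75, rel=1e-12)

    def test_curvature_inflection_in_loss_domain(self):
        # r=1, D_p = 1 (p=1, D=2): the convex-to-concave switch sits at o* < 0
        _, o_star = inflection_points(2.0, 2.0, 1.0, 2.0, p=1.0)
        assert o_star < 0.0
        # brute-force confirmation: curvature changes sign across o*
        h = 1e-4
        grid = np.array([o_star - 0.2, o_star + 0.2])
        f = lambda o: transformed_utility(np.array([o - h, o, o + h]), 1.0, 1.0, 2.0)
        curv = [float(np.diff(f(o), 2)[0]) for o in grid]
        assert curv[0] * curv[1] < 0

    def test_no_sign_change_reports_bracket(self):
        with pytest.raises(ValueError, match="bracket"):
            inflection_points(2.0, 2.0, 1.0, 2.0, bracket=(1.0, 2.0))


class TestStructuralInvariants:
    def test_normalization_on_random_sets(self):
        sets = generate_random_lotteries(seed=11, n_sets=100,
                                         lotteries_per_set=3)
        for T in (math.inf, 5.0):
            params = SRDTParams(utility=UtilitySpec(family="linear"), D=7.0, T=T)
            for cs in sets:
                dist = choice_distribution(cs, params)
                assert abs(dist.probabilities.sum() - 1.0) < 1e-12
                assert np.all(dist.probabilities >= 0)

    @settings(max_examples=80, deadline=None)
    @given(
        u=st.floats(-1e6, 1e6),
        p=st.floats(1e-6, 1.0),
        D=st.floats(0.01, 1e4),
    )
    def test_positivity_for_any_real_utility(self, u, p, D):
        lw = log_effective_utility(u, p, D)
        assert not math.isnan(lw)   # log of a strictly positive quantity

    def test_iia_ratio_invariance(self, linear_params):
        a = Lottery("a", [(8.0, 0.4), (1.0, 0.6)])
        b = Lottery("b", [(6.0, 0.7), (2.0, 0.3)])
        c = Lottery("c", [(12.0, 0.2), (0.5, 0.8)])
        two = choice_distribution(ChoiceSet([a, b]), linear_params)
        three = choice_distribution(ChoiceSet([a, b, c]), linear_params)
        r2 = two["a"] / two["b"]
        r3 = three["a"] / three["b"]
        assert math.isclose(r2, r3, rel_tol=1e-12)

    def test_strong_stochastic_transitivity(self):
        rng = np.random.default_rng(21)
        params = SRDTParams(utility=UtilitySpec(family="linear"), D=5.0)
        lots = [
            Lottery(f"L{i}", list(zip(rng.uniform(-5, 20, 2),
                                      [p, 1 - p])))
            for i, p in enumerate(rng.uniform(0.1, 0.9, 300))
        ]
        checked = 0
        for _ in range(1000):
            i, j, k = rng.choice(len(lots), 3, replace=False)
            pij = choice_distribution(ChoiceSet([lots[i], lots[j]]), params).probabilities[0]
            pjk = choice_distribution(ChoiceSet([lots[j], lots[k]]), params).probabilities[0]
            if pij >= 0.5 and pjk >= 0.5:
                pik = choice_distribution(ChoiceSet([lots[i], lots[k]]), params).probabilities[0]
                assert pik >= max(pij, pjk) - 1e-12
                checked += 1
        assert checked > 50

    def test_finite_T_limit_recovery(self, pressure_pair):
        inf_dist = choice_distribution(
            pressure_pair, SRDTParams(utility=UtilitySpec(family="linear"), D=10.0)
        )
        long_dist = choice_distribution(
            pressure_pair,
            SRDTParams(utility=UtilitySpec(family="linear"), D=10.0, T=1e12),
        )
        np.testing.assert_allclose(
            inf_dist.probabilities, long_dist.probabilities, atol=1e-6
        )
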