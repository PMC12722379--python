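import numpy as np
import pytest

from wolbachia_households import (
    MIXED,
    WILDTYPE_ONLY,
    WOLBACHIA_ONLY,
    build_generator,
    class_hitting_probability,
    conditional_hitting_time,
    expected_extinction_time,
    full_params,
    hit_location_probabilities,
    hitting_result,
    invasion_grid,
    min_release_size,
    tutorial_params,
)


class TestTutorialTable:
    def test_invasion_probabilities(self, tut_gen):
        res = hitting_result(tut_gen, WOLBACHIA_ONLY)
        by_state = dict(zip(res.states, res.probability))
        assert by_state[(1, 1)] == pytest.approx(0.524, abs=2e-3)
        assert by_state[(1, 2)] == pytest.approx(0.682, abs=2e-3)
        assert by_state[(2, 1)] == pytest.approx(0.349, abs=2e-3)

    def test_conditional_times(self, tut_gen):
        res = hitting_result(tut_gen, WOLBACHIA_ONLY)
        by_state = dict(zip(res.states, res.time))
        assert by_state[(1, 1)] == pytest.approx(5.03, abs=0.05)
        assert by_state[(1, 2)] == pytest.approx(5.35, abs=0.05)
        assert by_state[(2, 1)] == pytest.approx(7.80, abs=0.05)

    def test_wildtype_complements(self, tut_gen):
        to_w = class_hitting_probability(tut_gen, WOLBACHIA_ONLY)
        to_m = class_hitting_probability(tut_gen, WILDTYPE_ONLY)
        np.testing.assert_allclose(to_w + to_m, 1.0, atol=1e-10)
        by_state = dict(zip(tut_gen.class_states(MIXED), to_m))
        assert by_state[(1, 1)] == pytest.approx(0.477, abs=2e-3)
        assert by_state[(1, 2)] == pytest.approx(0.318, abs=2e-3)
        assert by_state[(2, 1)] == pytest.approx(0.651, abs=2e-3)


class TestHittingStructure:
    def test_location_probabilities_sum_to_class_probability(self, tut_gen):
        total = sum(
            hit_location_probabilities(tut_gen, (0, w)) for w in (1, 2, 3)
        )
        np.testing.assert_allclose(
            total, class_hitting_probability(tut_gen, WOLBACHIA_ONLY), atol=1e-12
        )

    def test_first_jump_decomposition(self, tut_gen):
        # from (2,1) the only route into the infected-only class passes
        # through (1,1), taken with first-jump probability 0.24/0.36
        for w in (1, 2, 3):
            a = dict(zip(tut_gen.class_states(MIXED),
                         hit_location_probabilities(tut_gen, (0, w))))
            assert a[(2, 1)] == pytest.approx((0.24 / 0.36) * a[(1, 1)], rel=1e-10)

    def test_holding_time_identity(self, tut_gen):
        # conditional on invading, the first jump from (2,1) must go to (1,1);
        # the extra expected time is the holding time 1/0.36
        res = hitting_result(tut_gen, WOLBACHIA_ONLY)
        by_state = dict(zip(res.states, res.time))
        assert by_state[(2, 1)] - by_state[(1, 1)] == pytest.approx(1 / 0.36, rel=1e-10)

    def test_target_inside_source_rejected(self, tut_gen):
        with pytest.raises(ValueError):
            hit_location_probabilities(tut_gen, (1, 1), source_label=MIXED)

    def test_probabilities_in_unit_interval(self, full_gen):
        a = class_hitting_probability(full_gen, WOLBACHIA_ONLY)
        assert a.min() >= 0 and a.max() <= 1

    def test_monotone_in_composition(self, full_gen):
        grid = invasion_grid(full_gen).set_index(["m", "w"]).invasion_probability
        for m in range(1, 10):
            for w in range(1, 10):
                assert grid[(m, w + 1)] >= grid[(m, w)] - 1e-12
                assert grid[(m + 1, w)] <= grid[(m, w)] + 1e-12


class TestInvasionGrid:
    def test_shape_and_boundaries(self, full_gen):
        df = invasion_grid(full_gen)
        assert len(df) == 495
        sub = df.set_index(["m", "w"])
        assert sub.loc[(0, 5), "invasion_probability"] == 1.0
        assert sub.loc[(0, 5), "conditional_time"] == 0.0
        assert sub.loc[(5, 0), "invasion_probability"] == 0.0
        assert np.isnan(sub.loc[(5, 0), "conditional_time"])


class TestExtinctionTime:
    def test_full_model_from_seven(self, full_gen):
        tau = expected_extinction_time(full_gen, WOLBACHIA_ONLY)
        by_state = dict(zip(full_gen.class_states(WOLBACHIA_ONLY), tau))
        assert by_state[(0, 7)] == pytest.approx(166.87, abs=0.05)
        assert round(by_state[(0, 7)]) == 167

    def test_increasing_and_saturating(self, full_gen):
        tau = expected_extinction_time(full_gen, WOLBACHIA_ONLY)
        assert np.all(np.diff(tau) > 0)
        # increments shrink: the curve saturates
        assert tau[29] - tau[28] < tau[1] - tau[0]

    def test_pure_death_chain(self):
        # with a negligible birth rate the infected-only class is a linear
        # death chain: E[T from n] = (1/(delta*d)) * sum_{i<=n} 1/i
        p = tutorial_params(C=6, b=1e-12, delta=2.0)
        gen = build_generator(p)
        tau = expected_extinction_time(gen, WOLBACHIA_ONLY)
        rate = p.d * p.delta
        for n in range(1, 7):
            expected = sum(1.0 / i for i in range(1, n + 1)) / rate
            assert tau[n - 1] == pytest.approx(expected, rel=1e-6)

    def test_single_exponential_lifetime(self):
        gen = build_generator(tutorial_params(C=4, b=1e-12, delta=1.2))
        tau = expected_extinction_time(gen, WOLBACHIA_ONLY)
        assert tau[0] == pytest.approx(1.0 / (0.12 * 1.2), rel=1e-6)

    def test_mixed_class_rejected(self, full_gen):
        with pytest.raises(ValueError):
            expected_extinction_time(full_gen, MIXED)


class TestReleaseSize:
    def test_full_model_fixed_total(self, full_gen):
        assert min_release_size(full_gen, 0.9, total=10) == 8

    def test_probability_brackets_threshold(self, full_gen):
        res = hitting_result(full_gen, WOLBACHIA_ONLY)
        by_state = dict(zip(res.states, res.probability))
        assert by_state[(3, 7)] < 0.9 <= by_state[(2, 8)]

    def test_large_resident_population_unreachable(self, full_gen):
        assert min_release_size(full_gen, 0.9, wildtype=15) is None

    def test_tiny_threshold(self, full_gen):
        assert min_release_size(full_gen, 1e-9, total=10) == 1

    def test_argument_validation(self, full_gen):
        with pytest.raises(ValueError):
            min_release_size(full_gen, 1.5, total=10)
        with pytest.raises(ValueError):
            min_release_size(full_gen, 0.9)
        with pytest.raises(ValueError):
            min_release_size(full_gen, 0.9, total=10, wildtype=5)
        with pytest.raises(ValueError):
            min_release_size(full_gen, 0.9, total=31)
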