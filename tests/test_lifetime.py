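import numpy as np
import pytest

import wakeupcea as w
from wakeupcea.lifetime import MarkovState


class TestLifeTable:
    def test_synthetic_probabilities_non_decreasing(self, life_table):
        blended = 0.6 * life_table.qx_male + 0.4 * life_table.qx_female
        assert np.all(np.diff(blended) >= 0)

    def test_near_immortal_limit(self):
        table = w.synthesize_life_table(makeham_a=1e-12, makeham_b=1e-12)
        assert np.all(table.qx_male[:-1] < 1e-6)

    def test_formula_at_age_65(self, life_table):
        # direct Gompertz-Makeham evaluation with the default parameters
        expected = 1.0 - np.exp(-(0.0002 + 0.00003 * 1.1**65))
        assert life_table.blended_qx(65.0, 0.6) == pytest.approx(expected, rel=1e-12)

    def test_file_round_trip(self, life_table, tmp_path):
        path = tmp_path / "lt.tsv"
        life_table.to_file(path)
        loaded = w.LifeTable.from_file(path)
        np.testing.assert_allclose(loaded.qx_male, life_table.qx_male)

    def test_age_beyond_table_is_certain_death(self, life_table):
        assert life_table.blended_qx(500.0, 0.6) == 1.0


class TestBackgroundMortality:
    def test_hr_one_leaves_table_probability(self, params, life_table):
        p = w.annual_nonstroke_death_prob(70.0, params.demographics, life_table, 1.0)
        assert p == pytest.approx(life_table.blended_qx(70.0, 0.6))

    def test_hazard_scale_adjustment(self, params):
        # p=0.10 with HR 2.37 -> 1 - 0.9^2.37
        table = w.LifeTable(np.array([65.0]), np.array([0.10]), np.array([0.10]))
        p = w.annual_nonstroke_death_prob(65.0, params.demographics, table, 2.37)
        assert p == pytest.approx(1.0 - 0.9**2.37)
        assert p == pytest.approx(0.221, abs=1e-3)

    def test_zero_probability_stays_zero(self, params):
        table = w.LifeTable(np.array([65.0]), np.array([0.0]), np.array([0.0]))
        assert w.annual_nonstroke_death_prob(65.0, params.demographics, table, 2.37) == 0.0


class TestRecurrentStrokeDestination:
    def test_from_mrs3_uniform_over_4_and_5(self, rng):
        draws = [w.recurrent_stroke_destination(3, rng) for _ in range(100_000)]
        counts = np.bincount(draws, minlength=6)
        assert counts[4] / len(draws) == pytest.approx(0.5, abs=0.01)
        assert counts[5] / len(draws) == pytest.approx(0.5, abs=0.01)

    def test_from_mrs0_uniform_over_five_states(self, rng):
        draws = [w.recurrent_stroke_destination(0, rng) for _ in range(100_000)]
        counts = np.bincount(draws, minlength=6)
        assert counts[0] == 0
        for m in range(1, 6):
            assert counts[m] / len(draws) == pytest.approx(0.2, abs=0.01)

    def test_mrs5_has_no_worse_non_death_state(self, rng):
        assert w.recurrent_stroke_destination(5, rng) == 5


class TestStepOneCycle:
    def test_quiet_cycle_accrues_state_utility_and_cost(self, params, rng,
                                                        zero_mortality_table):
        state = MarkovState(1, 65.0)
        nxt, utility, cost = w.step_one_cycle(
            state, params, zero_mortality_table, rng, force_recurrence=False
        )
        assert (utility, cost) == (0.8, 5_293.0)
        assert nxt.mrs == 1 and nxt.age == 66.0

    def test_severe_state_annual_cost(self, params, rng, zero_mortality_table):
        _, _, cost = w.step_one_cycle(
            MarkovState(4, 65.0), params, zero_mortality_table, rng,
            force_recurrence=False,
        )
        assert cost == 13_557.0

    def test_forced_fatal_recurrence(self, params, rng, life_table):
        nxt, _, cost = w.step_one_cycle(
            MarkovState(2, 65.0), params, life_table, rng,
            force_recurrence=True, force_fatal=True,
        )
        assert nxt.mrs == 6
        assert cost == 5_293.0 + 20_079.0

    def test_dead_state_rejected(self, params, rng, life_table):
        with pytest.raises(w.ValidationError):
            w.step_one_cycle(MarkovState(6, 65.0), params, life_table, rng)


class TestSimulateLifetime:
    def test_dead_on_entry_returns_zeros(self, params, rng, life_table):
        result = w.simulate_lifetime(6, params, life_table, rng)
        assert (result.life_years, result.qalys, result.cost) == (0.0, 0.0, 0.0)

    def test_discounted_annuity_closed_form(self, params, rng, zero_mortality_table):
        """Utility 1, no mortality/recurrence, horizon H: QALYs = sum 1.03^-t."""
        params.utilities.utility_by_mrs = (1.0,) * 6
        params.progression.annual_recurrent_stroke_probability = 0.0
        params.demographics.max_age = 65.0 + 20
        result = w.simulate_lifetime(0, params, zero_mortality_table, rng)
        annuity = sum(1.03 ** -t for t in range(1, 21))
        assert result.qalys == pytest.approx(annuity, rel=1e-9)
        assert result.life_years == pytest.approx(annuity, rel=1e-9)

    def test_undiscounted_life_years_equal_horizon(self, params, rng,
                                                   zero_mortality_table):
        params.progression.annual_recurrent_stroke_probability = 0.0
        params.demographics.annual_discount_rate = 0.0
        params.demographics.max_age = 65.0 + 15
        result = w.simulate_lifetime(2, params, zero_mortality_table, rng)
        assert result.life_years == pytest.approx(15.0)

    def test_discounting_reduces_totals(self, params, life_table):
        base = params.copy()
        base.demographics.annual_discount_rate = 0.0
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(7)
        undisc = w.simulate_lifetime(2, base, life_table, rng1)
        disc = w.simulate_lifetime(2, params, life_table, rng2)
        assert disc.life_years <= undisc.life_years
        assert disc.qalys <= undisc.qalys
        assert disc.cost <= undisc.cost

    def test_qalys_bounded_by_life_years(self, params, rng, life_table):
        for mrs in range(6):
            result = w.simulate_lifetime(mrs, params, life_table, rng)
            assert 0.0 <= result.qalys <= result.life_years


class TestVectorisedEngine:
    def test_matches_scalar_engine_in_expectation(self, params, life_table):
        n = 20_000
        rng = np.random.default_rng(42)
        ly_v, q_v, c_v = w.simulate_lifetimes(np.full(n, 3), params, life_table, rng)
        rng2 = np.random.default_rng(43)
        scalars = [w.simulate_lifetime(3, params, life_table, rng2) for _ in range(4000)]
        assert np.mean(ly_v) == pytest.approx(
            np.mean([s.life_years for s in scalars]), rel=0.03
        )

    def test_survival_independent_of_initial_mrs_without_excess_hazards(
        self, params, zero_mortality_table
    ):
        """HR=1 everywhere and no recurrence: life years identical across mRS."""
        params.progression.nonstroke_death_hazard_ratio_by_mrs = (1.0,) * 6
        params.progression.annual_recurrent_stroke_probability = 0.0
        table = w.synthesize_life_table()  # real mortality, equal across states
        rng = np.random.default_rng(5)
        means = []
        for mrs in range(6):
            ly, _, _ = w.simulate_lifetimes(np.full(20_000, mrs), params, table, rng)
            means.append(np.mean(ly))
        assert max(means) - min(means) < 0.15  # Monte-Carlo error only


class TestCohortExpectation:
    def test_agrees_with_monte_carlo_within_half_percent(
        self, params, life_table, mrs_dist
    ):
        """Deterministic matrix engine vs 10^5-patient Monte Carlo on QALYs."""
        probs = np.array(mrs_dist.untreated)
        expected = w.cohort_expectation(probs, params, life_table)
        rng = np.random.default_rng(11)
        initial = rng.choice(7, size=100_000, p=probs)
        ly, qalys, cost = w.simulate_lifetimes(initial, params, life_table, rng)
        assert np.mean(qalys) == pytest.approx(expected.qalys, rel=0.005)
        assert np.mean(ly) == pytest.approx(expected.life_years, rel=0.005)
        assert np.mean(cost) == pytest.approx(expected.cost, rel=0.01)

    def test_annuity_closed_form(self, params, zero_mortality_table):
        params.utilities.utility_by_mrs = (1.0,) * 6
        params.progression.annual_recurrent_stroke_probability = 0.0
        params.demographics.max_age = 65.0 + 30
        probs = np.zeros(7)
        probs[2] = 1.0
        result = w.cohort_expectation(probs, params, zero_mortality_table)
        annuity = sum(1.03 ** -t for t in range(1, 31))
        assert result.qalys == pytest.approx(annuity, rel=1e-6)

    def test_dead_mass_contributes_nothing(self, params, life_table):
        probs = np.zeros(7)
        probs[6] = 1.0
        result = w.cohort_expectation(probs, params, life_table)
        assert result.life_years == 0.0 and result.cost == 0.0
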