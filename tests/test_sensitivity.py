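import numpy as np
import pytest

import wakeupcea as w
from wakeupcea.sensitivity import PSAEntry, default_psa_spec, fit_psa_distribution

N_SMALL = 3_000  # inner simulation size for analysis-level tests


class TestDistributionFitting:
    def test_sensitivity_beta_recovers_interval_endpoints(self):
        entry = PSAEntry("diagnostic.sensitivity", "beta", 0.62, 0.57, 0.67)
        sampler = fit_psa_distribution(entry)
        assert sampler.dist.mean() == pytest.approx(0.62, rel=1e-6)
        assert sampler.ppf(0.025) == pytest.approx(0.57, abs=0.01)
        assert sampler.ppf(0.975) == pytest.approx(0.67, abs=0.01)

    def test_lognormal_interval_log_midpoint(self):
        entry = PSAEntry("treatment_effect.odds_ratios[0]", "lognormal", 1.75, 1.35, 2.27)
        sampler = fit_psa_distribution(entry)
        lo, hi = sampler.ppf(0.025), sampler.ppf(0.975)
        assert np.sqrt(lo * hi) == pytest.approx(np.exp(np.log(1.75) - 0.5 * (
            np.log(2.27 / 1.35) / 3.919928) ** 2), rel=1e-3)
        assert hi / lo == pytest.approx(2.27 / 1.35, rel=1e-6)
        assert sampler.dist.mean() == pytest.approx(1.75, rel=1e-6)

    def test_gamma_iqr_fit(self):
        entry = PSAEntry("timing.wake_to_hospital_minutes", "gamma", 51.0, 36.0, 72.0, "iqr")
        sampler = fit_psa_distribution(entry)
        assert sampler.dist.mean() == pytest.approx(51.0, rel=1e-9)
        assert sampler.ppf(0.75) / sampler.ppf(0.25) == pytest.approx(2.0, rel=1e-6)

    def test_fixed_family_degenerate(self, rng):
        sampler = fit_psa_distribution(PSAEntry("x", "fixed", 3.14))
        assert sampler.sample(rng) == 3.14

    def test_dirichlet_mean_recovers_base(self, rng, mrs_dist):
        entry = PSAEntry("mrs_distribution", "dirichlet", tuple(mrs_dist.untreated))
        sampler = fit_psa_distribution(entry)
        draws = np.array([sampler.sample(rng) for _ in range(5_000)])
        np.testing.assert_allclose(draws.mean(axis=0), mrs_dist.untreated, atol=0.005)

    def test_infeasible_fit_names_parameter(self):
        entry = PSAEntry("utilities.utility_by_mrs[2]", "beta", 0.65, 0.68, 0.9)
        with pytest.raises(w.FitError, match="0.65"):
            fit_psa_distribution(entry)

    def test_sampler_moments_recovered_in_simulation(self, rng):
        """Fitted samplers hit their target mean within 1% over 10^5 draws."""
        for entry in (
            PSAEntry("a", "beta", 0.78, 0.72, 0.84),
            PSAEntry("b", "gamma", 488.0, 390.0, 586.0),
            PSAEntry("c", "lognormal", 1.26, 1.05, 1.51),
        ):
            sampler = fit_psa_distribution(entry)
            draws = sampler.sample(rng, size=100_000)
            assert np.mean(draws) == pytest.approx(entry.base, rel=0.01)

    def test_default_spec_all_entries_fit(self, mrs_dist):
        for entry in default_psa_spec(mrs_dist):
            fit_psa_distribution(entry)


class TestOneWay:
    def test_zero_effect_parameter_has_zero_spread(self, params, mrs_dist, life_table):
        """male_fraction is inert when the life-table sex columns coincide."""
        entries = w.one_way_analysis(
            params,
            [("demographics.male_fraction", 0.4, 0.8),
             ("costs.mri_cost", 390.0, 586.0)],
            n=N_SMALL, seed=7, mrs_dist=mrs_dist, life_table=life_table,
        )
        by_path = {e.path: e for e in entries}
        assert by_path["demographics.male_fraction"].spread == pytest.approx(0.0, abs=1e-9)
        assert entries[0].spread >= entries[-1].spread  # sorted descending

    def test_icer_monotone_in_mri_cost(self, params, mrs_dist, life_table):
        entries = w.one_way_analysis(
            params, [("costs.mri_cost", 390.0, 586.0)],
            n=N_SMALL, seed=7, mrs_dist=mrs_dist, life_table=life_table,
        )
        e = entries[0]
        assert e.icer_high > e.icer_low

    def test_base_endpoints_reproduce_base_icer(self, params, mrs_dist, life_table):
        """Degenerate range at the base value returns the base-case ICER exactly."""
        base_icer = w.run_comparison(params, n=N_SMALL, seed=7, mrs_dist=mrs_dist,
                                     life_table=life_table)[2].icer
        entries = w.one_way_analysis(
            params, [("diagnostic.sensitivity", 0.62, 0.62)],
            n=N_SMALL, seed=7, mrs_dist=mrs_dist, life_table=life_table,
        )
        assert entries[0].icer_low == entries[0].icer_high == base_icer


class TestTwoWay:
    def test_degenerate_corners(self, params, mrs_dist, life_table):
        df, frontier = w.two_way_sensitivity_specificity(
            params, [0.0, 1.0], [1.0], n=N_SMALL, seed=7,
            mrs_dist=mrs_dist, life_table=life_table,
        )
        lookup = df.set_index(["sensitivity", "specificity"]).optimal
        # Se=0, Sp=1: MRI cost with no treatment benefit
        assert lookup[(0.0, 1.0)] == "no_treatment"
        # perfect triage with beneficial odds ratios
        assert lookup[(1.0, 1.0)] == "mri_based"

    def test_optimality_monotone_in_specificity(self, params, mrs_dist, life_table):
        df, frontier = w.two_way_sensitivity_specificity(
            params, [0.62], [0.0, 0.5, 0.9, 1.0], n=N_SMALL, seed=7,
            mrs_dist=mrs_dist, life_table=life_table,
        )
        optimal = df.sort_values("specificity").optimal.tolist()
        flips = sum(a != b for a, b in zip(optimal, optimal[1:]))
        assert flips <= 1  # once MRI becomes optimal it stays optimal
        if frontier is not None:
            assert all(
                o == "mri_based"
                for s, o in zip(df.specificity, df.optimal) if s >= frontier
            )


class TestThresholdSearch:
    def test_bisection_brackets_the_sign_flip(self, params, mrs_dist, life_table):
        """The late-treatment odds ratio threshold separates the two optimal
        regions: the final bracket holds opposite incremental-NMB signs."""
        found = w.threshold_search(
            params, "treatment_effect.beyond_last_band_or", (0.2, 5.0),
            n=20_000, seed=7, tol=0.1, mrs_dist=mrs_dist, life_table=life_table,
        )
        assert found is not None
        lo, hi = found.bracket
        assert hi - lo <= 0.1 + 1e-12
        assert lo <= found.value <= hi

        def inmb(value):
            p = params.copy()
            p.treatment_effect.beyond_last_band_or = value
            ref, alt, _ = w.run_comparison(p, n=20_000, seed=7, mrs_dist=mrs_dist,
                                           life_table=life_table)
            return (w.net_monetary_benefit(alt, 100_000)
                    - w.net_monetary_benefit(ref, 100_000))

        # same seed => deterministic objective; the bracket straddles the flip
        assert np.sign(inmb(lo)) != np.sign(inmb(hi))

    def test_no_sign_change_returns_none(self, params, mrs_dist, life_table):
        # male_fraction is inert with identical life-table sex columns
        found = w.threshold_search(
            params, "demographics.male_fraction", (0.4, 0.8), n=N_SMALL, seed=7,
            mrs_dist=mrs_dist, life_table=life_table,
        )
        assert found is None


class TestPSA:
    def test_all_fixed_spec_gives_identical_draws(self, params, mrs_dist, life_table):
        spec = [PSAEntry("diagnostic.sensitivity", "fixed", 0.62)]
        df, ceac = w.run_psa(
            params, spec, draws=5, n_per_draw=N_SMALL, seed=3,
            mrs_dist=mrs_dist, life_table=life_table,
        )
        assert df.delta_qalys.nunique() == 1
        assert df.delta_cost.nunique() == 1

    def test_ceac_complementarity_and_bounds(self, params, mrs_dist, life_table):
        df, ceac = w.run_psa(
            params, draws=8, n_per_draw=N_SMALL, seed=3,
            wtp_grid=(0, 50_000, 100_000, 200_000),
            mrs_dist=mrs_dist, life_table=life_table,
        )
        assert ((ceac.p_mri_based >= 0) & (ceac.p_mri_based <= 1)).all()
        np.testing.assert_allclose(ceac.p_mri_based + ceac.p_no_treatment, 1.0)

    def test_ceac_non_decreasing_when_qaly_gains_dominate(self, params, mrs_dist,
                                                          life_table):
        df, ceac = w.run_psa(
            params, draws=8, n_per_draw=N_SMALL, seed=3,
            wtp_grid=(0, 50_000, 100_000, 200_000, 500_000),
            mrs_dist=mrs_dist, life_table=life_table,
        )
        if (df.delta_qalys > 0).mean() >= 0.75:
            tail = ceac.p_mri_based.iloc[1:].to_numpy()
            assert np.all(np.diff(tail) >= -1e-12)
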