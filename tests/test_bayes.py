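"""Two-state Bayesian model: priors, fitting, probability profiles,
threshold queries and classification."""

import numpy as np
import pytest

from ptmdelta.bayes import (
    PosteriorDraws,
    ProbabilityProfile,
    build_model_spec,
    classify_observation,
    fit_state_model,
    gamma_moment_match,
    probability_profile,
    threshold_query,
)
from ptmdelta.delta import kde_density
from ptmdelta.reference import ReferenceStats


REF = ReferenceStats(residue="LYS", nucleus="CE", n_kept=400, n_removed=8,
                     mean=41.9, sd=1.6, q1=40.9, q3=42.9,
                     fence_low=38.0, fence_high=45.8)


def _point_mass_draws(mu_a, sigma_a, mu_b, sigma_b, n=50):
    ones = np.ones(n)
    return PosteriorDraws(mu_a=mu_a * ones, sigma_a=sigma_a * ones,
                          nu_a=30 * ones, mu_b=mu_b * ones,
                          sigma_b=sigma_b * ones, nu_b=30 * ones)


class TestModelSpec:
    def test_gamma_moment_match(self):
        assert gamma_moment_match(2.0, 1.0) == (4.0, 2.0)

    def test_gamma_moment_match_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_moment_match(0.0, 1.0)

    def test_prior_locations_are_empirical_means(self, rng):
        a = kde_density(rng.normal(-10.1, 1.0, 200), state="mono")
        b = kde_density(rng.normal(0.0, 1.0, 200), state="unmod")
        spec = build_model_spec(a, b, REF)
        assert spec.state_a.mu_loc == pytest.approx(a.samples.mean())
        assert spec.state_b.mu_loc == pytest.approx(b.samples.mean())
        assert spec.state_a.mu_scale == 0.35
        assert spec.state_a.nu_mean == 30.0

    def test_sigma_prior_centered_on_reference_sd(self, rng):
        a = kde_density(rng.normal(0, 1, 50))
        b = kde_density(rng.normal(1, 1, 50))
        spec = build_model_spec(a, b, REF)
        mean = spec.state_a.sigma_shape / spec.state_a.sigma_rate
        assert mean == pytest.approx(REF.sd)

    def test_nonpositive_reference_sd_rejected(self, rng):
        bad = ReferenceStats("LYS", "CE", 4, 0, 41.9, 0.0, 41, 42, 40, 44)
        a = kde_density(rng.normal(0, 1, 50))
        with pytest.raises(ValueError, match="sd"):
            build_model_spec(a, a, bad)


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        ya = rng.normal(-10.0, 2.0, 500)
        yb = rng.normal(0.0, 2.0, 500)
        a, b = kde_density(ya, state="A"), kde_density(yb, state="B")
        spec = build_model_spec(a, b, REF, seed=7)
        return spec, ya, yb, fit_state_model(spec, ya, yb)

    def test_parameter_recovery(self, fitted):
        """Posterior mean of μ recovers a Normal(−10, 2), n=500 truth
        within 0.3 ppm (≈ 3 standard errors)."""
        _, _, _, draws = fitted
        assert abs(draws.mu_a.mean() - (-10.0)) < 0.3
        assert abs(draws.mu_b.mean() - 0.0) < 0.3

    def test_sigma_draws_positive(self, fitted):
        _, _, _, draws = fitted
        assert (draws.sigma_a > 0).all()
        assert (draws.sigma_b > 0).all()
        assert (draws.nu_a > 0).all()

    def test_diagnostics_recorded_and_converged(self, fitted):
        _, _, _, draws = fitted
        assert draws.diagnostics["max_rhat"] < 1.05
        assert draws.diagnostics["a_ess_mu"] > 100

    def test_seed_determinism(self, fitted):
        spec, ya, yb, draws = fitted
        again = fit_state_model(spec, ya, yb)
        assert np.array_equal(draws.mu_a, again.mu_a)
        assert np.array_equal(draws.sigma_b, again.sigma_b)

    def test_too_few_samples_rejected(self, fitted):
        spec, ya, yb, _ = fitted
        with pytest.raises(ValueError, match="at least 10"):
            fit_state_model(spec, ya[:5], yb)

    def test_calibration_under_generating_state(self, fitted):
        """Data drawn from state A's fitted predictive is, on average,
        assigned more to A than to B."""
        spec, ya, yb, draws = fitted
        grid = np.linspace(-18, 8, 300)
        prof = probability_profile(draws, grid)
        rng = np.random.default_rng(5)
        fresh = rng.normal(draws.mu_a.mean(), draws.sigma_a.mean(), 200)
        fresh = fresh[(fresh > grid[0]) & (fresh < grid[-1])]
        p_a = np.interp(fresh, prof.grid, prof.mean_curve)
        assert p_a.mean() > (1 - p_a).mean()

    def test_uncertainty_band_shrinks_with_n(self):
        """Profile uncertainty bands are narrower at n=500 than at n=50."""
        rng = np.random.default_rng(3)
        widths = {}
        for n in (50, 500):
            ya = rng.normal(-6.0, 2.0, n)
            yb = rng.normal(0.0, 2.0, n)
            a, b = kde_density(ya, state="A"), kde_density(yb, state="B")
            spec = build_model_spec(a, b, REF, seed=11,
                                    n_warmup=400, n_draws=400)
            draws = fit_state_model(spec, ya, yb)
            grid = np.linspace(-10, 4, 200)
            prof = probability_profile(draws, grid)
            widths[n] = float(np.mean(prof.band_high - prof.band_low))
        assert widths[500] < widths[50]


class TestProbabilityProfile:
    def test_pointwise_normalization(self, rng):
        draws = PosteriorDraws(
            mu_a=rng.normal(-5, 0.3, 100), sigma_a=np.abs(rng.normal(2, 0.2, 100)),
            nu_a=np.full(100, 30.0), mu_b=rng.normal(0, 0.3, 100),
            sigma_b=np.abs(rng.normal(2, 0.2, 100)), nu_b=np.full(100, 30.0))
        prof = probability_profile(draws, np.linspace(-10, 5, 100))
        assert ((prof.curves >= 0) & (prof.curves <= 1)).all()
        # P_B per draw is 1 − P_A by construction of the two-state ratio
        assert np.allclose(prof.mean_curve,
                           prof.curves.mean(axis=0))

    def test_symmetric_case_half_at_zero(self):
        prof = probability_profile(_point_mass_draws(-2, 1.5, 2, 1.5),
                                   np.linspace(-5, 5, 201))
        mid = prof.at(0.0)
        assert mid["p_a"] == pytest.approx(0.5, abs=1e-9)

    def test_collapsed_posterior_matches_logistic_closed_form(self):
        """Point-mass posteriors at unit σ and means ±1 give
        P_A(Δ) = logistic(2Δ): P_A(ln(4)/2) = 0.8."""
        prof = probability_profile(_point_mass_draws(1.0, 1.0, -1.0, 1.0),
                                   np.linspace(-4, 4, 4001))
        x = np.log(4) / 2
        assert prof.at(x)["p_a"] == pytest.approx(0.8, abs=1e-4)
        logistic = 1 / (1 + np.exp(-2 * prof.grid))
        assert np.allclose(prof.mean_curve, logistic, atol=1e-9)

    def test_monotone_between_means_for_equal_sigma(self):
        prof = probability_profile(_point_mass_draws(3.0, 1.2, -3.0, 1.2),
                                   np.linspace(-3, 3, 100))
        assert (np.diff(prof.mean_curve) > 0).all()

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            probability_profile(_point_mass_draws(1, 1, -1, 1),
                                np.array([0.0, -1.0, 1.0]))


class TestThresholdQuery:
    def test_constant_one_profile_returns_whole_grid(self):
        grid = np.linspace(-2, 2, 50)
        prof = ProbabilityProfile(grid=grid, curves=np.ones((1, 50)),
                                  mean_curve=np.ones(50), band_low=np.ones(50),
                                  band_high=np.ones(50), prior_a=0.5)
        assert threshold_query(prof, 0.8) == [(-2.0, 2.0)]

    def test_logistic_boundary_at_half_log4(self):
        grid = np.linspace(-4, 4, 8001)
        prof = probability_profile(_point_mass_draws(1.0, 1.0, -1.0, 1.0), grid)
        regions = threshold_query(prof, 0.8, "A")
        assert len(regions) == 1
        assert regions[0][0] == pytest.approx(np.log(4) / 2, abs=2e-3)
        assert regions[0][1] == grid[-1]

    def test_level_above_maximum_gives_empty(self):
        prof = probability_profile(_point_mass_draws(0.5, 2.0, -0.5, 2.0),
                                   np.linspace(-3, 3, 100))
        assert threshold_query(prof, 0.999) == []

    def test_invalid_level(self):
        prof = probability_profile(_point_mass_draws(1, 1, -1, 1),
                                   np.linspace(-2, 2, 10))
        with pytest.raises(ValueError):
            threshold_query(prof, 1.5)


class TestClassifyObservation:
    @pytest.fixture()
    def profile(self):
        return probability_profile(_point_mass_draws(-10.0, 1.0, 0.0, 1.0),
                                   np.linspace(-15, 5, 500),
                                   state_a="monomethyl", state_b="charged")

    def test_shift_at_reference_mean_gives_delta_zero(self, profile):
        res = classify_observation(REF.mean, "DSS", REF, profile)
        assert res["delta_obs"] == 0.0
        assert res["p_a"] == pytest.approx(profile.at(0.0)["p_a"])

    def test_tms_shift_rereferenced_before_delta(self, profile):
        x = 35.0
        res = classify_observation(x, "TMS", REF, profile)
        assert res["delta_obs"] == pytest.approx((x - 1.7) - REF.mean)

    def test_consistency_with_direct_lookup(self, profile):
        res = classify_observation(32.0, "DSS", REF, profile)
        direct = profile.at(32.0 - REF.mean)
        assert res["p_a"] == direct["p_a"]
        assert res["p_b"] == pytest.approx(1.0 - direct["p_a"])

    def test_out_of_range_refused(self, profile):
        with pytest.raises(ValueError, match="out of calibrated range"):
            classify_observation(100.0, "DSS", REF, profile)


def test_parameter_recovery_coverage_over_seeds():
    """95% credible intervals for μ bracket the truth at close to the
    nominal rate across 20 simulated data sets."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        ya = rng.normal(-10.0, 2.0, 200)
        yb = rng.normal(0.0, 2.0, 200)
        a, b = kde_density(ya, state="A"), kde_density(yb, state="B")
        spec = build_model_spec(a, b, REF, seed=seed,
                                n_walkers=16, n_warmup=300, n_draws=300)
        draws = fit_state_model(spec, ya, yb)
        lo, hi = np.percentile(draws.mu_a, [2.5, 97.5])
        hits += lo <= -10.0 <= hi
    assert hits >= 15  # nominal 19/20, generous Monte-Carlo tolerance
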