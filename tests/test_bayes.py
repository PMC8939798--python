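"""Priors, MAP, DE-MCMC-Z sampler, R-hat and posterior predictive checks."""

import math

import numba
import numpy as np
import pytest
from scipy import stats

from biocal import bayes, synthetic
from biocal.bayes import (
    HierarchicalGrowthModel,
    HierarchicalGrowthSpec,
    SamplerConfig,
    Trace,
    beta_from_mean_sd,
    beta_hdi,
    find_map,
    log_posterior,
    posterior_predictive,
    rhat,
    sample_demcmc_z,
)
from biocal.multirep import make_monod_template


class TestBetaMoments:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [
            (0.6, 0.05, (57.0, 38.0)),
            (0.4, 0.1, (9.2, 13.8)),
            (0.5, math.sqrt(1 / 12), (1.0, 1.0)),
        ],
    )
    def test_moment_matching(self, mean, sd, expected):
        a, b = beta_from_mean_sd(mean, sd)
        assert a == pytest.approx(expected[0], rel=1e-9)
        assert b == pytest.approx(expected[1], rel=1e-9)
        d = stats.beta(a, b)
        assert d.mean() == pytest.approx(mean)
        assert d.std() == pytest.approx(sd)

    def test_infeasible_sd_rejected(self):
        with pytest.raises(ValueError):
            beta_from_mean_sd(0.5, 0.6)

    def test_hdi_has_equal_density_endpoints(self):
        """At an HDI's bounds the density is equal (interior optimum)."""
        a, b = beta_from_mean_sd(0.6, 0.05)
        lo, hi = beta_hdi(a, b, 0.95)
        d = stats.beta(a, b)
        assert d.cdf(hi) - d.cdf(lo) == pytest.approx(0.95, abs=1e-6)
        assert d.pdf(lo) == pytest.approx(d.pdf(hi), rel=1e-3)


class TestPriors:
    def test_lognormal_matches_scipy(self):
        p = bayes.Lognormal(math.log(0.25), 0.1)
        ref = stats.lognorm(s=0.1, scale=0.25)
        for x in (0.1, 0.25, 0.5):
            assert p.logpdf(x) == pytest.approx(ref.logpdf(x))
        assert p.logpdf(-1.0) == -np.inf

    def test_beta_prior_matches_scipy(self):
        p = bayes.BetaPrior(0.4, 0.1)
        assert p.logpdf(0.35) == pytest.approx(stats.beta.logpdf(0.35, 9.2, 13.8))
        assert p.logpdf(1.5) == -np.inf


class TestLogPosterior:
    spec = HierarchicalGrowthSpec()

    def test_empty_dataset_is_prior_only(self):
        lp = log_posterior(self.spec, lambda full: 0.0, rids=["w1", "w2"])
        theta = self.spec.prior_mode_theta(2)
        assert lp(theta) == pytest.approx(self.spec.log_prior(theta))

    def test_negative_offset_outside_support(self):
        lp = log_posterior(self.spec, lambda full: 0.0, rids=["w1"])
        assert lp([0.4, 0.6, 20.0, 0.25, -0.1]) == -np.inf

    def test_worse_fit_decreases_posterior(self):
        """With priors fixed, inflating one well's X0 misfit lowers the value."""
        target = {"X0_w1": 0.25}

        def objective(full):
            return -100.0 * (full["X0_w1"] - target["X0_w1"]) ** 2

        lp = log_posterior(self.spec, objective, rids=["w1"])
        good = lp([0.4, 0.6, 20.0, 0.25, 1.0])
        bad = lp([0.4, 0.6, 20.0, 0.25, 1.4])
        assert bad < good


class TestFindMap:
    def test_priors_only_map_at_prior_mode(self):
        spec = HierarchicalGrowthSpec()
        lp = log_posterior(spec, lambda full: 0.0, rids=["w1", "w2"])
        guess = spec.prior_mode_theta(2) * 1.1
        theta, info = find_map(lp, guess)
        np.testing.assert_allclose(theta, spec.prior_mode_theta(2), atol=1e-3)

    def test_map_is_fixed_point(self):
        spec = HierarchicalGrowthSpec()
        lp = log_posterior(spec, lambda full: 0.0, rids=["w1"])
        theta1, _ = find_map(lp, spec.prior_mode_theta(1) * 1.05)
        theta2, _ = find_map(lp, theta1)
        np.testing.assert_allclose(theta2, theta1, atol=1e-6)

    def test_non_finite_guess_rejected(self):
        with pytest.raises(ValueError):
            find_map(lambda t: -np.inf, [0.0])


@numba.njit(cache=True)
def _std_normal_logp(x):
    return -0.5 * (x[0] ** 2 + x[1] ** 2)


@numba.njit(cache=True)
def _corr_normal_logp(x):
    # bivariate normal, rho = 0.95
    rho = 0.95
    det = 1.0 - rho * rho
    return -0.5 * (x[0] ** 2 - 2 * rho * x[0] * x[1] + x[1] ** 2) / det


class TestDemcmcZ:
    def test_standard_normal_target(self):
        cfg = SamplerConfig(n_tune=2000, n_draws=20000, n_chains=4, seed=1)
        trace = sample_demcmc_z(_std_normal_logp, cfg, np.array([1.0, -1.0]))
        flat = trace.stacked()
        np.testing.assert_allclose(flat.mean(axis=0), [0.0, 0.0], atol=0.05)
        np.testing.assert_allclose(np.cov(flat.T), np.eye(2), atol=0.1)
        assert all(v < 1.01 for v in rhat(trace).values())

    def test_correlated_target_recovers_correlation(self):
        cfg = SamplerConfig(n_tune=2000, n_draws=20000, n_chains=4, seed=2)
        trace = sample_demcmc_z(_corr_normal_logp, cfg, np.array([0.0, 0.0]))
        corr = np.corrcoef(trace.stacked().T)[0, 1]
        assert corr == pytest.approx(0.95, abs=0.05)

    def test_lambda_zero_degenerates_to_random_walk(self):
        cfg = SamplerConfig(n_tune=500, n_draws=2000, n_chains=2, lam=0.0, epsilon=0.5, seed=3)

        def logp(x):
            return -0.5 * float(x @ x)

        trace = sample_demcmc_z(logp, cfg, np.zeros(2))
        assert all(0 < r < 1 for r in trace.acceptance_rates)

    def test_exactly_reproducible(self):
        cfg = SamplerConfig(n_tune=200, n_draws=500, n_chains=2, seed=7)

        def logp(x):
            return -0.5 * float(x @ x)

        t1 = sample_demcmc_z(logp, cfg, np.zeros(3))
        t2 = sample_demcmc_z(logp, cfg, np.zeros(3))
        for c1, c2 in zip(t1.chains, t2.chains):
            np.testing.assert_array_equal(c1, c2)

    def test_python_and_compiled_drivers_agree_statistically(self):
        cfg = SamplerConfig(n_tune=1000, n_draws=8000, n_chains=2, seed=5)
        t_py = sample_demcmc_z(lambda x: float(_std_normal_logp(x)), cfg, np.ones(2))
        t_nb = sample_demcmc_z(_std_normal_logp, cfg, np.ones(2))
        assert t_py.stacked().mean() == pytest.approx(t_nb.stacked().mean(), abs=0.1)
        assert t_py.stacked().std() == pytest.approx(t_nb.stacked().std(), abs=0.1)


class TestRhat:
    def test_constant_chains_report_one(self):
        trace = Trace(chains=[np.ones((100, 1)), np.ones((100, 1))], names=["a"])
        assert rhat(trace)["a"] == 1.0

    def test_disjoint_modes_flagged(self):
        rng = np.random.default_rng(0)
        c1 = rng.normal(-5, 1, (500, 1))
        c2 = rng.normal(5, 1, (500, 1))
        trace = Trace(chains=[c1, c2], names=["a"])
        assert rhat(trace)["a"] > 1.1

    def test_too_few_draws_rejected(self):
        trace = Trace(chains=[np.ones((3, 1)), np.ones((3, 1))], names=["a"])
        with pytest.raises(ValueError):
            rhat(trace)


def tiny_growth_setup(n_wells=3, seed=0, t_max=12.0):
    cfg = synthetic.GrowthExperimentConfig(
        n_wells=n_wells, seed=seed, t_max=t_max,
        sacrifice_times=np.linspace(t_max / 2, t_max, n_wells),
    )
    ds, truth = synthetic.generate_growth_dataset(cfg, return_truth=True)
    model = HierarchicalGrowthModel(
        ds, synthetic.true_biomass_model(), synthetic.true_glucose_model()
    )
    return ds, truth, model


class TestHierarchicalGrowthModel:
    def test_compiled_posterior_matches_generic_route(self):
        """The fixed-step compiled posterior agrees with the adaptive-solver
        reference (independent ODE route) up to discretization tolerance."""
        _, _, model = tiny_growth_setup()
        theta = model.spec.prior_mode_theta(3)
        z = model.z_from_theta(theta)
        log_jac = (
            math.log(theta[0] * (1 - theta[0]))
            + math.log(theta[1] * (1 - theta[1]))
            + float(np.sum(np.log(theta[2:])))
        )
        fast = model.logpost_z(z)
        slow = model.log_posterior_natural(theta) + log_jac
        assert fast == pytest.approx(slow, abs=0.5)

    def test_map_recovers_truth_on_small_dataset(self):
        _, truth, model = tiny_growth_setup()
        theta, info = model.find_map()
        for got, want in zip(theta[:4], (truth["mu_max"], truth["Y_XS"], truth["S0"], truth["X0_mu"])):
            assert got == pytest.approx(want, rel=0.05)

    def test_transform_round_trip(self):
        _, _, model = tiny_growth_setup()
        theta = np.array([0.42, 0.6, 20.0, 0.25, 0.9, 1.0, 1.1])
        np.testing.assert_allclose(model.theta_from_z(model.z_from_theta(theta)), theta)

    def test_converged_chains_cover_truth_on_full_experiment(self, growth28):
        """Long-run reference on the 28-well experiment: with a sampler
        budget long enough to converge (all split-R-hat <= 1.02), the 90%
        HDIs of the four global parameters cover the generating values."""
        ds, truth = growth28
        model = HierarchicalGrowthModel(
            ds, synthetic.true_biomass_model(), synthetic.true_glucose_model()
        )
        trace = model.sample(
            SamplerConfig(n_tune=20000, n_draws=60000, n_chains=4, seed=0)
        )
        rh = rhat(trace)
        flat = trace.to_frame()
        for name, tv in [
            ("mu_max", truth["mu_max"]), ("Y_XS", truth["Y_XS"]),
            ("S0", truth["S0"]), ("X0_mu", truth["X0_mu"]),
        ]:
            assert rh[name] < 1.05, f"{name}: R-hat {rh[name]:.3f}"
            lo, hi = bayes.sample_hdi(flat[name].values, 0.9)
            assert lo <= tv <= hi, f"{name}: HDI [{lo:.4f}, {hi:.4f}] misses {tv}"


class TestPosteriorPredictive:
    def setup_trace(self, model, theta, n=50, spread=0.0):
        rng = np.random.default_rng(0)
        rows = np.tile(theta, (n, 1)) * (1 + spread * rng.standard_normal((n, theta.size)))
        return Trace(chains=[rows], names=model.names)

    def test_zero_noise_bands_collapse_onto_trajectory(self):
        _, truth, model = tiny_growth_setup()
        theta = np.array(
            [truth["mu_max"], truth["Y_XS"], truth["S0"], truth["X0_mu"]]
            + [truth["F_offset"][r] for r in model.rids]
        )
        cal = synthetic.true_biomass_model()
        quiet = synthetic.CalibrationModel(
            independent_key=cal.independent_key,
            dependent_key=cal.dependent_key,
            noise=cal.noise,
            theta=np.concatenate([cal.theta[:5], [1e-9, 0.0], [cal.theta[-1]]]),
            cal_x=cal.cal_x,
            cal_y=cal.cal_y,
        )
        t_grid = np.linspace(0, 6, 10)
        trace = self.setup_trace(model, theta, n=20)
        out = posterior_predictive(
            trace, model.template, model.mapping, {quiet.dependent_key: quiet},
            t_grid, n_samples=20, seed=0, assemble=model.assemble_full_vector,
        )
        rid = model.rids[0]
        band = out[rid][quiet.dependent_key]
        assert np.ptp(band, axis=0).max() < 1e-6

    def test_band_width_grows_with_calibration_scale(self):
        _, truth, model = tiny_growth_setup()
        theta = np.array(
            [truth["mu_max"], truth["Y_XS"], truth["S0"], truth["X0_mu"]]
            + [truth["F_offset"][r] for r in model.rids]
        )
        trace = self.setup_trace(model, theta, n=40)
        widths = []
        for scale0 in (0.1, 0.5):
            cal = synthetic.true_biomass_model()
            scaled = synthetic.CalibrationModel(
                independent_key=cal.independent_key,
                dependent_key=cal.dependent_key,
                noise=cal.noise,
                theta=np.concatenate([cal.theta[:5], [scale0, 0.0], [cal.theta[-1]]]),
                cal_x=cal.cal_x,
                cal_y=cal.cal_y,
            )
            out = posterior_predictive(
                trace, model.template, model.mapping, {scaled.dependent_key: scaled},
                np.linspace(0, 6, 8), n_samples=40, seed=1,
                assemble=model.assemble_full_vector,
            )
            band = out[model.rids[0]][scaled.dependent_key]
            widths.append(np.mean(np.percentile(band, 95, 0) - np.percentile(band, 5, 0)))
        assert widths[1] > widths[0]

    def test_predictive_band_covers_held_out_observations(self):
        """Responses re-simulated at the truth fall inside the 90% band at
        roughly the nominal rate (single-seed sanity check)."""
        ds, truth, model = tiny_growth_setup(seed=3)
        theta = np.array(
            [truth["mu_max"], truth["Y_XS"], truth["S0"], truth["X0_mu"]]
            + [truth["F_offset"][r] for r in model.rids]
        )
        trace = self.setup_trace(model, theta, n=300, spread=0.002)
        cal = synthetic.true_biomass_model()
        rid = model.rids[-1]
        obs = ds[rid][cal.dependent_key]
        out = posterior_predictive(
            trace, model.template, model.mapping, {cal.dependent_key: cal},
            obs.t, n_samples=300, seed=2, assemble=model.assemble_full_vector,
        )
        band = out[rid][cal.dependent_key]
        lo, hi = np.percentile(band, [5, 95], axis=0)
        frac = np.mean((obs.y >= lo) & (obs.y <= hi))
        assert 0.75 <= frac <= 1.0
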