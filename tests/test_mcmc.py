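import numpy as np
import pytest

import fluxbma as fb
from fluxbma.mcmc import (
    beta_full_conditional,
    gp_effects_full_conditional,
    icar_conditional,
    log_sigma_conditional,
    slice_sample_bounded,
)

from _oracles import normal_loglik_sum, ridge_posterior


class TestThetaPriorBounds:
    def test_natural_log_identity(self):
        lo, hi = fb.theta_prior_bounds(1.0, np.e, rho=np.exp(-1.0))
        assert lo == pytest.approx(1.0 / np.e)
        assert hi == pytest.approx(1.0)

    def test_bounds_shrink_to_zero_as_rho_approaches_one(self):
        lo, hi = fb.theta_prior_bounds(0.75, 25.35, rho=1 - 1e-12)
        assert hi < 1e-9

    @pytest.mark.parametrize(
        "d_min,d_max,rho", [(0, 1, 0.05), (2, 1, 0.05), (1, 2, 0.0), (1, 2, 1.0)]
    )
    def test_invalid_inputs_rejected(self, d_min, d_max, rho):
        with pytest.raises(ValueError):
            fb.theta_prior_bounds(d_min, d_max, rho)


class TestExpCorrelation:
    def test_unit_diagonal_and_half_life(self):
        d = np.array([[0.0, np.log(2.0)], [np.log(2.0), 0.0]])
        phi = fb.exp_correlation(d, theta=1.0)
        assert phi[0, 0] == 1.0
        assert phi[0, 1] == pytest.approx(0.5)

    def test_prior_bound_gives_rho_at_extreme_distance(self):
        lo, hi = fb.theta_prior_bounds(0.75, 25.35, rho=0.05)
        phi = fb.exp_correlation(np.array([[0.0, 25.35], [25.35, 0.0]]), theta=lo)
        assert phi[0, 1] == pytest.approx(0.05)
        phi = fb.exp_correlation(np.array([[0.0, 0.75], [0.75, 0.0]]), theta=hi)
        assert phi[0, 1] == pytest.approx(0.05)

    def test_positive_definite_for_delta_one(self, layout):
        d = fb.pairwise_distances(layout).d
        phi = fb.exp_correlation(d, theta=0.3)
        assert np.linalg.eigvalsh(phi).min() > 0


class TestDeviance:
    def test_density_one_gives_zero(self):
        assert fb.deviance(np.array([2.0]), np.array([2.0]), 1.0 / (2 * np.pi)) == pytest.approx(0.0)

    def test_perfect_fit_unit_variance(self):
        y = np.arange(7.0)
        assert fb.deviance(y, y, 1.0) == pytest.approx(7 * np.log(2 * np.pi))

    def test_matches_scipy_logpdf_oracle(self, rng):
        y = rng.normal(size=40)
        mu = rng.normal(size=40)
        s2 = 1.7
        assert fb.deviance(y, mu, s2) == pytest.approx(normal_loglik_sum(y, mu, s2), rel=1e-12)


class TestFullConditionals:
    def test_beta_matches_ridge_closed_form(self, exp_dataset, rng):
        ds, _ = exp_dataset
        _, xmat, _ = ds.design_matrix()
        for _ in range(3):
            resid = rng.normal(size=xmat.shape[0])
            s2 = float(rng.uniform(0.5, 3.0))
            mean, cov = beta_full_conditional(xmat, resid, s2, 1e6)
            o_mean, o_cov = ridge_posterior(xmat, resid, s2, 1e6)
            assert np.allclose(mean, o_mean, rtol=1e-10)
            assert np.allclose(cov, o_cov, rtol=1e-10)

    def test_gp_effects_precision_weighted_mean(self, exp_dataset, rng):
        ds, _ = exp_dataset
        d = fb.pairwise_distances(ds.coords).d
        phi = fb.exp_correlation(d, theta=0.8)
        phi_inv = np.linalg.inv(phi)
        sums = rng.normal(size=ds.n_sites)
        mean, cov = gp_effects_full_conditional(phi_inv, 0.7, sums, ds.n_replicates, 1.4)
        prec = phi_inv / 0.7 + (ds.n_replicates / 1.4) * np.eye(ds.n_sites)
        assert np.allclose(cov, np.linalg.inv(prec), rtol=1e-10)
        assert np.allclose(mean, np.linalg.solve(prec, sums / 1.4), rtol=1e-10)

    def test_icar_prior_mean_is_neighbour_average(self, exp_dataset, rng):
        _, weights = exp_dataset
        u = rng.normal(size=len(weights.w))
        for i in range(len(u)):
            mean, var = icar_conditional(u, i, weights.w.astype(float), 2.0)
            nb = np.flatnonzero(weights.w[i])
            assert mean == pytest.approx(u[nb].mean(), rel=1e-12)
            assert var == pytest.approx(2.0 / len(nb), rel=1e-12)

    def test_slice_sampler_targets_truncated_density(self, rng):
        # sigma | data with flat prior on (0, 5): invariant distribution
        # check via a long chain against the analytic CDF by quantiles
        rss, n = 30.0, 25
        x = 1.0
        chain = []
        for _ in range(4000):
            x = slice_sample_bounded(
                rng, lambda s: log_sigma_conditional(s, rss, n), x, 0.0, 5.0
            )
            chain.append(x)
        chain = np.array(chain[500:])
        # target: sigma^-n exp(-rss / 2 sigma^2); compare mean to numeric
        from scipy.integrate import quad

        dens = lambda s: s ** (-n) * np.exp(-rss / (2 * s * s))
        z, _ = quad(dens, 1e-3, 5.0)
        m, _ = quad(lambda s: s * dens(s) / z, 1e-3, 5.0)
        assert chain.mean() == pytest.approx(m, rel=0.05)


class TestFits:
    def test_reproducible_given_seed(self, exp_dataset):
        ds, _ = exp_dataset
        cfg = fb.McmcConfig(n_iter=400, burn_in=100, thin=2, seed=9)
        a = fb.fit_exp_geostat(ds, config=cfg)
        b = fb.fit_exp_geostat(ds, config=cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.extra["theta"], b.extra["theta"])

    def test_variance_draws_respect_prior_supports(self, exp_fit, icar_fit):
        assert exp_fit.sigma2.max() < 25.0  # sigma ~ U(0,5)
        assert exp_fit.extra["sigma_s2"].max() < 100.0  # sigma_s ~ U(0,10)
        assert icar_fit.extra["sigma_u2"].max() < 100.0  # sigma_u ~ U(0,10)

    def test_theta_within_prior_bounds(self, exp_dataset, exp_fit):
        ds, _ = exp_dataset
        dist = fb.pairwise_distances(ds.coords)
        lo, hi = fb.theta_prior_bounds(dist.d_min, dist.d_max)
        th = exp_fit.extra["theta"]
        assert th.min() >= lo and th.max() <= hi

    def test_independent_recovers_known_coefficients(self, exp_dataset, fast_config):
        ds, _ = exp_dataset
        truth = fb.GenerativeParams()
        params = fb.GenerativeParams(structure="independent")
        sim = fb.simulate_fluxes(ds.coords, ds.X, params, seed=31)
        fit = fb.fit_independent(sim, config=fast_config)
        for name in ("moisture", "temperature"):
            k = fb.COVARIATES.index(name) + 1
            post_mean = fit.beta[:, k].mean()
            post_sd = fit.beta[:, k].std(ddof=1)
            assert abs(post_mean - truth.beta[k]) < 3 * post_sd

    def test_icar_disconnected_graph_rejected(self, exp_dataset, fast_config):
        ds, weights = exp_dataset
        w = weights.w.copy()
        w[0, :] = 0
        w[:, 0] = 0
        broken = fb.SpatialWeights(w=w, boundary=weights.boundary)
        with pytest.raises(ValueError, match="disconnected"):
            fb.fit_icar(ds, broken, config=fast_config)

    def test_icar_u_draws_centred(self, icar_fit):
        assert np.abs(icar_fit.effects.sum(axis=1)).max() < 1e-8

    def test_exp_with_tiny_spatial_variance_matches_independent(
        self, exp_dataset, fast_config, independent_fit
    ):
        ds, _ = exp_dataset
        priors = fb.Priors(sigma_s_bounds=(0.0, 1e-6))
        nested = fb.fit_exp_geostat(ds, priors=priors, config=fast_config)
        for k in (0, 1, 2):
            m1, s1 = nested.beta[:, k].mean(), nested.beta[:, k].std(ddof=1)
            m2, s2 = independent_fit.beta[:, k].mean(), independent_fit.beta[:, k].std(ddof=1)
            assert abs(m1 - m2) < 0.35 * (s1 + s2 + 1e-12) + 4 * (s1 + s2) / np.sqrt(len(nested.beta))
        assert nested.sigma2.mean() == pytest.approx(independent_fit.sigma2.mean(), rel=0.08)

    def test_samples_csv_round_trip(self, icar_fit, tmp_path):
        p = tmp_path / "samples.csv"
        icar_fit.to_csv(p)
        back = fb.PosteriorSamples.from_csv(p, model="icar")
        assert np.allclose(back.beta, icar_fit.beta)
        assert np.allclose(back.effects, icar_fit.effects)
        assert np.allclose(back.extra["sigma_u2"], icar_fit.extra["sigma_u2"])

    def test_icar_variance_recovered_on_regular_grid(self):
        """sigma_u^2 is weakly identified at 16 sites; the posterior median
        should still land within a factor of 2 of truth in most runs."""
        pts = np.array([(i, j) for j in range(4) for i in range(4)], float)
        coords = fb.SiteCoordinates(site_id=np.arange(16), x=pts[:, 0], y=pts[:, 1])
        weights = fb.thiessen_adjacency(coords, (-0.5, -0.5, 3.5, 3.5))
        cfg_moments = fb.DesignConfig(seed=0).covariate_moments
        design = fb.DesignConfig(n_sites=16, seed=0, covariate_moments=cfg_moments)
        truth = 1.78
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            covs = fb.generate_covariates(coords, fb.DesignConfig(n_sites=16, seed=seed))
            params = fb.GenerativeParams(structure="icar", sigma_u2=truth)
            sim = fb.simulate_fluxes(coords, covs, params, weights=weights, seed=seed)
            fit = fb.fit_icar(
                sim, weights, config=fb.McmcConfig(n_iter=3000, burn_in=1000, thin=2, seed=seed)
            )
            med = np.median(fit.extra["sigma_u2"])
            if truth / 2 <= med <= truth * 2:
                hits += 1
        assert hits >= 0.7 * n_rep


class TestConvergenceReport:
    @staticmethod
    def _pseudo_samples(chain: np.ndarray) -> fb.PosteriorSamples:
        n = len(chain)
        return fb.PosteriorSamples(
            model="independent",
            beta=np.column_stack([chain] + [np.random.default_rng(0).normal(size=n)] * 7),
            sigma2=np.ones(n),
            effects=np.zeros((n, 3)),
            deviance=np.ones(n),
        )

    def test_iid_chain_has_no_autocorrelation(self):
        chain = np.random.default_rng(5).normal(size=10_000)
        rep = fb.convergence_report(self._pseudo_samples(chain))
        row = rep.set_index("parameter").loc["b_intercept"]
        assert abs(row["acf_1"]) < 0.05
        assert row["ess"] > 5000

    def test_ar1_chain_recovers_known_autocorrelation(self):
        rng = np.random.default_rng(6)
        n, phi = 20_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        rep = fb.convergence_report(self._pseudo_samples(x))
        row = rep.set_index("parameter").loc["b_intercept"]
        assert row["acf_1"] == pytest.approx(phi, abs=0.03)

    def test_constant_chain_flagged_degenerate(self):
        rep = fb.convergence_report(self._pseudo_samples(np.full(500, 2.5)))
        row = rep.set_index("parameter").loc["b_intercept"]
        assert bool(row["degenerate"])
        assert np.isnan(row["ess"])

    def test_trace_plot_written(self, independent_fit, tmp_path):
        out = tmp_path / "trace.png"
        fb.mcmc.plot_traces(independent_fit, out, parameters=["sigma2", "b_moisture"])
        assert out.stat().st_size > 0
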