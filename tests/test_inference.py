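"""Priors, initialization, engines, envelopes, clusters, model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutspulse.estimators import GutsModel
from gutspulse.inference import (
    PosteriorResult,
    PriorSpec,
    compare_models,
    detect_posterior_clusters,
    fit_posterior_from_logdensity,
    init_from_unit_interval,
    posterior_trajectory_bci,
)
from gutspulse.params import make_sharing_map
from gutspulse.simulate import ExposureScenario


@pytest.fixture(scope="module")
def priors():
    return PriorSpec.defaults(
        "guts_rna_pulse", ["substance_1"],
        make_sharing_map("guts_rna_pulse", "specific"),
    )


class TestInitFromUnitInterval:
    def test_center_maps_to_prior_medians(self, priors):
        vals = init_from_unit_interval(np.zeros(len(priors.labels)), priors)
        np.testing.assert_allclose(
            np.log(list(vals.values())), priors.log_medians(), rtol=1e-12
        )

    def test_endpoint_maps_two_logsd_out(self, priors):
        u = np.zeros(len(priors.labels))
        u[0] = 1.0
        vals = init_from_unit_interval(u, priors)
        med = math.exp(priors.log_medians()[0])
        assert list(vals.values())[0] == pytest.approx(med * math.e**2, rel=1e-12)

    def test_symmetry_about_the_median_on_log_scale(self, priors):
        k = len(priors.labels)
        hi = np.log(list(init_from_unit_interval(np.ones(k), priors).values()))
        lo = np.log(list(init_from_unit_interval(-np.ones(k), priors).values()))
        np.testing.assert_allclose(
            (hi + lo) / 2, priors.log_medians(), rtol=1e-12
        )

    def test_out_of_range_rejected(self, priors):
        u = np.zeros(len(priors.labels))
        u[3] = 1.2
        with pytest.raises(ValueError, match="-1, 1"):
            init_from_unit_interval(u, priors)

    def test_pushforward_is_not_the_prior(self, priors, rng):
        """The bounded initializer is narrower than the prior: the Kolmogorov
        distance between transformed U(-1,1) draws and the prior is large."""
        u = rng.uniform(-1, 1, size=4000)
        mu, sd = priors.log_medians()[0], priors.log_sds()[0]
        x = mu + u * sd
        ks = stats.kstest(x, stats.norm(loc=mu, scale=sd).cdf)
        assert ks.statistic > 0.05
        assert ks.pvalue < 1e-6


class TestEngineLayer:
    def logp(self, x):
        return -0.5 * ((x[0] - 3.0) / 0.5) ** 2

    def test_mcmc_matches_analytic_gaussian_posterior(self):
        starts = np.random.default_rng(0).uniform(-1, 1, size=(5, 1))
        draws, *_ = fit_posterior_from_logdensity(
            self.logp, 1, starts, "mcmc", 4000, np.random.default_rng(1)
        )
        # 3 Monte-Carlo standard errors with a conservative effective n
        mc_se = 0.5 / math.sqrt(len(draws) / 20)
        assert abs(draws.mean() - 3.0) < 3 * mc_se
        assert draws.std() == pytest.approx(0.5, rel=0.15)

    def test_variational_matches_analytic_gaussian_posterior(self):
        starts = np.random.default_rng(0).uniform(-1, 1, size=(5, 1))
        draws, _, losses, best, x_map, _ = fit_posterior_from_logdensity(
            self.logp, 1, starts, "variational", 4000, np.random.default_rng(1)
        )
        assert x_map[0] == pytest.approx(3.0, abs=1e-5)
        assert draws.mean() == pytest.approx(3.0, abs=0.05)
        assert draws.std() == pytest.approx(0.5, rel=0.1)

    def test_seeded_reruns_are_reproducible(self):
        starts = np.random.default_rng(0).uniform(-1, 1, size=(3, 1))
        for engine in ("variational", "mcmc"):
            a = fit_posterior_from_logdensity(
                self.logp, 1, starts, engine, 500, np.random.default_rng(9)
            )[0]
            b = fit_posterior_from_logdensity(
                self.logp, 1, starts, engine, 500, np.random.default_rng(9)
            )[0]
            np.testing.assert_array_equal(a, b)

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError, match="engine"):
            fit_posterior_from_logdensity(
                self.logp, 1, np.zeros((2, 1)), "nuts", 10,
                np.random.default_rng(0),
            )

    def test_simulation_based_calibration_ranks_are_uniform(self):
        """Draw truth from the prior of a conjugate normal model, fit with the
        engine layer, and check the rank of the truth in the posterior draws
        is approximately uniform (reduced-scale SBC)."""
        rng = np.random.default_rng(5)
        prior_mu, prior_sd, noise_sd, n_data = 0.0, 1.0, 0.7, 8
        ranks = []
        for _ in range(40):
            theta = rng.normal(prior_mu, prior_sd)
            data = rng.normal(theta, noise_sd, size=n_data)
            # conjugate posterior is available; the engine must recover it
            def logp(x, data=data):
                return (
                    -0.5 * ((x[0] - prior_mu) / prior_sd) ** 2
                    - 0.5 * np.sum((data - x[0]) ** 2) / noise_sd**2
                )
            draws, *_ = fit_posterior_from_logdensity(
                logp, 1, rng.uniform(-1, 1, (2, 1)), "variational", 200, rng
            )
            ranks.append(np.mean(draws[:, 0] < theta))
        # uniformity of rank statistics (Kolmogorov-Smirnov, generous alpha)
        ks = stats.kstest(ranks, "uniform")
        assert ks.pvalue > 0.01

    def test_engines_agree_on_conjugate_posterior(self):
        """Both engines recover the same posterior (mean within 10%) on a
        data-informed normal model with known posterior."""
        rng = np.random.default_rng(11)
        data = rng.normal(1.7, 0.5, size=12)
        post_var = 1.0 / (1.0 / 4.0 + len(data) / 0.25)
        post_mean = post_var * (data.sum() / 0.25)

        def logp(x):
            return -0.5 * x[0] ** 2 / 4.0 - 0.5 * np.sum((data - x[0]) ** 2) / 0.25

        means = {}
        for engine in ("variational", "mcmc"):
            draws, *_ = fit_posterior_from_logdensity(
                logp, 1, rng.uniform(-1, 1, (3, 1)), engine, 3000,
                np.random.default_rng(2),
            )
            means[engine] = draws.mean()
            assert draws.mean() == pytest.approx(post_mean, rel=0.05)
            assert draws.std() == pytest.approx(math.sqrt(post_var), rel=0.15)
        assert means["mcmc"] == pytest.approx(means["variational"], rel=0.10)

    def test_engine_posteriors_overlap_on_a_small_fit(self, toy_bundle):
        """On a survival-only GUTS-reduced fit (a genuinely non-Gaussian
        posterior) the two engines must still produce overlapping 95%
        credible intervals for every parameter."""
        cis = {}
        for engine in ("variational", "mcmc"):
            est = GutsModel(
                variant="guts_reduced", sharing="specific", engine=engine,
                n_starts=3, draws=2000, seed=3, maxiter=200, mcmc_burn=500,
            )
            est.fit(toy_bundle.observations)
            cis[engine] = est.result_.summary(level=0.95)
        for lab in cis["mcmc"].index:
            a, b = cis["mcmc"].loc[lab], cis["variational"].loc[lab]
            assert a["lower"] <= b["upper"] and b["lower"] <= a["upper"], lab


class TestTrajectoryEnvelopes:
    def scenario(self):
        return ExposureScenario(substance="substance_1", c_external=6.7,
                                treatment_id="env")

    def test_single_draw_collapses_the_envelope(self, toy_fit):
        res = toy_fit.result_
        single = PosteriorResult(
            variant=res.variant, substances=res.substances, sharing=res.sharing,
            labels=res.labels, draws=res.draws.iloc[[0]],
            start_points=res.start_points, start_losses=res.start_losses,
            scaling=res.scaling,
        )
        env = posterior_trajectory_bci(single, self.scenario())
        assert (env["lower"] == env["median"]).all()
        assert (env["upper"] == env["median"]).all()

    def test_full_level_is_min_max_and_levels_nest(self, toy_fit):
        sc = self.scenario()
        e50 = posterior_trajectory_bci(toy_fit.result_, sc, level=0.5)
        e95 = posterior_trajectory_bci(toy_fit.result_, sc, level=0.95)
        e100 = posterior_trajectory_bci(toy_fit.result_, sc, level=1.0)
        assert (e50["upper"] - e50["lower"] <= e95["upper"] - e95["lower"] + 1e-12).all()
        assert (e95["upper"] <= e100["upper"] + 1e-12).all()
        assert (e95["lower"] >= e100["lower"] - 1e-12).all()

    def test_envelopes_cover_all_variant_endpoints(self, toy_fit):
        env = posterior_trajectory_bci(toy_fit.result_, self.scenario())
        assert set(env["endpoint"]) == {"cint", "nrf2", "survival"}


class TestPosteriorClusters:
    def test_bimodal_cloud_yields_two_clusters(self, rng):
        a = rng.normal(0.0, 0.3, size=(30, 2))
        b = rng.normal(6.0, 0.3, size=(30, 2))  # 10 within-cluster sd apart
        pts = np.vstack([a, b])
        losses = np.concatenate([np.full(30, 10.0), np.full(30, 11.0)])
        labels, summary = detect_posterior_clusters(pts, losses=losses, eps=0.6)
        assert len(summary) == 2
        assert set(labels[:30]) == {0} and set(labels[30:]) == {1}
        assert summary.loc[0, "best_loss"] == 10.0

    def test_single_tight_cloud_is_one_cluster(self, rng):
        pts = np.tile([[1.0, 2.0, 3.0]], (15, 1)) + rng.normal(0, 1e-6, (15, 3))
        labels, summary = detect_posterior_clusters(pts)
        assert len(summary) == 1
        assert set(labels) == {0}

    def test_labels_equivariant_under_permutation(self, rng):
        a = rng.normal(0.0, 0.3, size=(20, 2))
        b = rng.normal(6.0, 0.3, size=(20, 2))
        pts = np.vstack([a, b])
        losses = np.concatenate([np.full(20, 1.0), np.full(20, 2.0)])
        perm = rng.permutation(len(pts))
        l1, _ = detect_posterior_clusters(pts, losses=losses, eps=0.6)
        l2, _ = detect_posterior_clusters(pts[perm], losses=losses[perm], eps=0.6)
        np.testing.assert_array_equal(l1[perm], l2)

    def test_requires_enough_starts(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            detect_posterior_clusters(rng.normal(size=(5, 2)))


def _dummy_result(k, loglik, n=941, fingerprint="fp", sharing_mode="specific"):
    from gutspulse.likelihood import bic as bic_fn

    sharing = make_sharing_map("guts_rna_pulse", sharing_mode)
    labels = [f"p{i}" for i in range(3)]
    return PosteriorResult(
        variant="guts_rna_pulse", substances=["a"], sharing=sharing,
        labels=labels, draws=pd.DataFrame(np.ones((5, 3)), columns=labels),
        start_points=np.zeros((2, 3)), start_losses=np.zeros(2),
        loglik_hat=loglik, k_params=k, n_obs=n,
        bic=bic_fn(loglik, k, n), data_fingerprint=fingerprint,
    )


class TestCompareModels:
    def test_single_result_has_zero_delta(self):
        table = compare_models([_dummy_result(16, -100.0)])
        assert table["delta_bic"].tolist() == [0.0]

    def test_equal_loglik_prefers_fewer_parameters(self):
        t = compare_models([
            _dummy_result(30, -100.0), _dummy_result(16, -100.0, sharing_mode="independent"),
        ])
        assert t.iloc[0]["k_params"] == 16
        assert t["delta_bic"].iloc[1] == pytest.approx(14 * math.log(941), rel=1e-12)

    def test_order_invariance(self):
        a, b = _dummy_result(30, -90.0), _dummy_result(16, -100.0)
        t1 = compare_models([a, b])
        t2 = compare_models([b, a])
        pd.testing.assert_frame_equal(t1, t2)

    def test_mismatched_data_fingerprints_rejected(self):
        with pytest.raises(ValueError, match="fingerprint"):
            compare_models([
                _dummy_result(16, -100.0, fingerprint="x"),
                _dummy_result(30, -90.0, fingerprint="y"),
            ])


class TestMultistartWrapper:
    def test_multistart_fit_returns_posterior_with_start_bookkeeping(
        self, toy_bundle
    ):
        from gutspulse.inference import multistart_fit

        res = multistart_fit(
            "guts_reduced", toy_bundle.observations, sharing="specific",
            n_starts=12, seed=4, engine="variational", draws=100, maxiter=80,
        )
        assert res.start_points.shape == (12, 4)
        assert len(res.start_losses) == 12
        assert res.best_start == int(np.argmin(res.start_losses))
        assert res.provenance["n_starts"] == 12
        # identifiability diagnostic runs on the multistart endpoint cloud
        labels, summary = detect_posterior_clusters(res)
        assert len(labels) == 12
        assert summary["size"].sum() == np.sum(np.isfinite(res.start_losses))

    def test_degenerate_single_start_uses_the_seeded_stream(self, toy_bundle):
        from gutspulse.inference import multistart_fit

        a = multistart_fit("guts_reduced", toy_bundle.observations,
                           sharing="specific", n_starts=1, seed=4,
                           draws=50, maxiter=60)
        b = multistart_fit("guts_reduced", toy_bundle.observations,
                           sharing="specific", n_starts=1, seed=4,
                           draws=50, maxiter=60)
        np.testing.assert_array_equal(a.start_points, b.start_points)
        assert a.loglik_hat == b.loglik_hat
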