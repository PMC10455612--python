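"""Tests for the Bayesian estimator: direction rule, diagnostics, posterior
contracts, and the sampler's agreement with the reference kernels."""

import math

import numpy as np
import pytest

from mggum import (
    McmcConfig,
    PriorSpec,
    ResponseMatrix,
    ResponseScale,
    SimulationCondition,
    build_model,
    classify_item_direction,
    covariate_significance,
    fit,
    gelman_rubin,
    simulate_dataset,
)
from mggum.estimate import _Posterior
from mggum.kernels import ItemBank, PersonSample, joint_log_likelihood


class TestClassifyItemDirection:
    @pytest.mark.parametrize("delta,expected", [
        (-2.0, "negative"), (-1.51, "negative"),
        (-1.5, "neutral"), (0.0, "neutral"), (1.5, "neutral"),
        (1.51, "positive"), (2.0, "positive"),
    ])
    def test_rule_with_inclusive_boundaries(self, delta, expected):
        assert classify_item_direction(delta) == expected


class TestGelmanRubin:
    def test_hand_oracle(self):
        # chains (0,2) and (1,3): W=2, B/n=0.5, R-hat = sqrt(0.75)
        r = gelman_rubin(np.array([[0.0, 2.0], [1.0, 3.0]]))
        assert r == pytest.approx(math.sqrt(0.75), abs=1e-12)
        assert r == pytest.approx(0.866, abs=1e-3)

    def test_long_chains_same_distribution(self):
        rng = np.random.default_rng(0)
        r = gelman_rubin(rng.normal(size=(2, 20_000)))
        assert abs(r - 1.0) < 0.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 500))
        x[1] += 10
        assert gelman_rubin(x) > 3

    def test_zero_within_chain_variance(self):
        assert gelman_rubin(np.array([[1.0, 1.0], [2.0, 2.0]])) == np.inf

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.array([1.0, 2.0, 3.0]))


class TestConfigAndPriors:
    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1)
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=100, n_burnin=100)
        assert McmcConfig().n_keep == 1000

    def test_prior_spec_for_scale(self):
        p2 = PriorSpec.for_scale(ResponseScale(1))
        assert p2.tau == ((-2.0, 2.0),)
        p4 = PriorSpec.for_scale(ResponseScale(3))
        assert p4.tau == ((-3.0, 2.0), (-2.0, 2.0), (-1.0, 2.0))
        with pytest.raises(ValueError):
            PriorSpec(beta_sd=-1.0)


class TestBuildModel:
    def test_missing_covariates_rejected(self, small_sim):
        X = small_sim.persons.X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="covariate"):
            build_model(small_sim.responses, small_sim.items, small_sim.scale,
                        X=X)

    def test_all_missing_item_rejected(self, small_sim):
        mask = small_sim.responses.missing_mask.copy()
        mask[:, 2] = True
        bad = ResponseMatrix(values=small_sim.responses.values, missing_mask=mask)
        with pytest.raises(ValueError, match="no observed"):
            build_model(bad, small_sim.items, small_sim.scale)

    def test_anchored_dims(self, small_sim):
        model = build_model(small_sim.responses, small_sim.items,
                            small_sim.scale)
        expected = []
        for d in range(2):
            on_d = small_sim.items.dimension == d
            expected.append(bool(np.any(small_sim.items.direction[on_d] != "neutral")))
        assert model.anchored_dims().tolist() == expected


class TestPosteriorGradient:
    def test_sampler_loglik_matches_reference_kernels(self, small_sim):
        """The numba likelihood used by HMC must agree with the numpy
        reference implementation to machine precision."""
        model = build_model(small_sim.responses, small_sim.items,
                            small_sim.scale, X=small_sim.persons.X)
        post = _Posterior(model)
        rng = np.random.default_rng(5)
        q = 0.3 * rng.standard_normal(post.n_q)
        _, _, tau, theta, alpha, delta = post.unpack(q)
        bank = ItemBank(dimension=model.trait, alpha=alpha, delta=delta,
                        tau=tau, direction=small_sim.items.direction)
        expected = joint_log_likelihood(small_sim.responses, bank,
                                        PersonSample(theta=theta),
                                        small_sim.scale)
        assert post.pointwise_ll(q).sum() == pytest.approx(expected, abs=1e-9)
        assert post.item_loglik(alpha, delta, tau, theta).sum() == \
            pytest.approx(expected, abs=1e-9)
        assert post.person_loglik(alpha, delta, tau, theta).sum() == \
            pytest.approx(expected, abs=1e-9)

    def test_gradient_matches_finite_differences(self, small_sim):
        model = build_model(small_sim.responses, small_sim.items,
                            small_sim.scale, X=small_sim.persons.X)
        post = _Posterior(model)
        rng = np.random.default_rng(6)
        q = 0.4 * rng.standard_normal(post.n_q)
        lp, g = post.logp_grad(q)
        tail = post.K + post.P * post.D    # correlation + regression blocks
        idx = np.concatenate([rng.choice(post.n_q - tail, 25, replace=False),
                              np.arange(post.n_q - tail, post.n_q)])
        eps = 1e-6
        for i in idx:
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            fd = (post.logp_grad(qp)[0] - post.logp_grad(qm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestFitContracts:
    def test_retained_draw_counts(self, small_fit):
        cfg = small_fit.config
        assert small_fit.draws["alpha"].shape[:2] == (cfg.n_chains, cfg.n_keep)
        assert small_fit.draws["theta"].shape[1] == 1000

    def test_parameter_support_constraints(self, small_sim, small_fit):
        assert np.all(small_fit.draws["alpha"] > 0)
        dirs = small_sim.items.direction
        pos = np.asarray(dirs) == "positive"
        neg = np.asarray(dirs) == "negative"
        if pos.any():
            assert np.all(small_fit.draws["delta"][:, :, pos] >= 0)
        if neg.any():
            assert np.all(small_fit.draws["delta"][:, :, neg] <= 0)

    def test_omega_draws_are_correlation_matrices(self, small_fit):
        om = small_fit.stacked("omega")[::97]
        for m in om:
            np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-10)
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            assert np.linalg.eigvalsh(m).min() > 0

    def test_pointwise_loglik_shape_and_finite(self, small_sim, small_fit):
        n_obs = small_sim.responses.n_observed
        assert small_fit.pointwise_loglik.shape == (2000, n_obs)
        assert np.all(np.isfinite(small_fit.pointwise_loglik))
        assert np.all(small_fit.pointwise_loglik < 0)

    def test_rhat_reported_for_all_families(self, small_fit):
        for fam in ("alpha", "delta", "tau", "theta", "beta", "omega"):
            assert fam in small_fit.rhat

    def test_covariate_significance_shape(self, small_fit):
        sig = covariate_significance(small_fit)
        assert sig.shape == small_fit.estimates["beta"].shape
        assert sig.dtype == bool

    def test_estimates_match_draw_means(self, small_fit):
        np.testing.assert_allclose(small_fit.estimates["delta"],
                                   small_fit.stacked("delta").mean(axis=0))

    def test_summary_table(self, small_fit):
        df = small_fit.summary()
        assert {"parameter", "estimate", "se", "ci2.5", "ci97.5",
                "rhat"} <= set(df.columns)
        assert (df["se"] > 0).all()

    def test_save_and_load(self, small_fit, tmp_path):
        from mggum import load_fit
        out = small_fit.save(tmp_path / "fit")
        arrays = load_fit(out)
        assert "pointwise_loglik" in arrays
        np.testing.assert_allclose(arrays["draws_alpha"],
                                   small_fit.draws["alpha"])

    def test_no_covariate_fit_rejects_significance(self):
        cond = SimulationCondition(n_persons=60, n_traits=1, items_per_trait=4,
                                   n_options=2, seed=3)
        sim = simulate_dataset(cond)
        model = build_model(sim.responses, sim.items, sim.scale)
        f = fit(model, McmcConfig(seed=4, n_iterations=300, n_burnin=150))
        with pytest.raises(ValueError, match="without covariates"):
            covariate_significance(f)
        # unidimensional fit has the trivial 1x1 correlation matrix
        np.testing.assert_allclose(f.estimates["omega"], [[1.0]])

    def test_seeded_fit_is_deterministic(self):
        cond = SimulationCondition(n_persons=50, n_traits=2, items_per_trait=3,
                                   n_options=2, trait_cor=0.3, seed=8)
        sim = simulate_dataset(cond)
        model = build_model(sim.responses, sim.items, sim.scale)
        cfg = McmcConfig(seed=21, n_iterations=300, n_burnin=150)
        a = fit(model, cfg)
        b = fit(model, cfg)
        np.testing.assert_array_equal(a.draws["theta"], b.draws["theta"])
        np.testing.assert_array_equal(a.draws["tau"], b.draws["tau"])
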