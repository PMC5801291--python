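import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ppmcompare import (
    BayesSpec,
    ShrinkagePrior,
    bayes_threshold,
    compute_posterior,
    es_threshold,
    estimate_prior_variance,
    fit_group_glm,
    generate_subject_images,
    log_odds_map,
    SyntheticSpec,
)
from ppmcompare.bayesian import LOG_ODDS_CLIP

from conftest import glm_from_arrays


class TestPriorEstimation:
    def test_moments_arithmetic(self):
        # Var_v(beta) = 0.5, mean resid_var/n = 0.2 -> cB = 0.3
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 1, size=(40, 5, 5))
        beta = (beta - beta.mean()) / beta.std(ddof=1) * np.sqrt(0.5)
        var = np.full((40, 5, 5), 0.2 * 8)
        glm = glm_from_arrays(beta, var, n=8)
        prior = estimate_prior_variance(glm)
        assert np.isclose(prior.cB, 0.3, atol=1e-12)
        assert prior.V_used == 1000

    def test_clamped_at_zero(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(0, 1, size=(40, 5, 5))
        beta = (beta - beta.mean()) / beta.std(ddof=1) * np.sqrt(0.1)
        var = np.full((40, 5, 5), 0.2 * 8)
        prior = estimate_prior_variance(glm_from_arrays(beta, var, n=8))
        assert prior.cB == 0.0

    def test_parameter_recovery_small(self):
        # hierarchical draw with true cB = 0.25, sigma^2 = 1, n = 16
        rng = np.random.default_rng(7)
        shape = (40, 40, 20)
        ests = []
        for _ in range(10):
            beta = rng.normal(0, 0.5, size=shape)
            data = beta[None] + rng.normal(0, 1, size=(16, *shape))
            glm = glm_from_arrays(data.mean(0), data.var(0, ddof=1), n=16)
            ests.append(estimate_prior_variance(glm).cB)
        assert abs(np.mean(ests) - 0.25) / 0.25 < 0.1


class TestEsThreshold:
    def test_default_scale_worked_values(self):
        # sqrt(cB) = 0.0518 is the d = 1.0 default scale
        prior = ShrinkagePrior(cB=0.0518**2)
        assert es_threshold(prior, 1.0) == pytest.approx(0.0518, abs=1e-15)
        assert es_threshold(prior, 0.5) == 0.0259

    def test_degenerate_prior_gives_zero(self):
        assert es_threshold(ShrinkagePrior(cB=0.0), 0.8) == 0.0

    def test_requires_positive_d(self):
        with pytest.raises(ValueError):
            es_threshold(ShrinkagePrior(cB=1.0), 0.0)


class TestPosterior:
    def test_worked_example(self):
        glm = glm_from_arrays(np.full((2, 2, 2), 0.5), np.ones((2, 2, 2)), n=16)
        post = compute_posterior(glm, ShrinkagePrior(cB=0.25))
        assert np.allclose(post.post_var.values, 0.05)
        assert np.allclose(post.post_mean.values, 0.4)

    def test_pooled_and_voxel_agree_on_uniform_variance(self):
        glm = glm_from_arrays(np.full((2, 2, 2), 0.5), np.ones((2, 2, 2)), n=16)
        a = compute_posterior(glm, ShrinkagePrior(cB=0.25), error_var="pooled")
        b = compute_posterior(glm, ShrinkagePrior(cB=0.25), error_var="voxel")
        assert np.allclose(a.post_mean.values, b.post_mean.values)
        assert np.allclose(a.post_var.values, b.post_var.values)

    def test_flat_prior_limit(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(size=(3, 3, 3))
        var = rng.uniform(0.5, 2.0, size=(3, 3, 3))
        glm = glm_from_arrays(beta, var, n=10)
        post = compute_posterior(glm, ShrinkagePrior(cB=1e12), error_var="voxel")
        assert np.allclose(post.post_mean.values, beta, rtol=1e-6)
        assert np.allclose(post.post_var.values, var / 10, rtol=1e-6)

    def test_zero_mean_stays_zero(self):
        glm = glm_from_arrays(np.zeros((2, 2, 2)), np.ones((2, 2, 2)), n=8)
        post = compute_posterior(glm, ShrinkagePrior(cB=0.5))
        assert (post.post_mean.values == 0).all()

    def test_degenerate_prior_raises(self):
        glm = glm_from_arrays(np.zeros((2, 2, 2)), np.ones((2, 2, 2)), n=8)
        with pytest.raises(ValueError, match="degenerate prior"):
            compute_posterior(glm, ShrinkagePrior(cB=0.0))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        beta=st.floats(-3, 3),
        var=st.floats(0.05, 5),
        n=st.integers(2, 40),
        cB=st.floats(1e-3, 5),
    )
    def test_conjugate_identities_and_shrinkage(self, beta, var, n, cB):
        glm = glm_from_arrays(np.full((1, 1, 1), beta), np.full((1, 1, 1), var), n=n)
        post = compute_posterior(glm, ShrinkagePrior(cB=cB), error_var="voxel")
        pm = post.post_mean.values[0, 0, 0]
        pv = post.post_var.values[0, 0, 0]
        # independent closed form: precision-weighted average with the
        # zero prior mean
        w = cB / (cB + var / n)
        assert np.isclose(pm, w * beta, rtol=1e-12, atol=1e-12)
        assert np.isclose(pv, w * var / n, rtol=1e-12, atol=1e-12)
        assert abs(pm) <= abs(beta) + 1e-15
        assert pv <= min(cB, var / n) + 1e-15


class TestLogOdds:
    def test_zero_at_gamma_equal_posterior_mean(self):
        glm = glm_from_arrays(np.full((2, 2, 2), 0.5), np.ones((2, 2, 2)), n=16)
        post = compute_posterior(glm, ShrinkagePrior(cB=0.25))
        lo = log_odds_map(post, gamma=0.4)
        assert np.allclose(lo.values, 0.0, atol=1e-12)

    def test_worked_example(self):
        glm = glm_from_arrays(np.full((1, 1, 1), 0.5), np.ones((1, 1, 1)), n=16)
        post = compute_posterior(glm, ShrinkagePrior(cB=0.25))
        lo = log_odds_map(post, gamma=0.25).values[0, 0, 0]
        z = (0.25 - 0.4) / np.sqrt(0.05)
        oracle = np.log(stats.norm.sf(z) / stats.norm.cdf(z))
        assert np.isclose(lo, oracle, atol=1e-10)
        assert np.isclose(lo, 1.092, atol=1e-3)

    def test_strictly_decreasing_in_gamma(self):
        glm = glm_from_arrays(np.full((1, 1, 1), 0.5), np.ones((1, 1, 1)), n=16)
        post = compute_posterior(glm, ShrinkagePrior(cB=0.25))
        los = [log_odds_map(post, g).values[0, 0, 0] for g in np.linspace(0, 1, 20)]
        assert (np.diff(los) < 0).all()

    def test_clipping(self):
        glm = glm_from_arrays(np.full((1, 1, 1), 50.0), np.full((1, 1, 1), 0.01), n=30)
        post = compute_posterior(glm, ShrinkagePrior(cB=100.0))
        assert log_odds_map(post, gamma=0.0).values[0, 0, 0] == LOG_ODDS_CLIP


class TestBayesThreshold:
    @pytest.fixture(scope="class")
    def blob_analysis(self, strong_blob_images):
        images, _ = strong_blob_images
        glm = fit_group_glm(images)
        prior = estimate_prior_variance(glm)
        post = compute_posterior(glm, prior)
        return images, prior, post

    def test_vacuous_threshold_activates_everything(self, blob_analysis):
        images, prior, post = blob_analysis
        lo = log_odds_map(post, gamma=es_threshold(prior, 0.5))
        spec = BayesSpec(d=0.5, tau=-LOG_ODDS_CLIP - 1).resolve(prior)
        act = bayes_threshold(lo, spec, images.mask)
        assert act.active.sum() == images.mask.V

    def test_strict_threshold_empties_map(self, blob_analysis):
        images, prior, post = blob_analysis
        lo = log_odds_map(post, gamma=es_threshold(prior, 0.5))
        lo.values[np.isfinite(lo.values)] = np.minimum(
            lo.values[np.isfinite(lo.values)], 4.9
        )
        act = bayes_threshold(lo, BayesSpec(d=0.5, tau=5.0).resolve(prior), images.mask)
        assert act.active.sum() == 0

    def test_nesting_in_tau_and_d(self, blob_analysis):
        images, prior, post = blob_analysis
        active = {}
        for d in (0.2, 0.5, 0.8):
            lo = log_odds_map(post, gamma=es_threshold(prior, d))
            for tau in (3.0, 5.0, 10.0):
                spec = BayesSpec(d=d, tau=tau).resolve(prior)
                active[(d, tau)] = bayes_threshold(lo, spec, images.mask).active
        for d in (0.2, 0.5, 0.8):
            assert not (active[(d, 10.0)] & ~active[(d, 5.0)]).any()
            assert not (active[(d, 5.0)] & ~active[(d, 3.0)]).any()
        for tau in (3.0, 5.0, 10.0):
            assert not (active[(0.8, tau)] & ~active[(0.5, tau)]).any()
            assert not (active[(0.5, tau)] & ~active[(0.2, tau)]).any()

    def test_unresolved_spec_rejected(self, blob_analysis):
        images, prior, post = blob_analysis
        lo = log_odds_map(post, gamma=0.1)
        with pytest.raises(ValueError, match="resolve"):
            bayes_threshold(lo, BayesSpec(d=0.5, tau=5.0), images.mask)

    def test_gamma_resolution_identity(self, blob_analysis):
        _, prior, _ = blob_analysis
        spec = BayesSpec(d=0.5, tau=5.0).resolve(prior)
        assert spec.gamma == pytest.approx(0.5 * np.sqrt(prior.cB), rel=1e-12)


def test_logodds_grows_with_sample_size(strong_blob_images):
    # evidence for a strongly active blob accumulates with n
    images, truth = strong_blob_images
    mean_lo = []
    for n in (6, 10, 16):
        sub = images.subset(range(n))
        glm = fit_group_glm(sub)
        prior = estimate_prior_variance(glm)
        post = compute_posterior(glm, prior)
        lo = log_odds_map(post, gamma=es_threshold(prior, 0.5))
        mean_lo.append(lo.values[truth.active].mean())
    assert mean_lo[0] < mean_lo[1] < mean_lo[2]
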