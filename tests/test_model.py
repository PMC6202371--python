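"""Likelihood, coupling prior, posterior and MAP decoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periprior.model import (
    CouplingPriorParams,
    EvalGrid,
    GridBoundaryError,
    ParameterError,
    SensoryNoise,
    StimulusPair,
    component_modes,
    coupling_prior_logpdf,
    likelihood_logpdf,
    map_estimate,
    map_estimates,
    mle_estimate,
    posterior_log,
    predict_mean_estimates,
)

FUSED_25 = 2.025759  # (0/6.8^2 + 25/22.9^2) / (1/6.8^2 + 1/22.9^2)


def brute_force_argmax(center, noise, params, coarse=0.5, fine=0.1):
    """Independent grid-search oracle: dense coarse sweep over the region
    spanned by both component modes, then a fine sweep around the winner."""
    um, rm = component_modes(center, noise, params)
    pts = [um.v_hat, um.p_hat, rm.v_hat, rm.p_hat]
    margin = 5.0 * max(noise.sigma_v, noise.sigma_p, params.sigma_c)
    ax = np.arange(min(pts) - margin, max(pts) + margin, coarse)
    scores = posterior_log(ax[:, None], ax[None, :], center, noise, params)
    i, j = np.unravel_index(np.argmax(scores), scores.shape)
    fx = np.arange(ax[i] - 2 * coarse, ax[i] + 2 * coarse, fine)
    fy = np.arange(ax[j] - 2 * coarse, ax[j] + 2 * coarse, fine)
    scores = posterior_log(fx[:, None], fy[None, :], center, noise, params)
    i, j = np.unravel_index(np.argmax(scores), scores.shape)
    return fx[i], fy[j]


class TestLikelihood:
    def test_one_sigma_drop(self, visible_noise):
        center = StimulusPair(0.0, 0.0)
        drop = (likelihood_logpdf(visible_noise.sigma_v, 0.0, center, visible_noise)
                - likelihood_logpdf(0.0, 0.0, center, visible_noise))
        assert drop == pytest.approx(-0.5, abs=1e-12)

    def test_direct_exponent_evaluation(self, visible_noise):
        center = StimulusPair(0.0, 25.0)
        expected = (-math.log(2 * math.pi * 6.8 * 22.9)
                    - 3.0 ** 2 / (2 * 6.8 ** 2)
                    - (20.0 - 25.0) ** 2 / (2 * 22.9 ** 2))
        assert likelihood_logpdf(3.0, 20.0, center, visible_noise) == \
            pytest.approx(expected, abs=1e-12)

    def test_maximum_at_center(self, visible_noise):
        center = StimulusPair(0.0, 0.0)
        ax = np.linspace(-30, 30, 301)
        scores = likelihood_logpdf(ax[:, None], ax[None, :], center, visible_noise)
        i, j = np.unravel_index(np.argmax(scores), scores.shape)
        assert (ax[i], ax[j]) == (0.0, 0.0)

    @pytest.mark.parametrize("sv,sp", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_sigma_rejected(self, sv, sp):
        with pytest.raises(ParameterError):
            SensoryNoise(sv, sp)


class TestCouplingPrior:
    def test_uniform_only_mixture_is_flat(self):
        params = CouplingPriorParams(lam=0.0, sigma_c=10.0)
        expected = -math.log(params.area_A)
        for v, p in [(0, 0), (5, -90), (200, 150)]:
            assert coupling_prior_logpdf(v, p, params) == \
                pytest.approx(expected, abs=1e-12)

    def test_one_sigma_ridge_drop(self):
        params = CouplingPriorParams(lam=1.0, sigma_c=12.0)
        drop = (coupling_prior_logpdf(12.0, 0.0, params)
                - coupling_prior_logpdf(0.0, 0.0, params))
        assert drop == pytest.approx(-0.5, abs=1e-12)

    def test_direct_mixture_value_on_identity_line(self):
        params = CouplingPriorParams(lam=0.5, sigma_c=10.0, area_A=360000.0)
        expected = 0.5 / math.sqrt(2 * math.pi * 100.0) + 0.5 / 360000.0
        value = math.exp(coupling_prior_logpdf(7.0, 7.0, params))
        assert value == pytest.approx(expected, rel=1e-10)
        assert value == pytest.approx(0.019948, abs=1e-6)

    def test_depends_only_on_separation_and_tail_level(self):
        params = CouplingPriorParams(lam=0.7, sigma_c=15.0)
        assert coupling_prior_logpdf(10.0, -5.0, params) == \
            pytest.approx(coupling_prior_logpdf(110.0, 95.0, params), abs=1e-12)
        far = coupling_prior_logpdf(0.0, 5000.0, params)
        assert far == pytest.approx(math.log(0.3 / params.area_A), abs=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            CouplingPriorParams(lam=1.2, sigma_c=10.0)
        with pytest.raises(ParameterError):
            CouplingPriorParams(lam=0.5, sigma_c=0.0)
        with pytest.raises(ParameterError):
            CouplingPriorParams(lam=0.5, sigma_c=10.0, area_A=-1.0)


class TestPosterior:
    def test_pointwise_additivity_on_stencil(self, visible_noise):
        rng = np.random.default_rng(3)
        center = StimulusPair(*rng.uniform(-50, 50, 2))
        params = CouplingPriorParams(lam=0.3, sigma_c=20.0)
        ax = np.linspace(-40, 60, 5)
        post = posterior_log(ax[:, None], ax[None, :], center, visible_noise, params)
        manual = (coupling_prior_logpdf(ax[:, None], ax[None, :], params)
                  + likelihood_logpdf(ax[:, None], ax[None, :], center,
                                      visible_noise))
        np.testing.assert_allclose(post, manual, atol=1e-12)

    def test_flat_prior_argmax_is_likelihood_center(self, visible_noise):
        est = map_estimate(StimulusPair(10.0, -30.0), visible_noise,
                           CouplingPriorParams(lam=0.0, sigma_c=10.0))
        assert est.v_hat == pytest.approx(10.0, abs=1e-7)
        assert est.p_hat == pytest.approx(-30.0, abs=1e-7)

    def test_zero_disparity_symmetry(self, visible_noise):
        est = map_estimate(StimulusPair(12.0, 12.0), visible_noise,
                           CouplingPriorParams(lam=0.6, sigma_c=18.0))
        assert est.v_hat == pytest.approx(12.0, abs=1e-7)
        assert est.p_hat == pytest.approx(12.0, abs=1e-7)


class TestComponentModes:
    def test_ridge_flattens_to_center_for_wide_coupling(self, visible_noise):
        center = StimulusPair(0.0, 25.0)
        _, ridge = component_modes(center, visible_noise,
                                   CouplingPriorParams(lam=0.5, sigma_c=1e7))
        assert ridge.v_hat == pytest.approx(0.0, abs=1e-3)
        assert ridge.p_hat == pytest.approx(25.0, abs=1e-3)

    def test_tight_coupling_gives_reliability_weighted_average(self, visible_noise):
        center = StimulusPair(0.0, 25.0)
        _, ridge = component_modes(center, visible_noise,
                                   CouplingPriorParams(lam=0.5, sigma_c=1e-4))
        assert ridge.v_hat == pytest.approx(FUSED_25, abs=1e-3)
        assert ridge.p_hat == pytest.approx(FUSED_25, abs=1e-3)

    def test_modes_are_stationary_points(self, visible_noise):
        params = CouplingPriorParams(lam=0.4, sigma_c=16.5)
        center = StimulusPair(-8.0, 40.0)
        uniform, ridge = component_modes(center, visible_noise, params)

        def uniform_score(v, p):
            return likelihood_logpdf(v, p, center, visible_noise)

        def ridge_score(v, p):
            return (likelihood_logpdf(v, p, center, visible_noise)
                    - (v - p) ** 2 / (2 * params.sigma_c ** 2))

        h = 1e-4
        for (v, p), score in ((
                (uniform.v_hat, uniform.p_hat), uniform_score),
                ((ridge.v_hat, ridge.p_hat), ridge_score)):
            gv = (score(v + h, p) - score(v - h, p)) / (2 * h)
            gp = (score(v, p + h) - score(v, p - h)) / (2 * h)
            assert max(abs(gv), abs(gp)) < 1e-8


class TestMapEstimate:
    def test_forced_fusion_near_closed_form(self, visible_noise):
        est = map_estimate(StimulusPair(0.0, 25.0), visible_noise,
                           CouplingPriorParams(lam=1.0, sigma_c=1e-2))
        assert est.v_hat == pytest.approx(FUSED_25, abs=1e-3)
        assert est.p_hat == pytest.approx(FUSED_25, abs=1e-3)

    def test_agrees_with_grid_oracle(self, visible_noise):
        rng = np.random.default_rng(7)
        for _ in range(20):
            center = StimulusPair(0.0, rng.uniform(-220, 220))
            noise = SensoryNoise(rng.uniform(3, 15), rng.uniform(8, 30))
            params = CouplingPriorParams(rng.uniform(0.05, 0.95),
                                         rng.uniform(5, 45))
            est = map_estimate(center, noise, params)
            v, p = brute_force_argmax(center, noise, params)
            assert abs(est.v_hat - v) <= 0.1
            assert abs(est.p_hat - p) <= 0.1

    def test_coarse_scan_path_matches_fast_path(self, visible_noise):
        center = StimulusPair(0.0, 60.0)
        params = CouplingPriorParams(0.44, 16.5)
        fast = map_estimate(center, visible_noise, params)
        slow = map_estimate(center, visible_noise, params,
                            grid=EvalGrid(-300, 300, 2.0), coarse_scan=True)
        assert fast.v_hat == pytest.approx(slow.v_hat, abs=1e-6)
        assert fast.p_hat == pytest.approx(slow.p_hat, abs=1e-6)

    def test_boundary_hit_raises(self, visible_noise):
        with pytest.raises(GridBoundaryError):
            map_estimate(StimulusPair(0.0, 40.0), visible_noise,
                         CouplingPriorParams(lam=0.0, sigma_c=10.0),
                         grid=EvalGrid(-20.0, 20.0, 0.5))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shift=st.floats(-150, 150), d=st.floats(-120, 120),
           lam=st.floats(0.05, 0.95), sc=st.floats(5, 40))
    def test_translation_equivariance(self, shift, d, lam, sc):
        noise = SensoryNoise(6.8, 22.9)
        params = CouplingPriorParams(lam, sc)
        base = map_estimates(np.array([[0.0, d]]), noise, params)[0]
        moved = map_estimates(np.array([[shift, shift + d]]), noise, params)[0]
        np.testing.assert_allclose(moved, base + shift, atol=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(d=st.floats(1, 200), lam=st.floats(0.05, 0.95), sc=st.floats(5, 40))
    def test_mirror_antisymmetry(self, d, lam, sc):
        noise = SensoryNoise(6.8, 22.9)
        params = CouplingPriorParams(lam, sc)
        right = map_estimates(np.array([[0.0, d]]), noise, params)[0]
        left = map_estimates(np.array([[0.0, -d]]), noise, params)[0]
        np.testing.assert_allclose(left, -right, atol=1e-6)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(lam=st.floats(0.05, 0.95), sc=st.floats(5, 30))
    def test_segregation_limit_far_disparity(self, lam, sc):
        # at |d| = 1e4 sigma_c the ridge component is irrelevant: zero pull
        noise = SensoryNoise(6.8, 22.9)
        d = 1e4 * sc
        est = map_estimates(np.array([[0.0, d]]), noise,
                            CouplingPriorParams(lam, sc))[0]
        assert abs(est[0]) < 1e-6
        assert abs(est[1] - d) < 1e-6


class TestMleEstimate:
    def test_equal_reliabilities_give_midpoint(self):
        noise = SensoryNoise(10.0, 10.0)
        est = mle_estimate(StimulusPair(0.0, 60.0), noise)
        assert est.v_hat == pytest.approx(30.0, abs=1e-3)
        assert est.p_hat == pytest.approx(30.0, abs=1e-3)

    def test_reliability_weighted_average(self, visible_noise):
        est = mle_estimate(StimulusPair(0.0, 25.0), visible_noise)
        assert est.v_hat == pytest.approx(FUSED_25, abs=0.1)
        assert abs(est.v_hat - est.p_hat) < 0.1

    def test_zero_disparity_identity(self, visible_noise):
        est = mle_estimate(StimulusPair(-17.0, -17.0), visible_noise)
        assert est.v_hat == pytest.approx(-17.0, abs=1e-6)
        assert est.p_hat == pytest.approx(-17.0, abs=1e-6)


class TestPredictMeanEstimates:
    DISPARITIES = [0, 25, -25, 50, -50, 100, -100, 200, -200]

    def test_null_coupling_zero_bias(self, visible_noise):
        df = predict_mean_estimates(self.DISPARITIES, visible_noise,
                                    CouplingPriorParams(lam=0.0, sigma_c=10.0))
        nz = df["disparity_mm"] != 0
        np.testing.assert_allclose(df.loc[nz, "visual_bias_pct"], 0, atol=1e-8)
        np.testing.assert_allclose(df.loc[nz, "proprio_bias_pct"], 0, atol=1e-8)
        assert np.isnan(df.loc[~nz, "visual_bias_pct"]).all()

    def test_forced_fusion_conserves_disparity_split(self, visible_noise):
        df = predict_mean_estimates(self.DISPARITIES, visible_noise,
                                    CouplingPriorParams(lam=1.0, sigma_c=1e-2))
        nz = df["disparity_mm"] != 0
        total = df.loc[nz, "visual_bias_pct"] + df.loc[nz, "proprio_bias_pct"]
        np.testing.assert_allclose(total, 100.0, atol=0.5)

    def test_distance_dependent_pull(self, visible_noise):
        df = predict_mean_estimates([25, 200], visible_noise,
                                    CouplingPriorParams(lam=0.5, sigma_c=16.5))
        near, far = df["proprio_bias_pct"].to_numpy()
        assert near > far

    def test_antisymmetric_under_mirroring(self, visible_noise):
        df = predict_mean_estimates(self.DISPARITIES, visible_noise,
                                    CouplingPriorParams(lam=0.44, sigma_c=16.5))
        by_d = df.set_index("disparity_mm")
        for d in (25, 50, 100, 200):
            assert by_d.loc[d, "v_hat_mm"] == pytest.approx(
                -by_d.loc[-d, "v_hat_mm"], abs=1e-8)
            assert by_d.loc[d, "proprio_bias_pct"] == pytest.approx(
                by_d.loc[-d, "proprio_bias_pct"], abs=1e-8)
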