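"""Full conditionals against dense grid-integration oracles on toy models."""

import numpy as np
import pytest
from scipy import stats

from _oracles import (
    gaussian_product_moments,
    inverse_gamma_product_moments,
    truncated_gaussian_product_moments,
)
from isofactor.data import ObservedDataset, PriorConfig
from isofactor.sampler import (
    ModelState,
    SpikeSlab,
    full_conditional_D,
    full_conditional_I0,
    full_conditional_I_row,
    full_conditional_noise,
    full_conditional_W,
    full_conditional_Z,
)

GRID_TOL = 1e-6


def _make(n=1, T=None, A=None, P=None, I=None, Z=None, sigma2=None, I0=0.0, W=1.0, D=0.0):
    r = 1 if P is None else np.atleast_2d(P).shape[1]
    data = ObservedDataset(
        P=np.zeros((n, r)) if P is None else np.atleast_2d(np.asarray(P, float)),
        mask=np.ones((1, r), dtype=np.uint8),
        T=None if T is None else np.asarray(T, float).reshape(n, 1),
        A=None if A is None else np.asarray(A, float),
    )
    state = ModelState(
        I0=np.array([I0]),
        W=np.array([W]),
        D=np.array([D]),
        Z=np.ones((1, r)) if Z is None else np.asarray(Z, float).reshape(1, r),
        I=np.zeros((n, 1)) if I is None else np.asarray(I, float).reshape(n, 1),
        sigma2=np.ones(r) if sigma2 is None else np.asarray(sigma2, float),
    )
    return data, state


class TestConversionWeight:
    def test_zero_transcript_returns_prior(self):
        data, state = _make(n=3, T=[0, 0, 0], I=[1, 2, 3])
        g = full_conditional_W(0, state, data, PriorConfig())
        assert (g.mean, g.variance) == pytest.approx((1.0, 1.0))

    def test_flat_prior_limit_is_least_squares(self):
        data, state = _make(n=1, T=[1.0], I=[2.0])
        g = full_conditional_W(0, state, data, PriorConfig(tau_w=1e8))
        assert g.mean == pytest.approx(2.0, abs=1e-6)
        assert g.variance == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_oracle(self):
        # n=1, T=1, residual 2, tau_w=1 -> N(1.5, 0.5)
        data, state = _make(n=1, T=[1.0], I=[2.0])
        g = full_conditional_W(0, state, data, PriorConfig())
        mean, var = gaussian_product_moments(1.0, 1.0, xs=[1.0], ys=[2.0])
        assert g.mean == pytest.approx(1.5, abs=1e-12)
        assert g.mean == pytest.approx(mean, abs=GRID_TOL)
        assert g.variance == pytest.approx(var, abs=GRID_TOL)

    def test_grid_oracle_two_observations(self):
        data, state = _make(n=2, T=[0.5, -1.2], I=[1.3, 0.4], A=[1, 0], D=0.7, I0=0.2)
        g = full_conditional_W(0, state, data, PriorConfig(tau_w=0.8))
        resid = state.I[:, 0] - 0.2 - np.array([1, 0]) * 0.7
        mean, var = gaussian_product_moments(1.0, 0.8, xs=[0.5, -1.2], ys=resid)
        assert g.mean == pytest.approx(mean, abs=GRID_TOL)
        assert g.variance == pytest.approx(var, abs=GRID_TOL)


class TestConditionEffect:
    def test_all_control_returns_prior(self):
        data, state = _make(n=2, A=[0, 0], I=[1, 2])
        g = full_conditional_D(0, state, data, PriorConfig())
        assert (g.mean, g.variance) == pytest.approx((0.0, 1.0))

    def test_matches_grid_oracle(self):
        # n=2, A=(1,0), residual (2, .) -> N(1, 0.5)
        data, state = _make(n=2, A=[1, 0], I=[2.0, 5.0])
        g = full_conditional_D(0, state, data, PriorConfig())
        mean, var = gaussian_product_moments(0.0, 1.0, xs=[1.0, 0.0], ys=[2.0, 5.0])
        assert g.mean == pytest.approx(1.0, abs=1e-12)
        assert g.mean == pytest.approx(mean, abs=GRID_TOL)
        assert g.variance == pytest.approx(var, abs=GRID_TOL)

    def test_spike_slab_with_certain_inclusion_matches_normal(self):
        data, state = _make(n=2, A=[1, 0], I=[2.0, 5.0])
        normal = full_conditional_D(0, state, data, PriorConfig())
        ss = full_conditional_D(
            0, state, data, PriorConfig(prior_family="spike_slab", theta=1.0)
        )
        assert isinstance(ss, SpikeSlab)
        assert ss.p_include == 1.0
        assert ss.slab == normal

    def test_spike_slab_inclusion_increases_with_signal(self):
        weak = _make(n=4, A=[1, 1, 0, 0], I=[0.1, 0.2, 0.0, -0.1])
        strong = _make(n=4, A=[1, 1, 0, 0], I=[3.0, 3.1, 0.0, -0.1])
        cfg = PriorConfig(prior_family="spike_slab", theta=0.5)
        p_weak = full_conditional_D(0, weak[1], weak[0], cfg).p_include
        p_strong = full_conditional_D(0, strong[1], strong[0], cfg).p_include
        assert p_strong > p_weak


class TestIntercept:
    def test_flat_prior_limit_is_average_residual(self):
        data, state = _make(n=4, I=[1, 2, 3, 4])
        g = full_conditional_I0(0, state, data, PriorConfig(tau_i0=1e8))
        assert g.mean == pytest.approx(2.5, abs=1e-6)

    def test_matches_grid_oracle(self):
        data, state = _make(n=1, T=[2.0], I=[3.0], W=0.5)
        g = full_conditional_I0(0, state, data, PriorConfig(tau_i0=0.7))
        mean, var = gaussian_product_moments(0.0, 0.7, xs=[1.0], ys=[3.0 - 2.0 * 0.5])
        assert g.mean == pytest.approx(mean, abs=GRID_TOL)
        assert g.variance == pytest.approx(var, abs=GRID_TOL)


class TestLatentAbundance:
    def test_zero_detectability_returns_prior(self):
        data, state = _make(n=1, P=[[2.0]], Z=[0.0], I0=0.3)
        mean, cov = full_conditional_I_row(0, [0], [0], state, data, PriorConfig())
        assert mean[0] == pytest.approx(0.3)
        assert cov[0, 0] == pytest.approx(1.0)

    def test_matches_grid_oracle(self):
        # 1 isoform, 1 peptide, Z=1, sigma2=1, prior mean 0, P=2 -> N(1, 0.5)
        data, state = _make(n=1, P=[[2.0]])
        mean, cov = full_conditional_I_row(0, [0], [0], state, data, PriorConfig())
        omean, ovar = gaussian_product_moments(0.0, 1.0, xs=[1.0], ys=[2.0])
        assert mean[0] == pytest.approx(1.0, abs=1e-12)
        assert mean[0] == pytest.approx(omean, abs=GRID_TOL)
        assert cov[0, 0] == pytest.approx(ovar, abs=GRID_TOL)

    def test_two_peptide_grid_oracle(self):
        data, state = _make(n=1, P=[[2.0, -1.0]], Z=[1.3, 0.7], sigma2=[1.0, 2.0], I0=0.4)
        mean, cov = full_conditional_I_row(0, [0], [0, 1], state, data, PriorConfig())
        grid = np.arange(-12, 12, 1e-3)
        def logpost(t):
            return (
                stats.norm.logpdf(t, 0.4, 1.0)
                + stats.norm.logpdf(2.0, 1.3 * t, 1.0)
                + stats.norm.logpdf(-1.0, 0.7 * t, np.sqrt(2.0))
            )
        from _oracles import grid_moments
        omean, ovar = grid_moments(logpost, grid)
        assert mean[0] == pytest.approx(omean, abs=GRID_TOL)
        assert cov[0, 0] == pytest.approx(ovar, abs=GRID_TOL)

    def test_precision_is_spd_for_random_blocks(self, rng):
        for _ in range(10):
            q, r = 3, 5
            Z = rng.normal(1, 0.5, (q, r)) * (rng.uniform(size=(q, r)) < 0.6)
            sigma2 = rng.uniform(0.2, 3.0, r)
            prec = np.eye(q) + (Z / sigma2) @ Z.T
            assert np.all(np.linalg.eigvalsh(prec) > 0)


class TestDetectability:
    def test_zero_abundance_returns_truncated_prior(self):
        data, state = _make(n=2, P=[[1.0], [1.0]], I=[0.0, 0.0])
        bounds = np.array([[0.5, 2.0]])
        tg = full_conditional_Z(0, 0, state, data, PriorConfig(), bounds)
        assert (tg.mean, tg.variance) == pytest.approx((1.0, 1.0))
        assert (tg.lower, tg.upper) == (0.5, 2.0)

    def test_base_gaussian_before_truncation(self):
        # n=1, I=1, partial residual 2, sigma2=1, tau_z=1 -> N(1.5, 0.5)
        data, state = _make(n=1, P=[[2.0]], I=[1.0])
        bounds = np.array([[0.5, 2.0]])
        tg = full_conditional_Z(0, 0, state, data, PriorConfig(), bounds)
        assert (tg.mean, tg.variance) == pytest.approx((1.5, 0.5))

    def test_truncated_moments_match_grid_oracle(self):
        data, state = _make(n=2, P=[[2.0], [0.5]], I=[1.0, 0.8], sigma2=[1.5])
        bounds = np.array([[0.5, 2.0]])
        tg = full_conditional_Z(0, 0, state, data, PriorConfig(tau_z=0.9), bounds)
        omean, ovar = truncated_gaussian_product_moments(
            1.0, 0.9, 0.5, 2.0, xs=[1.0, 0.8], ys=[2.0, 0.5], lik_vars=[1.5, 1.5]
        )
        m, v = tg.moments()
        assert m == pytest.approx(omean, abs=GRID_TOL)
        assert v == pytest.approx(ovar, abs=GRID_TOL)

    def test_off_mask_entry_is_contract_violation(self):
        data, state = _make(n=1, P=[[2.0]])
        data.mask[0, 0] = 0
        with pytest.raises(ValueError, match="never sampled"):
            full_conditional_Z(0, 0, state, data, PriorConfig(), np.array([[0.5, 2.0]]))


class TestNoiseVariance:
    def test_zero_residuals_return_prior_rate(self):
        data, state = _make(n=2, P=[[1.0], [2.0]], I=[1.0, 2.0])
        ig = full_conditional_noise(0, state, data, PriorConfig())
        assert ig.shape == pytest.approx(2.0)
        assert ig.rate == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        # residuals (1, -1), a0=b0=1 -> IG(2, 2)
        data, state = _make(n=2, P=[[1.0], [-1.0]], I=[0.0, 0.0])
        ig = full_conditional_noise(0, state, data, PriorConfig())
        assert (ig.shape, ig.rate) == pytest.approx((2.0, 2.0))

    def test_matches_grid_oracle(self):
        resid = np.array([0.8, -1.1, 0.3, 0.6])
        data, state = _make(n=4, P=resid.reshape(4, 1), I=[0.0] * 4)
        ig = full_conditional_noise(0, state, data, PriorConfig())
        post = stats.invgamma(ig.shape, scale=ig.rate)
        omean, ovar = inverse_gamma_product_moments(1.0, 1.0, resid)
        assert post.mean() == pytest.approx(omean, abs=1e-5)
        assert post.var() == pytest.approx(ovar, abs=1e-4)

    def test_posterior_mean_monotone_in_rss(self):
        small = _make(n=2, P=[[0.1], [-0.1]], I=[0.0, 0.0])
        large = _make(n=2, P=[[2.0], [-2.0]], I=[0.0, 0.0])
        igs = full_conditional_noise(0, small[1], small[0], PriorConfig())
        igl = full_conditional_noise(0, large[1], large[0], PriorConfig())
        mean = lambda ig: ig.rate / (ig.shape - 1)
        assert mean(igs) < mean(igl)
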