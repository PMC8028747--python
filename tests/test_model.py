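"""Model layer: scaling constant, variance components, marginal likelihood."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import ndtr, roots_hermitenorm

from sgtlm import (ClusterData, MixingSpec, Panel, Theta, check_identifiability,
                   cluster_loglik, latent_icc, marginal_loglik,
                   random_effects_cov, success_prob, upsilon0)
from sgtlm.model import cluster_marginal_params
from sgtlm.mvt import MvtOptions

HI = MvtOptions(points=2048, shifts=8)


class TestUpsilon0:
    @pytest.mark.parametrize("deps,nu,expected", [
        (0.0, np.inf, 1.0),
        (-2.0, 5.0, 0.4598),              # the heavy-tail simulation setting
        (0.0, 5.0, math.sqrt(3 / 5)),
    ])
    def test_values(self, deps, nu, expected):
        assert upsilon0(deps, nu) == pytest.approx(expected, abs=5e-5)

    def test_domain(self):
        with pytest.raises(ValueError):
            upsilon0(0.5, 2.0)

    def test_unit_conditional_variance(self):
        """ups0 standardizes Var{Z_ij | b_i} = 1 (Monte-Carlo check)."""
        rng = np.random.default_rng(2)
        deps, nu = -2.0, 5.0
        u0 = upsilon0(deps, nu)
        from sgtlm import mixing_moment
        u1 = mixing_moment(1, MixingSpec.skew_t(nu))
        n = 2_000_000
        u = rng.gamma(nu / 2, 2 / nu, n)
        v = np.abs(rng.standard_normal(n))
        z = (v / np.sqrt(u) - math.sqrt(2 / math.pi) * u1) * u0 * deps \
            + u0 / np.sqrt(u) * rng.standard_normal(n)
        assert z.var() == pytest.approx(1.0, abs=0.01)


class TestRandomEffectsCov:
    def test_simulation_design_truth(self):
        th = Theta(beta=[0.0], delta_eps=-2.0, delta=[0.0, 2.0],
                   d_bar=[[0.5, 0.25], [0.25, 1.0]], nu=5.0)
        sb = random_effects_cov(th)
        assert sb[0, 0] == pytest.approx(0.8333, abs=5e-4)
        assert sb[0, 1] == pytest.approx(0.4167, abs=5e-4)
        assert sb[1, 1] == pytest.approx(4.731, abs=5e-4)

    def test_normal_limit_reduces_to_dbar(self):
        th = Theta(beta=[0.0], delta_eps=0.0, delta=[0.0],
                   d_bar=[[0.7]], nu=np.inf)
        assert random_effects_cov(th)[0, 0] == pytest.approx(0.7)

    def test_psd(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            A = rng.standard_normal((2, 2))
            th = Theta(beta=[0.0], delta_eps=rng.standard_normal(),
                       delta=rng.standard_normal(2), d_bar=A @ A.T + np.eye(2),
                       nu=4.5)
            assert np.linalg.eigvalsh(random_effects_cov(th))[0] > 0


class TestLatentIcc:
    def test_probit_limit(self):
        th = Theta(beta=[0.0], delta_eps=0.0, delta=[0.0], d_bar=[[0.5]],
                   nu=np.inf)
        assert latent_icc(th) == pytest.approx(0.5 / 1.5)

    def test_no_clustering(self):
        th = Theta(beta=[0.0], delta_eps=0.0, delta=[0.0], d_bar=[[1e-12]],
                   nu=np.inf)
        assert latent_icc(th) == pytest.approx(0.0, abs=1e-9)

    def test_mc_latent_correlation(self):
        """ICC matches the empirical correlation of two latent outcomes."""
        deps, nu, s2 = -1.0, 5.0, 0.5
        th = Theta(beta=[0.0], delta_eps=deps, delta=[0.0], d_bar=[[s2]],
                   nu=nu, upsilon0=upsilon0(deps, nu))
        rng = np.random.default_rng(4)
        from sgtlm import mixing_moment
        u1 = mixing_moment(1, MixingSpec.skew_t(nu))
        c = math.sqrt(2 / math.pi)
        n = 2_000_000
        u = rng.gamma(nu / 2, 2 / nu, n)
        v = np.abs(rng.standard_normal(n))
        shift = v / np.sqrt(u) - c * u1
        b = shift * 0.0 + np.sqrt(s2) * rng.standard_normal(n) / np.sqrt(u)
        u0 = th.upsilon0
        eps = rng.standard_normal((n, 2))
        z = b[:, None] + shift[:, None] * u0 * deps + u0 * eps / np.sqrt(u)[:, None]
        assert latent_icc(th) == pytest.approx(np.corrcoef(z.T)[0, 1], abs=0.01)

    def test_requires_random_intercept_model(self):
        th = Theta(beta=[0.0], delta_eps=0.0, delta=[0.0, 0.0],
                   d_bar=np.eye(2), nu=5.0)
        with pytest.raises(ValueError):
            latent_icc(th)


class TestClusterMarginalParams:
    def test_symmetric_case(self):
        th = Theta(beta=[1.0, -0.5], delta_eps=0.0, delta=[0.0],
                   d_bar=[[0.4]], nu=5.0)
        c = ClusterData(y=[0, 1], X=[[1.0, 0.2], [1.0, -0.1]],
                        W=[[1.0], [1.0]], id=0)
        mp = cluster_marginal_params(th, c)
        assert np.allclose(mp.lam_i, 0)
        assert np.allclose(mp.mu_i, c.X @ th.beta)

    def test_intercept_confounding(self):
        """With W = J only deps + delta0 enters the marginal shape."""
        base = dict(beta=[0.0], d_bar=[[0.4]], nu=5.0)
        c = ClusterData(y=[0, 1, 1], X=np.ones((3, 1)), W=np.ones((3, 1)), id=0)
        th1 = Theta(delta_eps=0.8, delta=[0.2], **base)
        th2 = Theta(delta_eps=0.0, delta=[1.0], **base)
        mp1 = cluster_marginal_params(th1, c)
        mp2 = cluster_marginal_params(th2, c)
        assert np.allclose(mp1.delta_i, mp2.delta_i)
        assert np.allclose(mp1.omega_i, mp2.omega_i)

    def test_rank_one_shape_update(self):
        rng = np.random.default_rng(0)
        th = Theta(beta=[0.3], delta_eps=-1.0, delta=[0.0, 0.7],
                   d_bar=np.eye(2) * 0.5, nu=6.0)
        c = ClusterData(y=[0, 1, 0], X=rng.standard_normal((3, 1)),
                        W=np.column_stack([np.ones(3), rng.standard_normal(3)]),
                        id=0)
        mp = cluster_marginal_params(th, c)
        gap = mp.omega_i - mp.omega_bar_i
        assert np.linalg.matrix_rank(gap, tol=1e-10) == 1


class TestClusterLoglik:
    def test_probit_limit_single_observation(self):
        th = Theta(beta=[0.7], delta_eps=0.0, delta=[0.0], d_bar=[[0.5]],
                   nu=np.inf, fix_delta_eps=True, fix_delta_all=True)
        c1 = ClusterData(y=[1], X=[[1.0]], W=[[1.0]], id=0)
        ll = cluster_loglik(th, c1, HI)
        assert math.exp(ll) == pytest.approx(ndtr(0.7 / math.sqrt(1.5)), abs=1e-6)

    def test_patterns_sum_to_one(self):
        """Probabilities over all 2^n outcome patterns sum to 1."""
        rng = np.random.default_rng(3)
        th = Theta(beta=[-0.5, 0.8], delta_eps=-1.0, delta=[0.0, 1.2],
                   d_bar=[[0.5, 0.2], [0.2, 0.9]], nu=5.0,
                   fix_delta0=True).finalize_scale()
        X = np.column_stack([np.ones(3), rng.standard_normal(3)])
        W = np.column_stack([np.ones(3), rng.standard_normal(3)])
        vhi = MvtOptions(points=262144, shifts=4)
        total = 0.0
        for pat in itertools.product([0, 1], repeat=3):
            c = ClusterData(y=list(pat), X=X, W=W, id=0)
            total += math.exp(cluster_loglik(th, c, vhi))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_rescaling_invariance(self):
        """The terminal rescaling is a pure reparameterization."""
        th = Theta(beta=[-0.5, 0.8], delta_eps=-1.5, delta=[0.0, 1.0],
                   d_bar=[[0.5, 0.1], [0.1, 0.8]], nu=5.0, fix_delta0=True)
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(4), rng.standard_normal(4)])
        W = np.column_stack([np.ones(4), rng.standard_normal(4)])
        c = ClusterData(y=[0, 1, 1, 0], X=X, W=W, id=0)
        ll_em = cluster_loglik(th, c, HI)
        ll_rescaled = cluster_loglik(th.finalize_scale(), c, HI)
        assert ll_rescaled == pytest.approx(ll_em, abs=2e-6)

    def test_ni_cap(self):
        th = Theta(beta=[0.0], delta_eps=0.0, delta=[0.0], d_bar=[[0.5]], nu=5.0)
        c = ClusterData(y=np.zeros(12, dtype=int), X=np.ones((12, 1)),
                        W=np.ones((12, 1)), id=0)
        with pytest.raises(ValueError):
            cluster_loglik(th, c)

    def test_probit_limit_matches_gauss_hermite(self, probit_panel_small):
        """Normal-limit marginal log-likelihood vs adaptive-free GH quadrature."""
        panel, _ = probit_panel_small
        th = Theta(beta=[-1.1, 0.9], delta_eps=0.0, delta=[0.0, 0.0],
                   d_bar=[[0.6, 0.1], [0.1, 0.8]], nu=np.inf,
                   fix_delta_eps=True, fix_delta_all=True)
        x, wq = roots_hermitenorm(60)
        L = np.linalg.cholesky(np.asarray(th.d_bar))
        XX, YY = np.meshgrid(x, x, indexing="ij")
        nodes = np.stack([XX.ravel(), YY.ravel()], 1) @ L.T
        wgt = np.outer(wq, wq).ravel() / (2 * np.pi)
        ll_gh = 0.0
        for c in panel.clusters:
            eta = (c.X @ th.beta)[None, :] + nodes @ c.W.T
            pr = ndtr(eta)
            lik = np.prod(np.where(c.y[None, :] == 1, pr, 1 - pr), axis=1)
            ll_gh += math.log(float(wgt @ lik))
        ll_pkg, n_floored = marginal_loglik(th, panel, MvtOptions(points=8192,
                                                                  shifts=8))
        assert n_floored == 0
        assert ll_pkg == pytest.approx(ll_gh, abs=1e-3)


class TestSuccessProb:
    def test_probit_null(self):
        th = Theta(beta=[0.0], delta_eps=0.0, delta=[0.0], d_bar=[[1e-8]],
                   nu=np.inf, fix_delta_eps=True, fix_delta_all=True)
        assert success_prob(th, [0.0], [0.0], HI) == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_linear_predictor(self):
        th0 = Theta(beta=[0.0], delta_eps=-1.0, delta=[0.8], d_bar=[[0.5]],
                    nu=5.0).finalize_scale()
        from dataclasses import replace
        probs = [success_prob(replace(th0, beta=np.array([b0])), [1.0], [0.5], HI)
                 for b0 in np.linspace(-2, 2, 7)]
        assert np.all(np.diff(probs) > 0)

    def test_mc_frequency(self):
        th = Theta(beta=[0.4], delta_eps=-1.5, delta=[1.0], d_bar=[[0.6]],
                   nu=5.0).finalize_scale()
        rng = np.random.default_rng(9)
        from sgtlm import mixing_moment
        u1 = mixing_moment(1, MixingSpec.skew_t(5.0))
        c0 = math.sqrt(2 / math.pi)
        n = 2_000_000
        u = rng.gamma(2.5, 2 / 5, n)
        v = np.abs(rng.standard_normal(n))
        shift = v / np.sqrt(u) - c0 * u1
        b = shift * th.delta[0] + math.sqrt(th.d_bar[0, 0]) * \
            rng.standard_normal(n) / np.sqrt(u)
        w = 0.7
        z = th.beta[0] + w * b + shift * th.upsilon0 * th.delta_eps \
            + th.upsilon0 * rng.standard_normal(n) / np.sqrt(u)
        freq = (z > 0).mean()
        se = math.sqrt(freq * (1 - freq) / n)
        assert success_prob(th, [1.0], [w], HI) == pytest.approx(
            freq, abs=4 * se + 1e-4)


class TestIdentifiability:
    def _panel(self, X, W):
        n = X.shape[0]
        return Panel([ClusterData(y=np.zeros(n, int), X=X, W=W, id=0),
                      ClusterData(y=np.ones(n, int), X=X + 0.0, W=W, id=1)])

    def test_random_intercept_requires_delta0(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(4), rng.standard_normal(4)])
        W = np.column_stack([np.ones(4), rng.standard_normal(4)])
        assert check_identifiability(self._panel(X, W)) == ["fix_delta0"]

    def test_binary_design_requires_delta_eps(self):
        X = np.column_stack([np.ones(4), [0, 1, 0, 1.0]])
        W = np.array([[0.5], [0.1], [-0.2], [0.3]])
        assert check_identifiability(self._panel(X, W)) == ["fix_delta_eps"]

    def test_continuous_design_no_restriction(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(4), rng.standard_normal(4)])
        W = rng.standard_normal((4, 1))
        assert check_identifiability(self._panel(X, W)) == []

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        W = np.ones((4, 1))
        with pytest.raises(ValueError):
            check_identifiability(self._panel(X, W))
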