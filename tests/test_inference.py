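"""Scores, standard errors, information criteria, empirical Bayes."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import ndtr
from scipy.stats import norm

from sgtlm import (ClusterData, MixingSpec, Panel, Theta, eb_random_effects,
                   eb_weights, information_criteria, mixing_moment)
from sgtlm.em import FitControl, estep, fit, q_function
from sgtlm.inference import (attach_inference, cluster_scores,
                             delta_method_varcomp, observed_information,
                             pack_free, unpack_free)
from sgtlm.mvt import MvtOptions
from sgtlm.simstudy import SimDesign, simulate_dataset

HI = MvtOptions(points=2048, shifts=8)
MED = MvtOptions(points=512, shifts=4)

FAST = FitControl(loglik_rtol=1e-5, max_iter=200,
                  moment_options=MvtOptions(points=128, shifts=2),
                  loglik_options=MvtOptions(points=512, shifts=4))


@pytest.fixture(scope="module")
def toy_two_clusters():
    rng = np.random.default_rng(6)
    clusters = [
        ClusterData(y=[0, 1, 1], X=np.column_stack([np.ones(3),
                                                    rng.standard_normal(3)]),
                    W=np.column_stack([np.ones(3), rng.standard_normal(3)]),
                    id="a"),
        ClusterData(y=[1, 0], X=np.column_stack([np.ones(2),
                                                 rng.standard_normal(2)]),
                    W=np.column_stack([np.ones(2), rng.standard_normal(2)]),
                    id="b"),
    ]
    return Panel(clusters)


class TestScores:
    def test_finite_difference_against_q(self, toy_two_clusters):
        """Analytic per-cluster scores match numerical gradients of Q_i."""
        panel = toy_two_clusters
        th = Theta(beta=[0.3, -0.2], delta_eps=-0.6, delta=[0.0, 0.4],
                   d_bar=[[0.7, 0.1], [0.1, 0.5]], nu=5.0, fix_delta0=True)
        moments = estep(th, panel, HI)
        g = cluster_scores(th, panel, moments)
        v0 = pack_free(th)
        for ci in range(panel.n_clusters):
            sub = Panel([panel.clusters[ci]])
            mom = [moments[ci]]
            num = np.zeros_like(v0)
            for j in range(v0.size):
                h = 1e-6 * max(1.0, abs(v0[j]))
                vp, vm = v0.copy(), v0.copy()
                vp[j] += h
                vm[j] -= h
                num[j] = (q_function(unpack_free(th, vp), mom, sub)
                          - q_function(unpack_free(th, vm), mom, sub)) / (2 * h)
            assert np.allclose(g[ci], num, atol=2e-5 * max(1, np.abs(num).max()))

    def test_score_identity_at_ml(self):
        """Summed scores vanish at the converged estimate."""
        panel, _ = simulate_dataset(
            SimDesign(mechanism="probit", n_clusters=120, seed=23), 0)
        res = fit(panel, nu=np.inf, fix_delta_eps=True, fix_delta_all=True,
                  control=replace(FAST, loglik_rtol=1e-6))
        g = cluster_scores(res.theta_em, panel, options=MED)
        total = g.sum(axis=0)
        scale = np.abs(g).sum(axis=0)
        assert np.all(np.abs(total) < 0.02 * scale + 0.5)

    def test_information_invariant_to_cluster_order(self, toy_two_clusters):
        panel = toy_two_clusters
        th = Theta(beta=[0.3, -0.2], delta_eps=-0.6, delta=[0.0, 0.4],
                   d_bar=[[0.7, 0.1], [0.1, 0.5]], nu=5.0, fix_delta0=True)
        info1 = observed_information(th, panel, options=HI)
        panel_r = Panel(panel.clusters[::-1])
        info2 = observed_information(th, panel_r, options=HI)
        assert np.allclose(info1, info2, atol=1e-7)


class TestInformationCriteria:
    def test_printed_formulas(self):
        ic = information_criteria(-100.0, 5, 60)
        assert ic["aic"] == pytest.approx(210.0)
        assert ic["bic"] == pytest.approx(200 + 5 * math.log(60), abs=1e-10)
        assert ic["hq"] == pytest.approx(200 + 10 * math.log(math.log(60)),
                                         abs=1e-10)

    def test_needs_observations(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 2, 1)


class TestDeltaMethod:
    def test_linear_map_when_delta_fixed(self):
        """With delta frozen, SE(sigma_kl) = U2 * SE(dbar_kl)."""
        th = Theta(beta=[0.0], delta_eps=0.0, delta=[0.0, 0.0],
                   d_bar=[[0.5, 0.1], [0.1, 0.8]], nu=5.0,
                   fix_delta_eps=True, fix_delta_all=True)
        k = len(pack_free(th))
        vcov = np.diag(np.arange(1.0, k + 1.0))
        out = delta_method_varcomp(th, vcov)
        u2 = mixing_moment(2, MixingSpec.skew_t(5.0))
        # the vech tail of the free vector: dbar00, dbar10, dbar11
        ses = np.sqrt(np.diag(vcov)[-3:])
        assert out["sigma11"]["se"] == pytest.approx(u2 * ses[0], rel=1e-9)
        assert out["sigma12"]["se"] == pytest.approx(u2 * ses[1], rel=1e-9)
        assert out["sigma22"]["se"] == pytest.approx(u2 * ses[2], rel=1e-9)

    def test_gradient_by_finite_differences(self):
        from sgtlm.model import random_effects_cov, random_effects_cov_gradients
        th = Theta(beta=[0.0], delta_eps=-1.0, delta=[0.0, 1.5],
                   d_bar=[[0.5, 0.2], [0.2, 1.0]], nu=5.0, fix_delta0=True)
        grads = random_effects_cov_gradients(th)
        tail0 = np.concatenate([[th.delta[1]],
                                [th.d_bar[0, 0], th.d_bar[1, 0], th.d_bar[1, 1]]])

        def sigma_of(tail):
            d = np.array([0.0, tail[0]])
            db = np.array([[tail[1], tail[2]], [tail[2], tail[3]]])
            return random_effects_cov(replace(th, delta=d, d_bar=db))

        for (k, l), g in grads.items():
            num = np.zeros(4)
            for j in range(4):
                h = 1e-6
                tp, tm = tail0.copy(), tail0.copy()
                tp[j] += h
                tm[j] -= h
                num[j] = (sigma_of(tp)[k, l] - sigma_of(tm)[k, l]) / (2 * h)
            assert np.allclose(g, num, atol=1e-6)


class TestEmpiricalBayes:
    def test_probit_single_obs_matches_quadrature(self):
        """Normal-limit EB posterior mean of b given one binary outcome."""
        th = Theta(beta=[0.3], delta_eps=0.0, delta=[0.0], d_bar=[[0.8]],
                   nu=np.inf, fix_delta_eps=True, fix_delta_all=True)
        c = ClusterData(y=[1], X=[[1.0]], W=[[1.0]], id=0)
        b_hat = eb_random_effects(th, Panel([c]), HI)[0, 0]
        s = math.sqrt(0.8)
        num = quad(lambda b: b * ndtr(0.3 + b) * norm.pdf(b, scale=s),
                   -12, 12)[0]
        den = quad(lambda b: ndtr(0.3 + b) * norm.pdf(b, scale=s), -12, 12)[0]
        assert b_hat == pytest.approx(num / den, abs=1e-4)

    def test_population_mean_is_zero(self):
        """Average EB prediction over many clusters is near E{b} = 0."""
        panel, b_true = simulate_dataset(
            SimDesign(mechanism="sgt", n_clusters=300, seed=3), 0)
        design = SimDesign(mechanism="sgt", n_clusters=300, seed=3)
        th = Theta(beta=list(design.beta), delta_eps=-2.0, delta=[0.0, 2.0],
                   d_bar=design.d_bar, nu=5.0, upsilon0=design.upsilon0,
                   fix_delta0=True)
        b_hat = eb_random_effects(th, panel, MED)
        se = b_true.std(axis=0) / math.sqrt(300)
        assert np.all(np.abs(b_hat.mean(axis=0)) < 4 * se)
        # predictions correlate with the simulated effects
        for l in range(2):
            assert np.corrcoef(b_hat[:, l], b_true[:, l])[0, 1] > 0.3

    def test_eb_rejection_oracle_small_cluster(self):
        """E{b | y} and E{U | y} against a latent-hierarchy rejection oracle."""
        th = Theta(beta=[0.2], delta_eps=-1.0, delta=[0.9], d_bar=[[0.5]],
                   nu=5.0).finalize_scale()
        X = np.array([[1.0], [1.0]])
        W = np.array([[0.6], [-0.4]])
        y = np.array([1, 0])
        panel = Panel([ClusterData(y=y, X=X, W=W, id=0)])
        b_hat = eb_random_effects(th, panel, HI)[0, 0]
        u_hat = eb_weights(th, panel, HI)[0]
        rng = np.random.default_rng(31)
        n = 4_000_000
        u1 = mixing_moment(1, MixingSpec.skew_t(5.0))
        c0 = math.sqrt(2 / math.pi)
        u = rng.gamma(2.5, 2 / 5, n)
        v = np.abs(rng.standard_normal(n))
        shift = v / np.sqrt(u) - c0 * u1
        b = shift * th.delta[0] + math.sqrt(th.d_bar[0, 0]) * \
            rng.standard_normal(n) / np.sqrt(u)
        u0 = th.upsilon0
        z = (th.beta[0] + W[:, 0][None, :] * b[:, None]
             + (shift * u0 * th.delta_eps)[:, None]
             + u0 * rng.standard_normal((n, 2)) / np.sqrt(u)[:, None])
        keep = (z[:, 0] > 0) & (z[:, 1] <= 0)
        bk, uk = b[keep], u[keep]
        nk = keep.sum()
        assert b_hat == pytest.approx(bk.mean(),
                                      abs=4 * bk.std() / math.sqrt(nk))
        assert u_hat == pytest.approx(uk.mean(),
                                      abs=4 * uk.std() / math.sqrt(nk))

    def test_weights_unit_in_normal_limit_and_on_average(self):
        panel, _ = simulate_dataset(
            SimDesign(mechanism="probit", n_clusters=200, seed=8), 0)
        th_inf = Theta(beta=[-1.0, 1.0], delta_eps=0.0, delta=[0.0, 0.0],
                       d_bar=np.eye(2) * 0.5, nu=np.inf,
                       fix_delta_eps=True, fix_delta_all=True)
        assert np.allclose(eb_weights(th_inf, panel), 1.0)
        # law of total expectation: E{E{U|y}} = E{U} = 1
        th5 = replace(th_inf, nu=5.0)
        w = eb_weights(th5, panel, MED)
        assert w.mean() == pytest.approx(1.0, abs=0.05)


class TestAttachInference:
    def test_probit_se_close_to_gauss_hermite_glmm(self):
        """Empirical-information SEs agree with numerically-maximized
        Gauss-Hermite likelihood curvature within 15%."""
        panel, _ = simulate_dataset(
            SimDesign(mechanism="probit", n_clusters=250, seed=14), 0)
        res = fit(panel, nu=np.inf, fix_delta_eps=True, fix_delta_all=True,
                  control=replace(FAST, loglik_rtol=1e-6))
        res = attach_inference(res, panel, compute_eb=False)
        # reference: numerical Hessian of the GH marginal likelihood in beta
        from scipy.special import roots_hermitenorm
        x, wq = roots_hermitenorm(40)
        L = np.linalg.cholesky(res.theta.d_bar)
        XX, YY = np.meshgrid(x, x, indexing="ij")
        nodes = np.stack([XX.ravel(), YY.ravel()], 1) @ L.T
        wgt = np.outer(wq, wq).ravel() / (2 * np.pi)

        def nll(beta):
            tot = 0.0
            for c in panel.clusters:
                eta = (c.X @ beta)[None, :] + nodes @ c.W.T
                pr = ndtr(eta)
                lik = np.prod(np.where(c.y[None, :] == 1, pr, 1 - pr), axis=1)
                tot += math.log(float(wgt @ lik))
            return -tot

        b0 = res.theta.beta
        h = 1e-4
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                bpp, bpm, bmp, bmm = (b0.copy() for _ in range(4))
                bpp[i] += h; bpp[j] += h
                bpm[i] += h; bpm[j] -= h
                bmp[i] -= h; bmp[j] += h
                bmm[i] -= h; bmm[j] -= h
                H[i, j] = (nll(bpp) - nll(bpm) - nll(bmp) + nll(bmm)) / (4 * h * h)
        se_ref = np.sqrt(np.diag(np.linalg.inv(H)))
        assert np.all(np.abs(res.se[:2] / se_ref - 1.0) < 0.15)

    def test_ic_parameter_count(self, toy_two_clusters):
        panel = toy_two_clusters
        res = fit(panel, nu=5.0, fix_delta0=True,
                  control=replace(FAST, max_iter=10))
        res = attach_inference(res, panel, compute_eb=False)
        # beta(2) + delta_eps + delta1 + vech(3) = 7 free parameters
        assert len(res.free_labels) == 7
        assert res.ic["aic"] == pytest.approx(-2 * res.loglik + 14)
        res2 = attach_inference(res, panel, include_nu=True, compute_eb=False)
        assert res2.ic["aic"] == pytest.approx(-2 * res.loglik + 16)
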