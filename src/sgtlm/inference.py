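"""Standard errors, information criteria and empirical-Bayes predictions.

Standard errors follow the empirical-information method: the observed
information is approximated by the sum of outer products of per-cluster
scores of the expected complete-data log-likelihood, evaluated at the ML
estimate on the working (upsilon0 = 1) scale.  The covariance is then
mapped to the reported, variance-standardized scale through the Jacobian of
the terminal rescaling (which depends on delta_eps through upsilon0).

Empirical-Bayes estimators are conditional means given the observed binary
pattern: random effects via the truncated-skew-t moment chains at orders
r in {0, 1, -1}, and cluster weights u2_i = E{U_i | y_i} (weights below 1
flag outlying clusters).
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from ._linalg import vech_indices
from .data import Panel
from .em import EStepMoments, FitResult, estep
from .model import (Theta, cluster_marginal_params, random_effects_cov,
                    random_effects_cov_gradients)
from .mvt import CdfPlan, MvtOptions
from .sgt_core import HALF_NORMAL_MEAN, mixing_moment
from .trunc_moments import TruncRegion, _JointJob

__all__ = ["observed_information", "information_criteria", "delta_method_varcomp",
           "eb_random_effects", "eb_weights", "attach_inference",
           "pack_free", "unpack_free"]

_C = HALF_NORMAL_MEAN


# ---------------------------------------------------------------------------
# free-parameter packing
# ---------------------------------------------------------------------------

def pack_free(theta: Theta) -> np.ndarray:
    """Free parameters in the order (beta, delta_eps?, delta_free, vech(D_bar))."""
    v = [theta.beta]
    if not theta.fix_delta_eps:
        v.append([theta.delta_eps])
    if not theta.fix_delta_all:
        start = 1 if theta.fix_delta0 else 0
        v.append(theta.delta[start:])
    q = theta.q
    v.append(theta.d_bar[vech_indices(q)])  # column-major lower triangle
    return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in v])


def unpack_free(template: Theta, v: np.ndarray) -> Theta:
    p, q = template.p, template.q
    v = np.asarray(v, dtype=float)
    k = 0
    beta = v[k:k + p]; k += p
    deps = template.delta_eps
    if not template.fix_delta_eps:
        deps = float(v[k]); k += 1
    delta = np.zeros(q)
    if not template.fix_delta_all:
        start = 1 if template.fix_delta0 else 0
        delta[start:] = v[k:k + q - start]; k += q - start
    d_bar = np.zeros((q, q))
    iu = vech_indices(q)
    d_bar[iu] = v[k:]
    d_bar = d_bar + d_bar.T - np.diag(np.diag(d_bar))
    return replace(template, beta=beta, delta_eps=deps, delta=delta, d_bar=d_bar)


def _rescale_jacobian(theta_em: Theta, eps: float = 1e-6) -> np.ndarray:
    """Jacobian of the terminal-rescaling map on the free-parameter vector."""
    v0 = pack_free(theta_em)
    def f(v):
        return pack_free(unpack_free(theta_em, v).finalize_scale())
    n = v0.size
    J = np.empty((n, n))
    for j in range(n):
        h = eps * max(1.0, abs(v0[j]))
        vp, vm = v0.copy(), v0.copy()
        vp[j] += h
        vm[j] -= h
        J[:, j] = (f(vp) - f(vm)) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# observed information
# ---------------------------------------------------------------------------

def cluster_scores(theta: Theta, panel: Panel,
                   moments: list[EStepMoments] | None = None,
                   options: MvtOptions | None = None) -> np.ndarray:
    """Per-cluster scores of Q_i(.|theta_hat) at theta_hat (upsilon0 = 1)."""
    if theta.upsilon0 != 1.0:
        raise ValueError("scores are defined on the upsilon0 = 1 working scale")
    if moments is None:
        moments = estep(theta, panel, options)
    u1 = mixing_moment(1, theta.mixing)
    q = theta.q
    dinv = np.linalg.inv(theta.d_bar)
    rows = []
    for m, c in zip(moments, panel.clusters):
        X, W = c.X, c.W
        J = np.ones(c.n)
        xb = X @ theta.beta
        s1 = m.u2z - W @ m.u2b
        s2 = m.vu - _C * u1 * m.u2
        s3 = m.v2 - 2 * _C * u1 * m.vu + (_C * u1) ** 2 * m.u2
        s4 = m.vuz - W @ m.vub
        vub_bar = m.vub - _C * u1 * m.u2b
        g = [-(m.u2 * (X.T @ X) @ theta.beta
               - X.T @ (s1 - theta.delta_eps * s2 * J))]
        if not theta.fix_delta_eps:
            g.append([-(s2 * float(J @ xb) + theta.delta_eps * c.n * s3
                        - float(J @ (s4 - _C * u1 * s1)))])
        if not theta.fix_delta_all:
            gd = -dinv @ (s3 * theta.delta - vub_bar)
            start = 1 if theta.fix_delta0 else 0
            g.append(gd[start:])
        gD = (-0.5 * dinv
              + 0.5 * dinv @ (m.u2b2 - np.outer(theta.delta, vub_bar)
                              - np.outer(vub_bar, theta.delta)
                              + s3 * np.outer(theta.delta, theta.delta)) @ dinv)
        # vech gradient of a symmetric-matrix derivative: off-diagonals doubled
        tri = vech_indices(q)
        vech = np.where(tri[0] == tri[1], 1.0, 2.0) * gD[tri]
        g.append(vech)
        rows.append(np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in g]))
    return np.vstack(rows)


def observed_information(theta: Theta, panel: Panel,
                         moments: list[EStepMoments] | None = None,
                         options: MvtOptions | None = None) -> np.ndarray:
    """Empirical observed information sum_i g_i g_i' on the working scale."""
    g = cluster_scores(theta, panel, moments, options)
    return g.T @ g


def information_criteria(loglik: float, n_params: int, n_obs: int) -> dict:
    """AIC, BIC and Hannan-Quinn penalized-likelihood criteria."""
    if n_obs <= 1:
        raise ValueError("information criteria need more than one observation")
    return {
        "aic": -2.0 * loglik + 2.0 * n_params,
        "bic": -2.0 * loglik + n_params * math.log(n_obs),
        "hq": -2.0 * loglik + 2.0 * n_params * math.log(math.log(n_obs)),
    }


def delta_method_varcomp(theta: Theta, vcov: np.ndarray) -> dict:
    """Standard errors of the Sigma_b entries by the delta method.

    ``theta`` and ``vcov`` must live on the same (reported) scale; the
    gradient runs over the (delta_free, vech D_bar) tail of the free vector.
    """
    grads = random_effects_cov_gradients(theta)
    sigma_b = random_effects_cov(theta)
    ntail = next(iter(grads.values())).size
    Vt = vcov[-ntail:, -ntail:]
    out = {}
    for (k, l), g in grads.items():
        var = float(g @ Vt @ g)
        out[f"sigma{k + 1}{l + 1}"] = {
            "estimate": float(sigma_b[k, l]),
            "se": math.sqrt(max(var, 0.0)),
        }
    return out


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def eb_random_effects(theta: Theta, panel: Panel,
                      options: MvtOptions | None = None) -> np.ndarray:
    """Conditional means E{b_i | y_i} at the reported parameter scale.

    b_bar_i = r_i (zbar_i - X_i beta) + (vu_inv_i - c U1) s_i, where
    vu_inv_i = E{V U^{-1/2} | y} = M (M Delta' Obar^{-1} (zbar_i - mu_i)
    + tau_{-1}) combines the r = 0 moment chain with the zeta1-tilted
    scalar at order r = -1 (conditioning V on (Z, U) makes the U powers in
    the location term cancel).  The skew channel drops out when s_i = 0
    (symmetric models).
    """
    mix = theta.mixing
    u1 = mixing_moment(1, mix)
    nu = np.inf if mix.is_normal_limit else theta.nu
    plan = CdfPlan()
    jobs = []
    for c in panel.clusters:
        mp = cluster_marginal_params(theta, c)
        region = TruncRegion.from_binary(c.y)
        obar = mp.omega_bar_i
        r_i = theta.d_bar @ c.W.T @ np.linalg.inv(obar)
        s_i = theta.delta - r_i @ mp.delta_i
        skew = bool(np.any(np.abs(s_i) > 1e-14))
        j0 = _JointJob(plan, mp.mu_i, mp.omega_i, mp.delta_i, nu, region,
                       r=0, order=1, need_tau=False)
        jm = None
        if skew:
            jm = _JointJob(plan, mp.mu_i, mp.omega_i, mp.delta_i, nu, region,
                           r=-1, order=0, tau_order=0, need_tau=True,
                           need_u=False)
        jobs.append((c, mp, r_i, s_i, j0, jm))
    values = plan.solve(options)
    out = []
    for c, mp, r_i, s_i, j0, jm in jobs:
        zbar = j0.finish(values).urz1
        b = r_i @ (zbar - c.X @ theta.beta)
        if jm is not None:
            taum = jm.finish(values).taur
            od = np.linalg.solve(mp.omega_bar_i, mp.delta_i)
            ualpha = mp.M_i * float(od @ (zbar - mp.mu_i))
            vu_inv = mp.M_i * (ualpha + taum)
            b = b + (vu_inv - _C * u1) * s_i
        out.append(b)
    return np.vstack(out)


def eb_weights(theta: Theta, panel: Panel,
               options: MvtOptions | None = None) -> np.ndarray:
    """Cluster weights u2_i = E{U_i | y_i}; values < 1 flag outliers."""
    if theta.mixing.is_normal_limit:
        return np.ones(panel.n_clusters)
    plan = CdfPlan()
    jobs = []
    for c in panel.clusters:
        mp = cluster_marginal_params(theta, c)
        jobs.append(_JointJob(plan, mp.mu_i, mp.omega_i, mp.delta_i, theta.nu,
                              TruncRegion.from_binary(c.y),
                              r=2, order=0, need_tau=False))
    values = plan.solve(options)
    return np.array([j.finish(values).ur for j in jobs])


# ---------------------------------------------------------------------------
# one-stop attachment to a FitResult
# ---------------------------------------------------------------------------

def attach_inference(res: FitResult, panel: Panel, include_nu: bool = False,
                     compute_eb: bool = True,
                     options: MvtOptions | None = None) -> FitResult:
    """Fill se/vcov/ic/eb on a FitResult (reported parameter scale)."""
    theta_em = res.theta_em
    info = observed_information(theta_em, panel, options=options)
    try:
        vcov_em = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov_em = np.linalg.pinv(info)
    J = _rescale_jacobian(theta_em)
    vcov = J @ vcov_em @ J.T
    res.vcov = vcov
    res.se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    res.free_labels = res.theta.free_labels()
    n_params = len(res.free_labels) + (1 if include_nu else 0)
    res.ic = information_criteria(res.loglik, n_params, panel.n_obs)
    if compute_eb:
        res.eb = {
            "b": eb_random_effects(res.theta, panel, options),
            "u2": (eb_weights(res.theta, panel, options)),
        }
    return res
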