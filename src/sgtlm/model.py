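"""The skew generalized t-link mixed binomial model (SGTLM).

Latent-variable formulation: each binary outcome is the sign indicator of a
latent continuous outcome

    Y_ij = 1{Z_ij > 0},
    Z_i  ~ SGT_{n_i}(eta_i - c*U1*ups0*deps*J, Omega_eps_i, deps*J, (nu, nu*ups0^2)),
    b_i  ~ ST_q(-c*U1*delta_bar, D, lambda, nu),

with eta_i = X_i beta + W_i b_i, link skewness deps, random-effects working
shape delta, scale matrix D_bar (D = D_bar + delta delta'), and the scaling
constant ups0 chosen so the conditional latent variance is one — making beta
directly comparable with probit fixed effects.  deps = delta = 0 and
nu -> inf recovers the probit GLMM; delta = deps = 0 gives the (generalized)
t-link model; nu -> inf alone the skew-probit model.

Marginally Z_i is skew-t, so each cluster's likelihood contribution is a
single n_i-dimensional skew-t cdf evaluated through the sign-flip matrix
A_i = diag(1 - 2 y_ij).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._linalg import check_pd
from .data import ClusterData, Panel
from .mvt import CdfPlan, MvtOptions
from .sgt_core import HALF_NORMAL_MEAN, MixingSpec, mixing_moment
from .trunc_moments import _submit_st_cdf

__all__ = [
    "Theta", "MarginalClusterParams", "upsilon0", "random_effects_cov",
    "latent_icc", "cluster_marginal_params", "cluster_loglik",
    "marginal_loglik", "success_prob", "check_identifiability",
    "LOGLIK_FLOOR",
]

_C = HALF_NORMAL_MEAN

#: floor applied to cluster probabilities before taking logs
LOGLIK_FLOOR = 1e-300

#: default cap on cluster size for the cdf accuracy envelope
DEFAULT_NI_CAP = 10


@dataclass(frozen=True)
class Theta:
    """SGTLM parameter theta = (beta, deps, delta, vech(D_bar)) plus nu.

    ``upsilon0`` is the latent scaling constant: 1 during EM, the
    variance-standardizing value after the terminal rescaling.  ``nu = inf``
    encodes the probit / skew-probit limits.
    """

    beta: np.ndarray
    delta_eps: float
    delta: np.ndarray
    d_bar: np.ndarray
    nu: float
    upsilon0: float = 1.0
    fix_delta_eps: bool = False
    fix_delta0: bool = False
    fix_delta_all: bool = False

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        d_bar = check_pd(self.d_bar, "d_bar")
        if delta.shape[0] != d_bar.shape[0]:
            raise ValueError("delta / d_bar dimension mismatch")
        if not (self.nu > 2):
            raise ValueError("nu must exceed 2 (use inf for the normal limit)")
        if not (self.upsilon0 > 0):
            raise ValueError("upsilon0 must be positive")
        if self.fix_delta_eps and self.delta_eps != 0.0:
            raise ValueError("delta_eps restricted to zero but nonzero value supplied")
        if self.fix_delta0 and delta[0] != 0.0:
            raise ValueError("delta[0] restricted to zero but nonzero value supplied")
        if self.fix_delta_all and np.any(delta != 0.0):
            raise ValueError("delta restricted to zero but nonzero value supplied")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "d_bar", d_bar)

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def q(self) -> int:
        return self.delta.shape[0]

    @property
    def mixing(self) -> MixingSpec:
        if np.isinf(self.nu):
            return MixingSpec.normal_limit()
        return MixingSpec.skew_t(self.nu)

    def finalize_scale(self) -> "Theta":
        """Apply the terminal rescaling beta <- u0*beta, delta <- u0*delta,
        D_bar <- u0^2*D_bar with u0 = upsilon0(delta_eps, nu)."""
        u0 = upsilon0(self.delta_eps, self.nu)
        return replace(self, beta=u0 * self.beta, delta=u0 * self.delta,
                       d_bar=u0 ** 2 * self.d_bar, upsilon0=u0)

    def free_labels(self) -> list[str]:
        """Names of free parameters, in estimation order."""
        q = self.q
        labels = [f"beta{j}" for j in range(self.p)]
        if not self.fix_delta_eps:
            labels.append("delta_eps")
        if not self.fix_delta_all:
            for k in range(q):
                if k == 0 and self.fix_delta0:
                    continue
                labels.append(f"delta{k}")
        for i in range(q):
            for j in range(i, q):
                labels.append(f"dbar{j}{i}")
        return labels


@dataclass(frozen=True)
class MarginalClusterParams:
    """Marginal skew-t parameters of one cluster's latent vector."""

    mu_i: np.ndarray
    omega_i: np.ndarray
    omega_bar_i: np.ndarray
    delta_i: np.ndarray
    lam_i: np.ndarray
    M_i: float


def upsilon0(delta_eps: float, nu: float) -> float:
    """Latent scaling constant [U2 + (U2 - c^2 U1^2) deps^2]^{-1/2}.

    Forces Var{Z_ij | b_i} = 1 so fixed effects keep the probit scale.
    Tends to 1 as deps -> 0 and nu -> inf.
    """
    mix = MixingSpec.normal_limit() if np.isinf(nu) else MixingSpec.skew_t(nu)
    if not mix.is_normal_limit and nu <= 2:
        raise ValueError("upsilon0 requires nu > 2")
    u1 = mixing_moment(1, mix)
    u2 = mixing_moment(2, mix)
    return (u2 + (u2 - _C ** 2 * u1 ** 2) * delta_eps ** 2) ** -0.5


def random_effects_cov(theta: Theta) -> np.ndarray:
    """Sigma_b = U2*D_bar + (U2 - c^2 U1^2) delta delta'."""
    mix = theta.mixing
    u1 = mixing_moment(1, mix)
    u2 = mixing_moment(2, mix)
    return u2 * theta.d_bar + (u2 - _C ** 2 * u1 ** 2) * np.outer(theta.delta, theta.delta)


def random_effects_cov_gradients(theta: Theta):
    """Gradients of each Sigma_b entry w.r.t. (free delta elements, vech D_bar).

    Returned as a dict mapping entry label (k, l) -> gradient vector aligned
    with the (delta, vech D_bar) tail of the free-parameter vector.
    """
    q = theta.q
    mix = theta.mixing
    u1 = mixing_moment(1, mix)
    u2 = mixing_moment(2, mix)
    w = u2 - _C ** 2 * u1 ** 2
    if theta.fix_delta_all:
        free_delta = []
    else:
        free_delta = [k for k in range(q) if not (k == 0 and theta.fix_delta0)]
    nd = len(free_delta)
    nvech = q * (q + 1) // 2
    grads = {}
    vech_pos = {}
    pos = 0
    for i in range(q):
        for j in range(i, q):
            vech_pos[(j, i)] = pos
            pos += 1
    for k in range(q):
        for l in range(k, q):
            g = np.zeros(nd + nvech)
            for m, kk in enumerate(free_delta):
                d = 0.0
                if kk == k:
                    d += w * theta.delta[l]
                if kk == l:
                    d += w * theta.delta[k]
                g[m] = d
            g[nd + vech_pos[(max(k, l), min(k, l))]] = u2
            grads[(k, l)] = g
    return grads


def latent_icc(theta: Theta) -> float:
    """Latent intra-class correlation for a random-intercept-only model.

    rho = [U2 s2 + (U2 - c^2 U1^2) u0^2 deps^2]
          / [U2 (u0^2 + s2) + (U2 - c^2 U1^2) u0^2 deps^2], s2 = D_bar_11.
    """
    if theta.q != 1 or theta.delta[0] != 0.0:
        raise ValueError("latent ICC is defined for a pure random-intercept model "
                         "(q = 1, delta = 0)")
    mix = theta.mixing
    u1 = mixing_moment(1, mix)
    u2 = mixing_moment(2, mix)
    w = u2 - _C ** 2 * u1 ** 2
    s2 = float(theta.d_bar[0, 0])
    u0sq = theta.upsilon0 ** 2
    num = u2 * s2 + w * u0sq * theta.delta_eps ** 2
    den = u2 * (u0sq + s2) + w * u0sq * theta.delta_eps ** 2
    return num / den


def cluster_marginal_params(theta: Theta, cluster: ClusterData) -> MarginalClusterParams:
    """Marginal ST parameters of Z_i: location, scale, shape.

    mu_i = X_i beta - c U1 Delta_i,  Obar_i = u0^2 I + W D_bar W',
    Delta_i = u0 deps J + W delta,   Omega_i = Obar_i + Delta_i Delta_i'.
    """
    X, W = cluster.X, cluster.W
    if X.shape[1] != theta.p or W.shape[1] != theta.q:
        raise ValueError("cluster design does not match theta dimensions")
    mix = theta.mixing
    u1 = mixing_moment(1, mix)
    u0 = theta.upsilon0
    n = cluster.n
    delta_i = u0 * theta.delta_eps * np.ones(n) + W @ theta.delta
    obar = u0 ** 2 * np.eye(n) + W @ theta.d_bar @ W.T
    omega = obar + np.outer(delta_i, delta_i)
    mu_i = X @ theta.beta - _C * u1 * delta_i
    t = float(delta_i @ np.linalg.solve(obar, delta_i))
    M = (1.0 + t) ** -0.5
    from ._linalg import inv_sqrtm_sym
    lam_i = inv_sqrtm_sym(omega) @ delta_i / M
    return MarginalClusterParams(mu_i=mu_i, omega_i=omega, omega_bar_i=obar,
                                 delta_i=delta_i, lam_i=lam_i, M_i=M)


def _submit_cluster_loglik(plan: CdfPlan, theta: Theta, cluster: ClusterData) -> int:
    """Submit the augmented-T cdf behind one cluster's likelihood.

    f(y_i) = ST_{n_i}(0 | A mu_i, A Omega_i A, A lambda_i, nu') with
    A = diag(1 - 2 y_ij); the SGT degrees (nu, nu*u0^2) enter via the
    rescaled scale u0^2 already folded into Omega_i through upsilon0.
    """
    mp = cluster_marginal_params(theta, cluster)
    A = 1.0 - 2.0 * cluster.y
    nu = np.inf if np.isinf(theta.nu) else theta.nu
    return _submit_st_cdf(plan, np.zeros(cluster.n), A * mp.mu_i,
                          mp.omega_i * np.outer(A, A), A * mp.delta_i, nu)


def cluster_loglik(theta: Theta, cluster: ClusterData,
                   options: MvtOptions | None = None,
                   ni_cap: int = DEFAULT_NI_CAP) -> float:
    """Log probability of one cluster's outcome pattern."""
    if cluster.n > ni_cap:
        raise ValueError(
            f"cluster size {cluster.n} exceeds the cdf accuracy cap {ni_cap}")
    plan = CdfPlan()
    i = _submit_cluster_loglik(plan, theta, cluster)
    val = 2.0 * plan.solve(options)[i]
    return math.log(max(val, LOGLIK_FLOOR))


def marginal_loglik(theta: Theta, panel: Panel,
                    options: MvtOptions | None = None,
                    ni_cap: int = DEFAULT_NI_CAP):
    """Marginal log-likelihood summed over clusters (one batched cdf solve).

    Returns ``(loglik, n_floored)`` where n_floored counts clusters whose
    probability had to be floored at 1e-300.
    """
    plan = CdfPlan()
    idx = []
    for c in panel.clusters:
        if c.n > ni_cap:
            raise ValueError(
                f"cluster {c.id}: size {c.n} exceeds the cdf accuracy cap {ni_cap}")
        idx.append(_submit_cluster_loglik(plan, theta, c))
    vals = 2.0 * plan.solve(options)[idx]
    floored = int(np.sum(vals < LOGLIK_FLOOR))
    return float(np.sum(np.log(np.maximum(vals, LOGLIK_FLOOR)))), floored


def success_prob(theta: Theta, x, w, options: MvtOptions | None = None) -> float:
    """Marginal P(Y_ij = 1) for one observation with covariates (x, w)."""
    cluster = ClusterData(y=np.array([1]), X=np.atleast_2d(np.asarray(x, float)),
                          W=np.atleast_2d(np.asarray(w, float)), id="_one")
    return math.exp(cluster_loglik(theta, cluster, options))


def check_identifiability(panel: Panel, fix_delta_eps: bool = False,
                          fix_delta0: bool = False) -> list[str]:
    """Return the restrictions a design *requires* for identifiability.

    With only intercept/binary fixed covariates the conditional skew-probit
    link is unidentified: deps must be fixed at 0.  With a random-intercept
    column in W, only deps + delta_0 is identified: one of them must be
    pinned (delta_0 = 0 by default).  Raises on rank-deficient X.
    """
    X = panel.stacked_X()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("stacked fixed-effects design is rank deficient")
    required = []
    binary_only = all(np.isin(np.unique(X[:, j]), (0.0, 1.0)).all()
                      for j in range(X.shape[1]))
    if binary_only and not fix_delta_eps:
        required.append("fix_delta_eps")
    W = np.vstack([c.W for c in panel.clusters])
    has_intercept = any(np.ptp(W[:, j]) == 0.0 and W[0, j] != 0.0
                        for j in range(W.shape[1]))
    if has_intercept and not (fix_delta0 or fix_delta_eps):
        required.append("fix_delta0")
    return required
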