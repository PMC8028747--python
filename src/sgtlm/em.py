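"""Maximum-likelihood fitting of the SGTLM by a parameter-expanded EM algorithm.

The E-step reduces to truncated skew-t moment bundles per cluster (the
conditional latent vector given the observed signs), the M-step has closed
forms, and convergence is accelerated by expanding the complete-data model
with a q x q working scale matrix alpha acting on the random effects.  The
PX phase runs until the dominant eigenvalue of alpha - I falls below a
switch tolerance, after which plain EM iterates to convergence of the
marginal log-likelihood.  Throughout the iterations the scaling constant
upsilon0 is held at 1; the terminal rescaling restores the unit conditional
latent variance without changing the marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._linalg import nearest_pd
from .data import Panel
from .model import (Theta, cluster_marginal_params, marginal_loglik)
from .mvt import CdfPlan, EM_OPTIONS, MvtOptions
from .sgt_core import HALF_NORMAL_MEAN, mixing_moment
from .trunc_moments import TruncRegion, _JointJob

__all__ = ["FitControl", "EStepMoments", "FitResult", "estep", "mstep",
           "px_mstep", "fit", "select_nu", "q_function"]

_C = HALF_NORMAL_MEAN


@dataclass
class FitControl:
    """Iteration limits, tolerances and cdf accuracy knobs for the fitter."""

    max_iter: int = 500
    loglik_rtol: float = 1e-6
    px_switch_tol: float = 1e-2
    nu_grid: np.ndarray | None = None
    seed: int = 0
    verbose: bool = False
    moment_options: MvtOptions = field(default_factory=lambda: EM_OPTIONS)
    loglik_options: MvtOptions = field(default_factory=lambda: MvtOptions(points=512, shifts=4))
    ni_cap: int = 10

    @staticmethod
    def default_nu_grid() -> np.ndarray:
        # the application's selection grid: 2.5, 2.6, ..., 15
        return np.round(np.arange(2.5, 15.0 + 1e-9, 0.1), 10)


@dataclass
class EStepMoments:
    """Conditional-expectation bundle for one cluster (hats suppressed)."""

    u2: float
    u2z: np.ndarray
    u2z2: np.ndarray
    vu: float
    vuz: np.ndarray
    v2: float
    tau: float
    tauz: np.ndarray
    u2b: np.ndarray
    vub: np.ndarray
    u2bz: np.ndarray
    u2b2: np.ndarray


@dataclass
class FitResult:
    """Fitted SGTLM: rescaled estimate, trace and metadata.

    ``theta`` is on the final (upsilon0-standardized) scale; ``theta_em`` is
    the working upsilon0 = 1 estimate the EM converged to (used by the
    information-matrix machinery).
    """

    theta: Theta
    theta_em: Theta
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    n_px_iter: int
    converged: bool
    n_floored: int = 0
    # inference attachments (filled by sgtlm.inference)
    se: np.ndarray | None = None
    vcov: np.ndarray | None = None
    free_labels: list[str] | None = None
    ic: dict | None = None
    eb: dict | None = None
    nu_profile: list | None = None
    nu_at_edge: bool = False


def _needs_skew_channel(theta: Theta) -> bool:
    return not (theta.fix_delta_eps and theta.fix_delta_all)


def estep(theta: Theta, panel: Panel,
          options: MvtOptions | None = None) -> list[EStepMoments]:
    """Conditional expectations of the complete-data sufficient statistics.

    Evaluated with upsilon0 = 1.  Each cluster's conditional latent vector is
    a truncated skew-t; its (U, Z) and (V, Z) joint moments come from one
    pooled batch of low-dimensional t cdfs.
    """
    if theta.upsilon0 != 1.0:
        raise ValueError("the E-step runs on the upsilon0 = 1 scale")
    opts = options or EM_OPTIONS
    mix = theta.mixing
    u1 = mixing_moment(1, mix)
    nu = np.inf if mix.is_normal_limit else theta.nu
    skew = _needs_skew_channel(theta)
    plan = CdfPlan()
    jobs = []
    for c in panel.clusters:
        mp = cluster_marginal_params(theta, c)
        region = TruncRegion.from_binary(c.y)
        try:
            uj = _JointJob(plan, mp.mu_i, mp.omega_i, mp.delta_i, nu, region,
                           r=2, order=2, need_tau=False)
            tj = (_JointJob(plan, mp.mu_i, mp.omega_i, mp.delta_i, nu, region,
                            r=1, order=0, tau_order=1, need_tau=True,
                            need_u=False) if skew else None)
        except Exception as exc:
            raise RuntimeError(f"E-step failed for cluster {c.id}: {exc}") from exc
        jobs.append((c, mp, uj, tj))
    values = plan.solve(opts)

    out = []
    for c, mp, uj, tj in jobs:
        try:
            bu = uj.finish(values)
        except Exception as exc:
            raise RuntimeError(f"E-step failed for cluster {c.id}: {exc}") from exc
        u2, u2z, u2z2 = bu.ur, bu.urz1, bu.urz2
        obar = mp.omega_bar_i
        mu = mp.mu_i
        dlt = mp.delta_i
        M = mp.M_i
        od = np.linalg.solve(obar, dlt)
        if tj is not None:
            bt = tj.finish(values)
            tau, tauz = bt.taur, bt.taurz1
        else:
            # symmetric model: V is independent of the data given lambda_i = 0,
            # so the scalar channel collapses to E{V} = c, E{V^2} = 1 (the
            # z-vector channel is never consumed when all skewness is frozen)
            tau, tauz = _C, _C * u2z
        u2a = M * float(od @ (u2z - u2 * mu))
        taua = M * float(od @ (tauz - tau * mu))
        u2az = M * (u2z2 - np.outer(u2z, mu)) @ od
        u2a2 = M ** 2 * (u2 * float(od @ mu) ** 2
                         + float(od @ (u2z2 - 2.0 * np.outer(u2z, mu)) @ od))
        vu = M * (u2a + tau)
        vuz = M * (u2az + tauz)
        v2 = M ** 2 * (1.0 + taua + u2a2)
        X, W = c.X, c.W
        xb = X @ theta.beta
        r_i = theta.d_bar @ W.T @ np.linalg.inv(obar)
        lam_cap = (np.eye(theta.q) - r_i @ W) @ theta.d_bar
        s_i = theta.delta - r_i @ dlt
        u2b = r_i @ (u2z - u2 * xb) + (vu - _C * u1 * u2) * s_i
        vub = r_i @ (vuz - vu * xb) + (v2 - _C * u1 * vu) * s_i
        u2bz = r_i @ (u2z2 - np.outer(xb, u2z)) + np.outer(s_i, vuz - _C * u1 * u2z)
        s3 = v2 - 2.0 * _C * u1 * vu + (_C * u1) ** 2 * u2
        core = u2z2 + u2 * np.outer(xb, xb) - np.outer(u2z, xb) - np.outer(xb, u2z)
        cross = (vuz - vu * xb) - _C * u1 * (u2z - u2 * xb)
        u2b2 = (lam_cap + s3 * np.outer(s_i, s_i) + r_i @ core @ r_i.T
                + np.outer(r_i @ cross, s_i) + np.outer(s_i, r_i @ cross))
        u2b2 = 0.5 * (u2b2 + u2b2.T)
        out.append(EStepMoments(u2=u2, u2z=u2z, u2z2=u2z2, vu=vu, vuz=vuz,
                                v2=v2, tau=tau, tauz=tauz, u2b=u2b, vub=vub,
                                u2bz=u2bz, u2b2=u2b2))
    return out


def q_function(theta: Theta, moments: list[EStepMoments], panel: Panel) -> float:
    """Theta-dependent part of the expected complete-data log-likelihood.

    Evaluated with the conditional expectations ``moments`` held fixed (they
    come from the E-step at some reference theta); additive terms free of
    beta, delta_eps, delta and D_bar are dropped.  Used for M-step ascent
    checks and score validation.
    """
    u1 = mixing_moment(1, theta.mixing)
    n = panel.n_clusters
    sign, logdet = np.linalg.slogdet(theta.d_bar)
    if sign <= 0:
        return -np.inf
    dinv = np.linalg.inv(theta.d_bar)
    total = -0.5 * n * logdet
    for m, c in zip(moments, panel.clusters):
        X, W = c.X, c.W
        J = np.ones(c.n)
        beta = theta.beta
        deps = theta.delta_eps
        s2 = m.vu - _C * u1 * m.u2
        s3 = m.v2 - 2 * _C * u1 * m.vu + (_C * u1) ** 2 * m.u2
        u2g = m.u2z - W @ m.u2b - deps * s2 * J
        tr_u2g2 = (np.trace(m.u2z2) + np.trace(W @ m.u2b2 @ W.T)
                   - 2.0 * np.trace(W @ m.u2bz)
                   + c.n * deps ** 2 * s3
                   - 2.0 * deps * float(J @ ((m.vuz - W @ m.vub)
                                             - _C * u1 * (m.u2z - W @ m.u2b))))
        total -= 0.5 * (m.u2 * float(beta @ X.T @ X @ beta)
                        - 2.0 * float(beta @ X.T @ u2g) + tr_u2g2)
        vub_bar = m.vub - _C * u1 * m.u2b
        inner = (m.u2b2 - np.outer(vub_bar, theta.delta)
                 - np.outer(theta.delta, vub_bar)
                 + s3 * np.outer(theta.delta, theta.delta))
        total -= 0.5 * float(np.sum(dinv * inner))
    return total


# ---------------------------------------------------------------------------
# M-step helpers
# ---------------------------------------------------------------------------

def _suff(moments, panel, theta):
    """Per-cluster S-statistics and the global sums used by the updates."""
    u1 = mixing_moment(1, theta.mixing)
    S1, S2, S3, S4 = [], [], [], []
    for m, c in zip(moments, panel.clusters):
        S1.append(m.u2z - c.W @ m.u2b)
        S2.append(m.vu - _C * u1 * m.u2)
        S3.append(m.v2 - 2.0 * _C * u1 * m.vu + (_C * u1) ** 2 * m.u2)
        S4.append(m.vuz - c.W @ m.vub)
    return S1, np.array(S2), np.array(S3), S4


def _delta_update(moments, panel, theta, S3sum):
    """Constrained/unconstrained update of the working shape delta (ECM)."""
    u1 = mixing_moment(1, theta.mixing)
    q = theta.q
    if theta.fix_delta_all:
        return np.zeros(q)
    vub_bar = sum(m.vub - _C * u1 * m.u2b for m in moments)
    if not theta.fix_delta0:
        return vub_bar / S3sum
    # delta[0] frozen at 0: conditional maximization given the current d_bar
    P = np.linalg.inv(theta.d_bar)
    free = np.arange(1, q)
    delta = np.zeros(q)
    if free.size:
        rhs = (P @ vub_bar)[free]
        delta[free] = np.linalg.solve(P[np.ix_(free, free)], rhs) / S3sum
    return delta


def _dbar_update(moments, theta, delta_new, S3sum, n):
    u1 = mixing_moment(1, theta.mixing)
    vub_bar = sum(m.vub - _C * u1 * m.u2b for m in moments)
    acc = sum(m.u2b2 for m in moments)
    d_bar = (acc - np.outer(vub_bar, delta_new) - np.outer(delta_new, vub_bar)
             + S3sum * np.outer(delta_new, delta_new)) / n
    return nearest_pd(d_bar)


def mstep(moments: list[EStepMoments], panel: Panel, theta: Theta) -> Theta:
    """Closed-form joint update of (delta_eps, beta, delta, D_bar).

    delta_eps is updated first because the beta update references the new
    value; restricted components are excluded from their update equations.
    """
    u1 = mixing_moment(1, theta.mixing)
    S1, S2, S3, S4 = _suff(moments, panel, theta)
    Xs = [c.X for c in panel.clusters]
    Js = [np.ones(c.n) for c in panel.clusters]
    T1 = np.linalg.inv(sum(m.u2 * X.T @ X for m, X in zip(moments, Xs)))
    sxs1 = sum(X.T @ s1 for X, s1 in zip(Xs, S1))
    if theta.fix_delta_eps:
        deps = 0.0
    else:
        T2 = sum(s2 * (J @ X) for s2, J, X in zip(S2, Js, Xs))
        num = float(T2 @ T1 @ sxs1) - sum(float(J @ (s4 - _C * u1 * s1))
                                          for J, s4, s1 in zip(Js, S4, S1))
        den = float(T2 @ T1 @ T2) - float(sum(c.n * s3 for c, s3
                                              in zip(panel.clusters, S3)))
        deps = num / den
    beta = T1 @ sum(X.T @ (s1 - deps * s2 * J)
                    for X, s1, s2, J in zip(Xs, S1, S2, Js))
    S3sum = float(S3.sum())
    delta = _delta_update(moments, panel, theta, S3sum)
    d_bar = _dbar_update(moments, theta, delta, S3sum, panel.n_clusters)
    return replace(theta, beta=beta, delta_eps=deps, delta=delta, d_bar=d_bar)


def px_mstep(moments: list[EStepMoments], panel: Panel,
             theta: Theta) -> tuple[Theta, np.ndarray]:
    """Parameter-expanded M-step: joint (beta*, vec(alpha)) solve plus the
    reduction back to the original parameters.  Returns (theta_new, alpha).

    Under the delta0 = 0 restriction the working matrix is constrained to
    keep e1 invariant (first row of alpha = e1') so the reduction
    alpha @ delta* preserves the restriction.
    """
    q, p = theta.q, theta.p
    u1 = mixing_moment(1, theta.mixing)
    S1, S2, S3, S4 = _suff(moments, panel, theta)
    Xs = [c.X for c in panel.clusters]
    Ws = [c.W for c in panel.clusters]
    Js = [np.ones(c.n) for c in panel.clusters]

    d = p + q * q
    G = np.zeros((d, d))
    ups = np.zeros(d)
    xi = np.zeros(d)
    for m, c, s2 in zip(moments, panel.clusters, S2):
        X, W = c.X, c.W
        J = np.ones(c.n)
        G[:p, :p] += m.u2 * X.T @ X
        blk = np.kron(m.u2b[None, :], X.T @ W)        # p x q^2, vec col-major
        G[:p, p:] += blk
        G[p:, :p] += blk.T
        G[p:, p:] += np.kron(m.u2b2, W.T @ W)
        ups[:p] += X.T @ m.u2z
        ups[p:] += (W.T @ m.u2bz.T).ravel(order="F")
        xi[:p] += s2 * (X.T @ J)
        vub_bar = m.vub - _C * u1 * m.u2b
        xi[p:] += np.kron(vub_bar, W.T @ J)

    # free coordinates of vec(alpha) under the restriction
    fixed = []
    if theta.fix_delta0 and not theta.fix_delta_all:
        fixed = [p + l * q + 0 for l in range(1, q)]  # alpha[0, l>=1] = 0
    free = np.array([i for i in range(d) if i not in fixed])
    Gf = G[np.ix_(free, free)]
    try:
        Gf_inv_ups = np.linalg.solve(Gf, ups[free])
        Gf_inv_xi = np.linalg.solve(Gf, xi[free])
    except np.linalg.LinAlgError:
        th = mstep(moments, panel, theta)
        return th, np.eye(q)

    if theta.fix_delta_eps:
        deps = 0.0
    else:
        num = float(xi[free] @ Gf_inv_ups) - sum(
            float(J @ (m.vuz - _C * u1 * m.u2z))
            for J, m in zip(Js, moments))
        den = float(xi[free] @ Gf_inv_xi) - float(
            sum(c.n * s3 for c, s3 in zip(panel.clusters, S3)))
        deps = num / den

    sol = np.zeros(d)
    sol[free] = Gf_inv_ups - deps * Gf_inv_xi
    beta = sol[:p]
    alpha = sol[p:].reshape(q, q, order="F")

    S3sum = float(S3.sum())
    delta_star = _delta_update(moments, panel, theta, S3sum)
    d_bar_star = _dbar_update(moments, theta, delta_star, S3sum, panel.n_clusters)
    delta = alpha @ delta_star
    if theta.fix_delta0 and not theta.fix_delta_all:
        delta[0] = 0.0
    d_bar = nearest_pd(alpha @ d_bar_star @ alpha.T)
    th = replace(theta, beta=beta, delta_eps=deps, delta=delta, d_bar=d_bar)
    return th, alpha


def _init_theta(panel: Panel, nu: float, fix_delta_eps: bool, fix_delta0: bool,
                fix_delta_all: bool) -> Theta:
    return Theta(beta=np.zeros(panel.p), delta_eps=0.0,
                 delta=np.zeros(panel.q), d_bar=np.eye(panel.q), nu=nu,
                 upsilon0=1.0, fix_delta_eps=fix_delta_eps,
                 fix_delta0=fix_delta0, fix_delta_all=fix_delta_all)


def fit(panel: Panel, nu: float, fix_delta_eps: bool = False,
        fix_delta0: bool = False, fix_delta_all: bool = False,
        control: FitControl | None = None, theta0: Theta | None = None,
        use_px: bool = True, skew_starts=None) -> FitResult:
    """Fit the SGTLM at fixed degrees of freedom nu (inf = probit limit).

    Runs PX-EM until the working scale stabilizes at the identity, then plain
    EM until the relative log-likelihood change falls below ``loglik_rtol``,
    then applies the terminal upsilon0 rescaling.

    ``skew_starts``: optional deterministic multi-start over link-skewness
    initializations (e.g. ``(0.0, -2.0, 2.0)``).  The skewness channel of
    this model can carry two separated likelihood modes — a strongly skewed
    one and a near-symmetric one with inflated scale parameters — and plain
    EM from the zero start cannot cross the valley between them; the best
    final log-likelihood among the starts is returned.
    """
    ctrl = control or FitControl()
    if skew_starts is not None and theta0 is None and not fix_delta_eps:
        best = None
        for s in skew_starts:
            th0 = _init_theta(panel, nu, fix_delta_eps, fix_delta0,
                              fix_delta_all)
            th0 = replace(th0, delta_eps=float(s))
            res = fit(panel, nu, fix_delta_eps, fix_delta0, fix_delta_all,
                      ctrl, theta0=th0, use_px=use_px)
            if best is None or res.loglik > best.loglik:
                best = res
        return best
    theta = theta0 if theta0 is not None else _init_theta(
        panel, nu, fix_delta_eps, fix_delta0, fix_delta_all)
    if theta.upsilon0 != 1.0:
        theta = replace(theta, upsilon0=1.0)
    trace = []
    floored = 0
    px_phase = use_px
    n_px = 0
    converged = False
    ll_prev = None
    px_stall = 0
    it = 0
    while it < ctrl.max_iter:
        it += 1
        moments = estep(theta, panel, ctrl.moment_options)
        if px_phase:
            theta, alpha = px_mstep(moments, panel, theta)
            n_px += 1
            lam_max = np.max(np.abs(np.linalg.eigvals(alpha - np.eye(theta.q))))
            if lam_max < ctrl.px_switch_tol:
                px_phase = False
        else:
            theta = mstep(moments, panel, theta)
        ll, nf = marginal_loglik(theta, panel, ctrl.loglik_options, ctrl.ni_cap)
        floored += nf
        trace.append(ll)
        if ctrl.verbose:
            print(f"[sgtlm] iter {it:4d} loglik {ll:.6f}"
                  f"{' (px)' if px_phase or (n_px == it) else ''}")
        small = (ll_prev is not None
                 and abs(ll - ll_prev) / max(abs(ll_prev), 1.0) < ctrl.loglik_rtol)
        if px_phase:
            # safeguard: on variance-component boundaries alpha need not
            # approach I although the observed-data model has stabilized;
            # a stalled likelihood forces the switch to plain EM
            px_stall = px_stall + 1 if small else 0
            if px_stall >= 3:
                px_phase = False
        elif small:
            converged = True
            break
        ll_prev = ll

    theta_final = theta.finalize_scale()
    return FitResult(theta=theta_final, theta_em=theta, loglik=trace[-1],
                     loglik_trace=np.asarray(trace), n_iter=it, n_px_iter=n_px,
                     converged=converged, n_floored=floored)


def select_nu(panel: Panel, nu_grid=None, control: FitControl | None = None,
              **restrictions) -> tuple[float, FitResult]:
    """Profile the fit over a grid of degrees of freedom.

    Each grid point is warm-started from the previous solution; the pair
    (nu, theta(nu)) maximizing the marginal log-likelihood is returned, with
    the profile curve attached and a flag when the maximum sits at the lower
    grid edge (the unbounded-profile symptom of pure t links).
    """
    ctrl = control or FitControl()
    grid = np.atleast_1d(np.asarray(
        nu_grid if nu_grid is not None else
        (ctrl.nu_grid if ctrl.nu_grid is not None else FitControl.default_nu_grid()),
        dtype=float))
    if grid.size == 0:
        raise ValueError("empty nu grid")
    best = None
    best_nu = None
    profile = []
    warm = None
    any_converged = False
    for nu in grid:
        theta0 = replace(warm, nu=float(nu)) if warm is not None else None
        res = fit(panel, float(nu), control=ctrl, theta0=theta0, **restrictions)
        any_converged = any_converged or res.converged
        profile.append((float(nu), res.loglik))
        warm = res.theta_em
        if best is None or res.loglik > best.loglik:
            best, best_nu = res, float(nu)
    if not any_converged:
        raise RuntimeError("no grid point produced a converged fit")
    best.nu_profile = profile
    best.nu_at_edge = bool(best_nu == grid.min() and grid.size > 1)
    return best_nu, best
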