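"""Moments of truncated multivariate skew-t / skew-generalized-t laws.

Binary outcomes observe only the orthant in which a latent SGT vector fell,
so EM inference needs the first two moments of SGT vectors truncated to
products of half-lines, together with joint moments against the gamma
scale-mixing variable U and the hidden half-normal skewness variable V.

Everything reduces to a single standardized kernel: moments of
``TST_p(0, R, lambda, nu, a)`` — a right-truncated skew t with correlation
matrix R — which are assembled from low-dimensional Student-t cdfs of the
*augmented* (p+1)-variate symmetric t vector (the extra coordinate carries
the skewness through the working shape delta).  The Gaussian limit
(``nu = inf``) runs through the same assembly with normal kernels, which is
how probit / skew-probit models are fitted.

Joint moments E{U^{r/2} g(Z)} and E{U^{r/2} zeta1(U^{1/2} alpha) g(Z)} are
tilted truncated-ST / truncated-t moments at shifted degrees of freedom
nu + r; second moments therefore exist whenever nu + r > 4 (r = 2 in the
E-step, hence the fit-able domain nu > 2).

All cdf evaluations can be pooled across many problems (a ``CdfPlan``) and
solved in one vectorized batch; the public functions are thin wrappers that
build a plan, solve it, and assemble the results.  Internal job classes work
directly on the working shape delta (the EM's natural parameter); the
lambda parameterization appears only at the public API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from ._linalg import sqrtm_sym
from .mvt import CdfPlan, MvtOptions
from .sgt_core import (HALF_NORMAL_MEAN, MixingSpec, SgtParams,
                       lambda_to_delta)

__all__ = [
    "TruncRegion", "JointMomentBundle", "DegenerateRegionError",
    "tst_moments_std", "tsgt_moments", "tsn_moments", "joint_em_moments",
]

_C = HALF_NORMAL_MEAN

#: normalizing probabilities below this raise DegenerateRegionError
DEGENERATE_ALPHA = 1e-12


class DegenerateRegionError(RuntimeError):
    """Truncation region has (numerically) vanishing probability."""


@dataclass(frozen=True)
class TruncRegion:
    """Product of half-lines A_1 x ... x A_p.

    ``orient[k] = +1`` encodes A_k = (-inf, a_k] and ``-1`` encodes
    A_k = (a_k, inf); ``diag(orient)`` is the sign-flip matrix that maps any
    such region to a right-truncated one.
    """

    a: np.ndarray
    orient: np.ndarray

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        o = np.atleast_1d(np.asarray(self.orient, dtype=float))
        if a.shape != o.shape:
            raise ValueError("a and orient must have equal length")
        if not np.all(np.abs(o) == 1.0):
            raise ValueError("orientation signs must be +-1")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "orient", o)

    @property
    def dim(self) -> int:
        return self.a.shape[0]

    @staticmethod
    def right(a) -> "TruncRegion":
        a = np.atleast_1d(np.asarray(a, dtype=float))
        return TruncRegion(a, np.ones_like(a))

    @staticmethod
    def from_binary(y) -> "TruncRegion":
        """Region of the latent vector given binary outcomes: y=0 -> Z<=0, y=1 -> Z>0."""
        y = np.atleast_1d(np.asarray(y))
        return TruncRegion(np.zeros(y.shape[0]), np.where(y == 0, 1.0, -1.0))


@dataclass
class JointMomentBundle:
    """E{U^{r/2} Z^(s)} and E{U^{r/2} zeta1(U^{1/2} alpha) Z^(s)} moments."""

    r: float
    ur: float
    urz1: np.ndarray | None = None
    urz2: np.ndarray | None = None
    taur: float | None = None
    taurz1: np.ndarray | None = None
    taurz2: np.ndarray | None = None
    alpha_st: float = np.nan


# ---------------------------------------------------------------------------
# kernel helpers: Student pdfs with Gaussian limits
# ---------------------------------------------------------------------------

def _t_pdf1(x: float, df: float) -> float:
    if np.isinf(df):
        return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)
    lg = special.gammaln((df + 1) / 2) - special.gammaln(df / 2)
    return math.exp(lg) / math.sqrt(df * math.pi) * (1 + x * x / df) ** (-(df + 1) / 2)


def _t_pdf2(x: np.ndarray, sigma: np.ndarray, df: float) -> float:
    det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
    if det <= 0:
        return 0.0
    q = (x[0] ** 2 * sigma[1, 1] - 2 * x[0] * x[1] * sigma[0, 1]
         + x[1] ** 2 * sigma[0, 0]) / det
    if np.isinf(df):
        return math.exp(-0.5 * q) / (2 * math.pi * math.sqrt(det))
    lg = special.gammaln((df + 2) / 2) - special.gammaln(df / 2)
    return math.exp(lg) / (df * math.pi * math.sqrt(det)) * (1 + q / df) ** (-(df + 2) / 2)


def _delta_of(lam: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Working shape delta = (1 + lam'lam)^{-1/2} omega^{1/2} lam."""
    s0 = math.sqrt(1.0 + float(lam @ lam))
    return sqrtm_sym(omega) @ lam / s0


# ---------------------------------------------------------------------------
# Standardized kernel: right-truncated ST_p(0, R, shape, nu) moments
# ---------------------------------------------------------------------------

class _Prop2Job:
    """Request/assemble pair for the standardized truncated-ST moments.

    The assembly is written on the augmented (p+1)-variate central t vector
    T = (T0, T') with correlation [[1, -d'], [-d, R]] and limits (0, a): the
    normalizer and every partial-integral term are cdfs of T or of its
    conditional distributions.  All terms are used in ratios, so the skew
    factor 2 cancels and never appears here.
    """

    def __init__(self, plan: CdfPlan, R: np.ndarray, nu: float, a: np.ndarray,
                 order: int, delta: np.ndarray):
        p = R.shape[0]
        self.p, self.order, self.nu = p, order, float(nu)
        finite = np.isfinite(nu)
        if order >= 1 and finite and nu <= 2:
            raise ValueError("first truncated moments require nu > 2")
        if order >= 2 and finite and nu <= 4:
            raise ValueError("second truncated moments require nu > 4")
        d = np.asarray(delta, dtype=float)
        a = np.asarray(a, dtype=float)
        self.R, self.d, self.a = R, d, a
        rbar = np.empty((p + 1, p + 1))
        rbar[0, 0] = 1.0
        rbar[0, 1:] = -d
        rbar[1:, 0] = -d
        rbar[1:, 1:] = R
        abar = np.concatenate(([0.0], a))
        self._rbar, self._abar = rbar, abar

        # normalizer (half convention: true region probability is 2x this)
        self.i_ast = plan.add(abar, rbar, nu)

        if finite:
            lg = special.gammaln((nu - 1) / 2) - special.gammaln((nu - 2) / 2)
            self.k0 = math.exp(lg) / math.sqrt(nu * math.pi)
            sc0, df0 = nu / (nu - 1), nu - 1
        else:
            self.k0 = 1.0 / math.sqrt(2 * math.pi)
            sc0, df0 = 1.0, np.inf
        self.i_c0 = plan.add(a, sc0 * (R - np.outer(d, d)), df0)

        # first-moment partial integrals q_i (skip margins with a_i = +inf)
        self.qf = np.zeros(p)
        self.i_q = np.full(p, -1, dtype=int)
        for i in range(p):
            if not np.isfinite(a[i]):
                continue
            if finite:
                z = math.sqrt((nu - 2) / nu) * a[i]
                self.qf[i] = math.sqrt((nu - 2) / nu) * _t_pdf1(z, nu - 2)
                dfq, scq = nu - 1, (nu + a[i] ** 2) / (nu - 1)
            else:
                self.qf[i] = _t_pdf1(a[i], np.inf)
                dfq, scq = np.inf, 1.0
            keep = [k for k in range(p + 1) if k != i + 1]
            r12 = rbar[keep, i + 1]
            mu_c = r12 * a[i]
            cov_c = rbar[np.ix_(keep, keep)] - np.outer(r12, r12)
            self.i_q[i] = plan.add(abar[keep] - mu_c, scq * cov_c, dfq)

        if order < 2:
            return

        # alpha_st* for the leading second-moment term
        sc2, df2 = ((nu / (nu - 2), nu - 2) if finite else (1.0, np.inf))
        self.i_ast2 = plan.add(abar, sc2 * rbar, df2)

        # H0 (pairs with the augmented skew coordinate) and H (plain pairs)
        self.h0f = np.zeros(p)
        self.i_h0 = np.full(p, -1, dtype=int)
        self.hf = np.zeros((p, p))
        self.i_h = np.full((p, p), -1, dtype=int)
        schh, dfh = ((nu / (nu - 4), nu - 4) if finite else (1.0, np.inf))
        for i in range(p):
            if not np.isfinite(a[i]):
                continue
            r11 = np.array([[1.0, -d[i]], [-d[i], 1.0]])
            x = np.array([0.0, a[i]])
            self.h0f[i] = schh * _t_pdf2(x, schh * r11, dfh)
            if self.h0f[i] > 0 and p > 1:
                alpha0 = a[i] ** 2 / max(1.0 - d[i] ** 2, 1e-12)
                keep = [k for k in range(p + 1) if k not in (0, i + 1)]
                r12 = rbar[np.ix_([0, i + 1], keep)]
                sol = np.linalg.solve(r11, r12)
                mu_c = sol.T @ x
                cov_c = rbar[np.ix_(keep, keep)] - r12.T @ sol
                scc = (nu + alpha0) / (nu - 2) if finite else 1.0
                dfc = nu - 2 if finite else np.inf
                lim = np.delete(a, i) - mu_c
                self.i_h0[i] = plan.add(lim, scc * cov_c, dfc)
        for i in range(p):
            for jj in range(i + 1, p):
                if not (np.isfinite(a[i]) and np.isfinite(a[jj])):
                    continue
                rho = R[i, jj]
                r11 = np.array([[1.0, rho], [rho, 1.0]])
                x = np.array([a[i], a[jj]])
                f = schh * _t_pdf2(x, schh * r11, dfh)
                self.hf[i, jj] = self.hf[jj, i] = f
                if f <= 0:
                    continue
                alph = (a[i] ** 2 - 2 * rho * a[i] * a[jj] + a[jj] ** 2) / max(1 - rho ** 2, 1e-12)
                keep = [k for k in range(p + 1) if k not in (i + 1, jj + 1)]
                r12 = rbar[np.ix_([i + 1, jj + 1], keep)]
                sol = np.linalg.solve(r11, r12)
                mu_c = sol.T @ x
                cov_c = rbar[np.ix_(keep, keep)] - r12.T @ sol
                scc = (nu + alph) / (nu - 2) if finite else 1.0
                dfc = nu - 2 if finite else np.inf
                lim = abar[keep] - mu_c
                self.i_h[i, jj] = self.i_h[jj, i] = plan.add(lim, scc * cov_c, dfc)

    # -- assembly ---------------------------------------------------------
    def finish(self, values: np.ndarray):
        p, nu = self.p, self.nu
        finite = np.isfinite(nu)
        ast = values[self.i_ast]
        if ast < DEGENERATE_ALPHA:
            raise DegenerateRegionError(
                f"truncation region has probability ~{2 * ast:.2e}")
        r1 = nu / (nu - 2) if finite else 1.0
        c0 = self.k0 * values[self.i_c0]
        q = np.array([self.qf[i] * values[self.i_q[i]] if self.i_q[i] >= 0 else 0.0
                      for i in range(p)])
        m1 = r1 / ast * (c0 * self.d - self.R @ q)
        if self.order < 2:
            return m1, None
        ast2 = values[self.i_ast2]
        h0 = np.array([self.h0f[i] * (values[self.i_h0[i]] if self.i_h0[i] >= 0 else 1.0)
                       for i in range(p)])
        H = np.zeros((p, p))
        for i in range(p):
            for jj in range(i + 1, p):
                if self.i_h[i, jj] >= 0:
                    H[i, jj] = H[jj, i] = self.hf[i, jj] * values[self.i_h[i, jj]]
        d0 = float(self.d @ h0)
        aq = np.where(np.isfinite(self.a), self.a, 0.0) * q
        Dd = np.diag(self.d * h0 - aq - np.einsum("ij,ji->i", self.R, H))
        m2 = r1 / ast * (ast2 * self.R + self.R @ (H + Dd) @ self.R
                         - np.outer(self.R @ h0, self.d) - np.outer(self.d, self.R @ h0)
                         + d0 * np.outer(self.d, self.d))
        m2 = 0.5 * (m2 + m2.T)
        return m1, m2


def tst_moments_std(R, lam, nu, a, order: int = 2,
                    options: MvtOptions | None = None):
    """First (and second) moments of TST_p(0, R, lambda, nu) right-truncated at a.

    R must be a correlation matrix.  The mean requires nu > 2 and the second
    moment nu > 4 (nu = inf gives the truncated skew-normal).
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    plan = CdfPlan()
    job = _Prop2Job(plan, R, nu, np.atleast_1d(np.asarray(a, float)), order,
                    delta=_delta_of(lam, R))
    return job.finish(plan.solve(options))


# ---------------------------------------------------------------------------
# General (mu, Omega, delta, nu) truncated moments
# ---------------------------------------------------------------------------

class _TsgtJob:
    """Reduce a general truncated skew-t to the standardized kernel.

    Inputs are already on the ST scale (any nu0/nu rescaling folded into
    ``omega``) with the working shape ``delta``.  Orientation flips, then
    standardization (delta transforms linearly under diagonal scaling), then
    the standardized kernel; ``finish`` maps the moments back.
    """

    def __init__(self, plan: CdfPlan, mu, omega, delta, nu, region: TruncRegion,
                 order: int = 2):
        A = region.orient
        mu_f = A * mu
        omega_f = omega * np.outer(A, A)
        delta_f = A * delta
        sd = np.sqrt(np.diag(omega_f))
        Rc = omega_f / np.outer(sd, sd)
        d_std = delta_f / sd
        a_std = (A * region.a - mu_f) / sd
        self.A, self.mu_f, self.sd = A, mu_f, sd
        self.job = _Prop2Job(plan, Rc, nu, a_std, order, delta=d_std)

    def finish(self, values: np.ndarray):
        m1s, m2s = self.job.finish(values)
        A, mu_f, sd = self.A, self.mu_f, self.sd
        m1 = A * (mu_f + sd * m1s)
        if m2s is None:
            return m1, None
        exx = (np.outer(mu_f, mu_f) + np.outer(mu_f, sd * m1s)
               + np.outer(sd * m1s, mu_f) + np.outer(sd, sd) * m2s)
        m2 = np.outer(A, A) * exx
        return m1, 0.5 * (m2 + m2.T)


def tsgt_moments(params: SgtParams, region: TruncRegion, order: int = 2,
                 options: MvtOptions | None = None):
    """Moments of a general truncated SGT vector (any half-line orientations)."""
    if region.dim != params.dim:
        raise ValueError("region / parameter dimension mismatch")
    omega_st = params.mixing.scale_ratio * params.omega
    delta = lambda_to_delta(params.lam, omega_st).delta
    nu = np.inf if params.mixing.is_normal_limit else params.mixing.nu
    plan = CdfPlan()
    job = _TsgtJob(plan, params.mu, omega_st, delta, nu, region, order)
    return job.finish(plan.solve(options))


def tsn_moments(mu, omega, lam, region: TruncRegion, order: int = 2,
                options: MvtOptions | None = None):
    """Truncated multivariate skew-normal moments (the nu -> inf limit)."""
    params = SgtParams(mu, omega, lam, MixingSpec.normal_limit())
    return tsgt_moments(params, region, order, options)


# ---------------------------------------------------------------------------
# Joint moments with the mixing variable U and skewness variable V
# ---------------------------------------------------------------------------

class _JointJob:
    """E{U^{r/2} Z^(s)} and E{U^{r/2} zeta1(U^{1/2} alpha) Z^(s)} over a
    truncated SGT law, via degree-shifted truncated-ST / truncated-t moments.

    ``mu, omega, delta`` describe the ST-scale law (nu0/nu folded in); pass
    ``delta`` straight from the model layer to avoid matrix-root round trips.
    """

    def __init__(self, plan: CdfPlan, mu, omega, delta, nu, region: TruncRegion,
                 r: float, order: int = 1, tau_order: int = 1,
                 need_tau: bool = True, need_u: bool = True):
        finite = np.isfinite(nu)
        if finite and r <= -nu:
            raise ValueError("joint moment order r must exceed -nu")
        self.r, self.order, self.tau_order = r, order, tau_order
        self.need_tau, self.need_u = need_tau, need_u

        obar = omega - np.outer(delta, delta)
        self.M = (1.0 + float(delta @ np.linalg.solve(obar, delta))) ** -0.5
        if finite:
            # C_r uses the gamma mixing at (nu/2, nu/2) on the ST scale
            self.Cr = ((2.0 / nu) ** (r / 2.0)
                       * math.exp(special.gammaln((nu + r) / 2)
                                  - special.gammaln(nu / 2)))
            shrink = nu / (nu + r)
            df_r = nu + r
        else:
            self.Cr, shrink, df_r = 1.0, 1.0, np.inf
        A = region.orient
        a_f = A * region.a
        mu_f = A * mu
        omega_f = omega * np.outer(A, A)
        obar_f = obar * np.outer(A, A)
        delta_f = A * delta
        self.A = A

        # true normalizer: ST cdf of the flipped law (augmented, with its 2)
        self.i_ast = _submit_st_cdf(plan, a_f, mu_f, omega_f, delta_f, nu)
        if need_u:
            self.i_au = _submit_st_cdf(plan, a_f, mu_f, shrink * omega_f,
                                       math.sqrt(shrink) * delta_f, df_r)
            if order >= 1:
                self.ujob = _TsgtJob(plan, mu, shrink * omega,
                                     math.sqrt(shrink) * delta, df_r, region,
                                     order)
        if need_tau:
            self.i_atau = plan.add(a_f - mu_f, shrink * obar_f, df_r)
            if tau_order >= 1:
                self.tjob = _TsgtJob(plan, mu, shrink * obar, np.zeros(len(a_f)),
                                     df_r, region, tau_order)

    def finish(self, values: np.ndarray) -> JointMomentBundle:
        ast = 2.0 * values[self.i_ast]
        if ast < DEGENERATE_ALPHA:
            raise DegenerateRegionError(
                f"truncation region has probability ~{ast:.2e}")
        ur = np.nan
        if self.need_u:
            au = 2.0 * values[self.i_au]
            ur = self.Cr * au / ast
        out = JointMomentBundle(r=self.r, ur=ur, alpha_st=ast)
        if self.need_u and self.order >= 1:
            m1, m2 = self.ujob.finish(values)
            out.urz1 = ur * m1
            if m2 is not None:
                out.urz2 = ur * m2
        if self.need_tau:
            atau = values[self.i_atau]
            out.taur = _C * self.M * self.Cr * atau / ast
            if self.tau_order >= 1:
                m1t, m2t = self.tjob.finish(values)
                out.taurz1 = out.taur * m1t
                if m2t is not None:
                    out.taurz2 = out.taur * m2t
        return out


def _submit_st_cdf(plan: CdfPlan, a, mu, omega, delta, nu) -> int:
    """Submit the augmented-T representation of an ST cdf (half value)."""
    p = len(a)
    aug = np.empty((p + 1, p + 1))
    aug[0, 0] = 1.0
    aug[0, 1:] = -delta
    aug[1:, 0] = -delta
    aug[1:, 1:] = omega
    upper = np.concatenate(([0.0], np.asarray(a, float) - np.asarray(mu, float)))
    return plan.add(upper, aug, nu)


def joint_em_moments(params: SgtParams, region: TruncRegion, r: float,
                     order: int = 1, tau_order: int = 1, need_tau: bool = True,
                     need_u: bool = True,
                     options: MvtOptions | None = None) -> JointMomentBundle:
    """Joint truncated moments of (U, Z) (and the zeta1-tilted tau-chain).

    ``order`` / ``tau_order`` select how many Z-moments (0, 1 or 2) are
    assembled for the U-chain and the tau-chain respectively.
    """
    if region.dim != params.dim:
        raise ValueError("region / parameter dimension mismatch")
    mix = params.mixing
    omega_st = mix.scale_ratio * params.omega
    delta = lambda_to_delta(params.lam, omega_st).delta
    nu = np.inf if mix.is_normal_limit else mix.nu
    plan = CdfPlan()
    job = _JointJob(plan, params.mu, omega_st, delta, nu, region, r,
                    order, tau_order, need_tau, need_u)
    out = job.finish(plan.solve(options))
    # moments refer to the original mixing U ~ Gamma(nu/2, nu0/2); the job
    # works on the rescaled ST law whose mixing is Gamma(nu/2, nu/2)
    fac = 1.0 if mix.is_normal_limit else (mix.nu / mix.nu0) ** (r / 2.0)
    if fac != 1.0:
        for name in ("ur", "taur"):
            val = getattr(out, name)
            if val is not None:
                setattr(out, name, val * fac)
        for name in ("urz1", "urz2", "taurz1", "taurz2"):
            val = getattr(out, name)
            if val is not None:
                setattr(out, name, val * fac)
    return out
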