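"""Skew generalized t (SGT) and skew t (ST) distribution primitives.

The SGT family arises as a skew scale mixture of normals: a p-variate vector
with the constructive representation

    Z = mu + U^{-1/2} (delta * Z0 + X),   Z0 ~ half-normal(0,1),
    X ~ N_p(0, Omega_bar),   U ~ Gamma(nu/2, nu0/2),

all independent, with Omega = Omega_bar + delta delta' and the shape vector
lambda related to the *working shape* delta by

    lambda = (1 + delta' Obar^{-1} delta)^{1/2} Omega^{-1/2} delta,
    delta  = (1 + lambda' lambda)^{-1/2} Omega^{1/2} lambda.

The skew t (ST) case is nu0 == nu; lambda = 0 gives the generalized t (GT);
nu -> inf gives the skew normal / normal limits.  The scaling identity
SGT_p(mu, Omega, lambda, (nu, nu0)) == ST_p(mu, (nu0/nu) Omega, lambda, nu)
lets every SGT computation be routed through an ST one.

All matrix square roots are *symmetric* (eigendecomposition), never Cholesky,
so the lambda <-> delta maps are exact bijections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy import stats as sps

from ._linalg import check_pd, inv_sqrtm_sym, sqrtm_sym
from .mvt import MvtOptions, mvt_cdf

__all__ = [
    "HALF_NORMAL_MEAN", "MixingSpec", "SgtParams", "WorkingShapeParams",
    "mixing_moment", "delta_to_lambda", "lambda_to_delta", "ssmn_moments",
    "shape_indices", "sgt_pdf", "st_cdf", "sgt_rvs",
]

#: mean of a standard half-normal variable, c = sqrt(2/pi)
HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)
_C = HALF_NORMAL_MEAN


@dataclass(frozen=True)
class MixingSpec:
    """Degrees-of-freedom pair (nu, nu0) of the gamma scale-mixing variable.

    ``U ~ Gamma(nu/2, nu0/2)`` (rate parameterization).  ``nu0 == nu`` is the
    skew-t branch; ``nu = nu0 = inf`` is the (skew) normal limit where U is
    degenerate at 1.
    """

    nu: float
    nu0: float

    def __post_init__(self):
        if not (self.nu > 0 and self.nu0 > 0):
            raise ValueError("mixing degrees of freedom must be positive")
        if np.isinf(self.nu) != np.isinf(self.nu0):
            raise ValueError("nu and nu0 must be both finite or both infinite")

    @property
    def is_skew_t(self) -> bool:
        return np.isinf(self.nu) or self.nu0 == self.nu

    @property
    def is_normal_limit(self) -> bool:
        return np.isinf(self.nu)

    @property
    def scale_ratio(self) -> float:
        """nu0 / nu, the rescaling factor of the ST representation."""
        return 1.0 if self.is_normal_limit else self.nu0 / self.nu

    @staticmethod
    def skew_t(nu: float) -> "MixingSpec":
        return MixingSpec(nu, nu)

    @staticmethod
    def normal_limit() -> "MixingSpec":
        return MixingSpec(np.inf, np.inf)


def mixing_moment(t: float, mixing: MixingSpec) -> float:
    """E{U^{-t/2}} = (nu0/2)^{t/2} Gamma((nu-t)/2) / Gamma(nu/2), for t < nu.

    These inverse moments drive every moment formula of the family; they are
    finite only when t < nu, and tend to 1 as nu = nu0 -> inf.
    """
    if mixing.is_normal_limit:
        return 1.0
    if t >= mixing.nu:
        raise ValueError(
            f"mixing moment of order t={t} does not exist for nu={mixing.nu}")
    lg = special.gammaln((mixing.nu - t) / 2.0) - special.gammaln(mixing.nu / 2.0)
    return float((mixing.nu0 / 2.0) ** (t / 2.0) * math.exp(lg))


@dataclass(frozen=True)
class WorkingShapeParams:
    """Unconstrained (delta, Omega_bar) parameterization of the shape."""

    delta: np.ndarray
    omega_bar: np.ndarray

    def __post_init__(self):
        d = np.atleast_1d(np.asarray(self.delta, dtype=float))
        ob = check_pd(self.omega_bar, "omega_bar")
        if d.shape[0] != ob.shape[0]:
            raise ValueError("delta / omega_bar dimension mismatch")
        if not np.all(np.isfinite(d)):
            raise ValueError("delta must be finite")
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "omega_bar", ob)


@dataclass(frozen=True)
class SgtParams:
    """(mu, Omega, lambda, mixing) of one SGT/ST distribution."""

    mu: np.ndarray
    omega: np.ndarray
    lam: np.ndarray
    mixing: MixingSpec = field(default_factory=lambda: MixingSpec.skew_t(5.0))

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        om = check_pd(self.omega, "omega")
        if not (mu.shape[0] == lam.shape[0] == om.shape[0]):
            raise ValueError("mu / omega / lambda dimension mismatch")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "lam", lam)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]

    def working_delta(self) -> np.ndarray:
        """delta = (1 + lam'lam)^{-1/2} Omega^{1/2} lam."""
        s0 = math.sqrt(1.0 + float(self.lam @ self.lam))
        return sqrtm_sym(self.omega) @ self.lam / s0


def delta_to_lambda(ws: WorkingShapeParams) -> tuple[np.ndarray, np.ndarray]:
    """(delta, Omega_bar) -> (lambda, Omega) with Omega = Obar + delta delta'."""
    d = ws.delta
    omega = ws.omega_bar + np.outer(d, d)
    t = float(d @ np.linalg.solve(ws.omega_bar, d))
    lam = math.sqrt(1.0 + t) * (inv_sqrtm_sym(omega) @ d)
    return lam, omega


def lambda_to_delta(lam, omega) -> WorkingShapeParams:
    """(lambda, Omega) -> (delta, Omega_bar); requires delta' Omega^{-1} delta < 1."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    omega = check_pd(omega, "omega")
    s0 = math.sqrt(1.0 + float(lam @ lam))
    d = sqrtm_sym(omega) @ lam / s0
    omega_bar = omega - np.outer(d, d)
    w = np.linalg.eigvalsh(omega_bar)
    if w[0] <= 1e-12 * max(w[-1], 1e-300):
        raise ValueError("Omega - delta delta' is not positive definite")
    return WorkingShapeParams(delta=d, omega_bar=omega_bar)


def ssmn_moments(mu, ws: WorkingShapeParams, mixing: MixingSpec):
    """Mean and covariance of the untruncated SGT vector.

    mean = mu + c*U1*delta,  cov = U2*Omega - c^2*U1^2*delta delta',
    with U_t the inverse mixing moments; the covariance needs nu > 2.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if not mixing.is_normal_limit and mixing.nu <= 2:
        raise ValueError("covariance requires nu > 2")
    u1 = mixing_moment(1, mixing)
    u2 = mixing_moment(2, mixing)
    d = ws.delta
    omega = ws.omega_bar + np.outer(d, d)
    mean = mu + _C * u1 * d
    cov = u2 * omega - (_C * u1) ** 2 * np.outer(d, d)
    return mean, cov


def shape_indices(delta_k: float, sigma_k: float, mixing: MixingSpec):
    """Marginal skewness and excess kurtosis of one SGT coordinate.

    gamma1 = c*dk/s^3 [3(U3 - U1 U2) - dk^2 (U3 - 4 U1^3/pi)]
    gamma2 = 1/s^4 [3(U4 - U2^2) - 4 c^2 dk^2 U1 (3(U3 - U1 U2)
                                                  - dk^2 (U3 - 3 U1^3/pi))]
    where s^2 is the marginal variance.  The expressions assume a unit
    marginal scale (omega_kk = 1) with delta_k the working shape on that
    scale; requires nu > 4.
    """
    if not mixing.is_normal_limit and mixing.nu <= 4:
        raise ValueError("shape indices require nu > 4")
    u1, u2, u3, u4 = (mixing_moment(t, mixing) for t in (1, 2, 3, 4))
    dk, s = float(delta_k), float(sigma_k)
    g1 = _C * dk / s ** 3 * (3.0 * (u3 - u1 * u2) - dk ** 2 * (u3 - 4.0 * u1 ** 3 / math.pi))
    g2 = (3.0 * (u4 - u2 ** 2)
          - 4.0 * _C ** 2 * dk ** 2 * u1 * (3.0 * (u3 - u1 * u2)
                                            - dk ** 2 * (u3 - 3.0 * u1 ** 3 / math.pi))) / s ** 4
    return g1, g2


def _gt_logpdf(z0sq: np.ndarray, p: int, nu: float, nu0: float, logdet: float):
    lg = (special.gammaln((p + nu) / 2.0) - special.gammaln(nu / 2.0)
          + 0.5 * nu * math.log(nu0) - 0.5 * p * math.log(math.pi) - 0.5 * logdet)
    return lg - 0.5 * (p + nu) * np.log(nu0 + z0sq)


def sgt_pdf(z, params: SgtParams):
    """Density of the p-variate SGT distribution (vectorized over rows of z)."""
    z = np.asarray(z, dtype=float)
    one = z.ndim == 1
    zz = np.atleast_2d(z)
    p = params.dim
    if zz.shape[1] != p:
        raise ValueError(f"z has dimension {zz.shape[1]}, expected {p}")
    mix = params.mixing
    om_isqrt = inv_sqrtm_sym(params.omega)
    z0 = (zz - params.mu) @ om_isqrt
    z0sq = np.einsum("ij,ij->i", z0, z0)
    alpha = z0 @ params.lam
    sign, logdet = np.linalg.slogdet(params.omega)
    if mix.is_normal_limit:
        logsym = (-0.5 * p * math.log(2 * math.pi) - 0.5 * logdet - 0.5 * z0sq)
        skew = special.ndtr(alpha)
    else:
        nu, nu0 = mix.nu, mix.nu0
        logsym = _gt_logpdf(z0sq, p, nu, nu0, logdet)
        arg = alpha * np.sqrt((p + nu) / (nu0 + z0sq))
        skew = sps.t.cdf(arg, p + nu)
    out = 2.0 * np.exp(logsym) * skew
    return float(out[0]) if one else out


def st_cdf(a, params: SgtParams, options: MvtOptions | None = None) -> float:
    """P(Z <= a) componentwise for an ST/SGT vector.

    Uses the augmented representation: for Z ~ ST_p(mu, Omega, lambda, nu),
    P(Z <= a) = 2 T_{p+1}((0, a - mu) | [[1, -d'], [-d, Omega]], nu) with
    d the working shape.  SGT inputs are first rescaled to ST form.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    p = params.dim
    if a.shape[0] != p:
        raise ValueError("cdf point has wrong dimension")
    mix = params.mixing
    omega_st = mix.scale_ratio * params.omega
    d = SgtParams(params.mu, omega_st, params.lam,
                  MixingSpec.skew_t(mix.nu)).working_delta()
    aug = np.empty((p + 1, p + 1))
    aug[0, 0] = 1.0
    aug[0, 1:] = -d
    aug[1:, 0] = -d
    aug[1:, 1:] = omega_st
    upper = np.concatenate(([0.0], a - params.mu))
    df = np.inf if mix.is_normal_limit else mix.nu
    return min(1.0, 2.0 * mvt_cdf(upper, aug, df, options))


def sgt_rvs(params: SgtParams, size: int, seed=None) -> np.ndarray:
    """Draws from the constructive representation (half-normal + normal + gamma)."""
    rng = np.random.default_rng(seed)
    p = params.dim
    mix = params.mixing
    ws = lambda_to_delta(params.lam, params.omega)
    z0 = np.abs(rng.standard_normal(size))
    x = rng.multivariate_normal(np.zeros(p), ws.omega_bar, size=size,
                                method="eigh")
    if mix.is_normal_limit:
        u = np.ones(size)
    else:
        u = rng.gamma(shape=mix.nu / 2.0, scale=2.0 / mix.nu0, size=size)
    return params.mu + (z0[:, None] * ws.delta + x) / np.sqrt(u)[:, None]
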