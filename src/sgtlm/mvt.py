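"""Batched multivariate t and normal orthant/cdf probabilities.

The EM machinery needs thousands of low-dimensional (p <= ~8) multivariate
Student-t cdf evaluations per iteration.  No installed routine is vectorized
over problems, so this module implements the classical separation-of-variables
integrator (sequential conditioning after a Cholesky factorization with
small-limit-first variable reordering, evaluated on scrambled Sobol points)
with full vectorization across both integration points and a *batch* of
independent problems.  ``df = inf`` gives the multivariate normal case; the Student case
adds one scale-mixing variable obtained from the inverse chi-square cdf.

Randomization is deterministic: the Sobol scramblings derive from a fixed
internal seed, so every cdf value is a reproducible, smooth function of its
inputs.  The point budget (``points`` per replicate, ``shifts`` independent
replicates) is the accuracy knob; the spread across replicates provides the
error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps
from scipy.stats import qmc

__all__ = ["MvtOptions", "CdfPlan", "mvt_cdf", "mvt_cdf_batch"]

_TINY = 1e-15


@dataclass
class MvtOptions:
    """Accuracy/reproducibility knobs for the quasi-Monte-Carlo integrator."""

    points: int = 512      # Sobol points per replicate (rounded up to 2^k)
    shifts: int = 6        # independent scramblings (error estimate)
    seed: int = 20212021   # internal; results are deterministic given this
    max_dim: int = 12

    def scaled(self, factor: float) -> "MvtOptions":
        return MvtOptions(points=max(32, int(self.points * factor)),
                          shifts=self.shifts, seed=self.seed, max_dim=self.max_dim)


DEFAULT_OPTIONS = MvtOptions()
# cheaper budget used inside EM iterations (a documented config knob)
EM_OPTIONS = MvtOptions(points=128, shifts=3)


def _standardize(upper: np.ndarray, cov: np.ndarray):
    sd = np.sqrt(np.einsum("bii->bi", cov))
    if np.any(sd <= 0):
        raise ValueError("covariance with non-positive diagonal")
    corr = cov / (sd[:, :, None] * sd[:, None, :])
    with np.errstate(invalid="ignore"):
        b = upper / sd
    b[np.isposinf(upper)] = np.inf
    b[np.isneginf(upper)] = -np.inf
    return b, corr


def _chol_batch(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # tiny ridge for problems that are numerically semi-definite
        d = corr.shape[-1]
        return np.linalg.cholesky(corr + 1e-10 * np.eye(d))


def mvt_cdf_batch(upper, cov, df, options: MvtOptions | None = None):
    """P(X <= upper) for a batch of centered t_d(cov, df) problems.

    Parameters
    ----------
    upper : (B, d) array, entries may be ``+inf`` (inactive margin).
    cov : (B, d, d) array of scale matrices.
    df : scalar or (B,) array; ``inf`` selects the Gaussian kernel.

    Returns
    -------
    values : (B,) array of probabilities.
    errors : (B,) array of Monte-Carlo error estimates (3.5 sigma of the
        shift means).
    """
    opts = options or DEFAULT_OPTIONS
    upper = np.array(upper, dtype=float, copy=True)
    cov = np.asarray(cov, dtype=float)
    if upper.ndim != 2 or cov.ndim != 3:
        raise ValueError("upper must be (B, d) and cov (B, d, d)")
    B, d = upper.shape
    if d > opts.max_dim:
        raise ValueError(f"dimension {d} exceeds the configured cap {opts.max_dim}")
    if B == 0:
        return np.empty(0), np.empty(0)
    df = np.broadcast_to(np.asarray(df, dtype=float), (B,)).copy()
    if np.any(df <= 0):
        raise ValueError("degrees of freedom must be positive")

    if d == 1:
        # exact univariate shortcut
        b1 = upper[:, 0] / np.sqrt(cov[:, 0, 0])
        vals = np.where(np.isinf(df), special.ndtr(b1),
                        sps.t.cdf(np.where(np.isfinite(b1), b1, np.sign(b1) * 1e30),
                                  np.where(np.isinf(df), 1.0, df)))
        vals = np.where(np.isposinf(b1), 1.0, np.where(np.isneginf(b1), 0.0, vals))
        return vals, np.zeros(B)

    b, corr = _standardize(upper, cov)

    # variable reordering: small upper limits first sharpens the sequential
    # conditioning (infinite/padded margins sort last)
    order = np.argsort(np.where(np.isfinite(b), b, np.inf), axis=1, kind="stable")
    b = np.take_along_axis(b, order, axis=1)
    corr = np.take_along_axis(
        np.take_along_axis(corr, order[:, :, None], axis=1),
        order[:, None, :], axis=2)
    L = _chol_batch(corr)

    # points rounded up to a power of two (Sobol balance)
    n = 1 << (max(opts.points, 16) - 1).bit_length()
    finite = np.isfinite(df)
    dff = np.where(finite, df, 2.0)  # placeholder for the inf rows

    acc = np.zeros((opts.shifts, B))
    for k in range(opts.shifts):
        eng = qmc.Sobol(d, scramble=True, seed=opts.seed + 7919 * k)
        w = eng.random(n)  # column 0 drives the chi mixing
        # scale-mixing factor s = sqrt(chi2_df / df); 1 in the Gaussian case.
        # df takes few distinct values in practice, so invert the chi-square
        # cdf once per distinct df rather than once per problem.
        if finite.any():
            q = np.clip(w[:, 0], _TINY, 1 - _TINY)  # (n,)
            s = np.ones((B, n))
            for v in np.unique(dff[finite]):
                rows = finite & (dff == v)
                sv = np.sqrt(special.chdtri(v, 1.0 - q) / v)
                s[rows, :] = sv[None, :]
        else:
            s = np.ones((B, n))
        prod = np.ones((B, n))
        y = np.zeros((B, n, d - 1))
        for m in range(d):
            num = s * b[:, m, None]
            if m > 0:
                num = num - np.einsum("bj,bnj->bn", L[:, m, :m], y[:, :, :m])
            with np.errstate(invalid="ignore"):
                e = special.ndtr(num / L[:, m, m, None])
            e = np.where(np.isposinf(b[:, m, None]) & np.ones_like(num, bool), 1.0, e)
            e = np.where(np.isneginf(b[:, m, None]) & np.ones_like(num, bool), 0.0, e)
            prod *= e
            if m < d - 1:
                u = np.clip(w[None, :, m + 1] * e, _TINY, 1 - _TINY)
                y[:, :, m] = special.ndtri(u)
        acc[k] = prod.mean(axis=1)

    values = acc.mean(axis=0)
    errors = 3.5 * acc.std(axis=0, ddof=1) / np.sqrt(opts.shifts)
    return np.clip(values, 0.0, 1.0), errors


def mvt_cdf(upper, cov, df, options: MvtOptions | None = None) -> float:
    """Single-problem convenience wrapper around :func:`mvt_cdf_batch`."""
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    val, _ = mvt_cdf_batch(upper[None, :], cov[None, :, :], df, options)
    return float(val[0])


class CdfPlan:
    """Pools many cdf requests (possibly of different dimensions) so they can
    be solved in a handful of vectorized batches.

    Usage: ``i = plan.add(upper, cov, df)`` during a request phase, then
    ``values = plan.solve(opts)`` and read ``values[i]``.
    """

    def __init__(self):
        self._upper: list[np.ndarray] = []
        self._cov: list[np.ndarray] = []
        self._df: list[float] = []
        self._cache: dict = {}

    def add(self, upper, cov, df) -> int:
        u = np.atleast_1d(np.asarray(upper, dtype=float))
        c = np.atleast_2d(np.asarray(cov, dtype=float))
        if u.shape[0] != c.shape[0]:
            raise ValueError("limit/scale dimension mismatch in cdf request")
        # identical requests (e.g. shared normalizers) are solved once
        key = (np.round(u, 12).tobytes(), np.round(c, 12).tobytes(), float(df))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self._upper.append(u)
        self._cov.append(c)
        self._df.append(float(df))
        idx = len(self._upper) - 1
        self._cache[key] = idx
        return idx

    def __len__(self) -> int:
        return len(self._upper)

    def solve(self, options: MvtOptions | None = None,
              chunk: int = 4096) -> np.ndarray:
        opts = options or DEFAULT_OPTIONS
        m = len(self._upper)
        values = np.empty(m)
        if m == 0:
            return values
        dims = np.array([u.shape[0] for u in self._upper])
        for d in np.unique(dims):
            idx = np.nonzero(dims == d)[0]
            for lo in range(0, idx.size, chunk):
                sel = idx[lo:lo + chunk]
                up = np.stack([self._upper[i] for i in sel])
                cv = np.stack([self._cov[i] for i in sel])
                dfs = np.array([self._df[i] for i in sel])
                vals, _ = mvt_cdf_batch(up, cv, dfs, opts)
                values[sel] = vals
        return values
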