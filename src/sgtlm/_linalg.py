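"""Small symmetric-matrix helpers shared across the package."""

from __future__ import annotations

import numpy as np

# relative eigenvalue floor below which a matrix is treated as non-PD
PD_RTOL = 1e-10


def as_matrix(x) -> np.ndarray:
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    return a


def check_pd(omega: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate symmetry and positive definiteness (relative eigenvalue floor)."""
    omega = as_matrix(omega)
    if not np.allclose(omega, omega.T, atol=1e-8 * max(1.0, np.abs(omega).max())):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(omega)
    if w[0] <= PD_RTOL * max(w[-1], 1e-300):
        raise ValueError(f"{name} is not positive definite (eigenvalues {w})")
    return omega


def sqrtm_sym(omega: np.ndarray) -> np.ndarray:
    """Symmetric positive-definite square root via eigendecomposition.

    The symmetric root (not Cholesky) is used everywhere a matrix square
    root appears so that shape-parameter conversions round-trip exactly.
    """
    omega = as_matrix(omega)
    w, v = np.linalg.eigh(omega)
    if w[0] <= 0:
        raise ValueError("matrix square root requires a positive definite input")
    return (v * np.sqrt(w)) @ v.T


def inv_sqrtm_sym(omega: np.ndarray) -> np.ndarray:
    omega = as_matrix(omega)
    w, v = np.linalg.eigh(omega)
    if w[0] <= 0:
        raise ValueError("matrix inverse square root requires a positive definite input")
    return (v / np.sqrt(w)) @ v.T


def vech_indices(q: int):
    """Column-major lower-triangle index arrays: (0,0),(1,0),..,(q-1,0),(1,1),..."""
    rows, cols = [], []
    for j in range(q):
        for i in range(j, q):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def nearest_pd(a: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetrize and floor eigenvalues; used to keep scale-matrix updates PD."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    if w[0] >= floor:
        return a
    w = np.maximum(w, floor)
    return (v * w) @ v.T
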