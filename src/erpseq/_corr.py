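"""Correlation-matrix parameterization via canonical partial correlations.

The random-slope correlation matrix is parameterized by the C-vine of
partial correlations z in (-1, 1). Under an LKJ(eta) law on the matrix the
partial correlations are independent, with (z+1)/2 ~ Beta(b, b) and
b = eta + (K - 2 - j)/2 for a coordinate in column j of the Cholesky
factor (Lewandowski, Kurowicka & Joe construction). Working in z-space
gives a normalized prior density without any matrix-space Jacobian.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln

__all__ = [
    "n_partials",
    "partial_beta_shapes",
    "cholesky_from_partials",
    "corr_from_partials",
    "lkj_partials_logpdf",
    "sample_partials",
]


def n_partials(k: int) -> int:
    return k * (k - 1) // 2


def _coord_columns(k: int) -> np.ndarray:
    """Column index j for each flat coordinate, row-major over (i, j), j < i."""
    return np.array([j for i in range(1, k) for j in range(i)], dtype=int)


def partial_beta_shapes(k: int, eta: float) -> np.ndarray:
    """Beta shape b for each flat partial-correlation coordinate."""
    cols = _coord_columns(k)
    return eta + (k - 2 - cols) / 2.0


def cholesky_from_partials(z: np.ndarray, k: int) -> np.ndarray:
    """Build the lower Cholesky factor of the correlation matrix.

    ``z`` has shape (..., n_partials(k)); returns (..., k, k).
    """
    z = np.asarray(z, dtype=float)
    batch = z.shape[:-1]
    L = np.zeros(batch + (k, k))
    L[..., 0, 0] = 1.0
    idx = 0
    for i in range(1, k):
        rem = np.ones(batch)  # prod of sqrt(1 - z^2) along the row so far
        for j in range(i):
            zij = z[..., idx]
            L[..., i, j] = zij * rem
            rem = rem * np.sqrt(1.0 - zij**2)
            idx += 1
        L[..., i, i] = rem
    return L


def corr_from_partials(z: np.ndarray, k: int) -> np.ndarray:
    L = cholesky_from_partials(z, k)
    return L @ np.swapaxes(L, -1, -2)


def lkj_partials_logpdf(z: np.ndarray, k: int, eta: float) -> np.ndarray:
    """Normalized log density of the partials under LKJ(eta), summed over coords."""
    z = np.asarray(z, dtype=float)
    if np.any(np.abs(z) >= 1.0):
        out = np.full(z.shape[:-1], -np.inf)
        ok = np.all(np.abs(z) < 1.0, axis=-1)
        zc = np.clip(z, -1 + 1e-12, 1 - 1e-12)
        out[ok] = lkj_partials_logpdf(zc, k, eta)[ok] if np.any(ok) else out[ok]
        return out
    b = partial_beta_shapes(k, eta)
    logp = (b - 1.0) * np.log1p(-(z**2)) - (2.0 * b - 1.0) * np.log(2.0) - betaln(b, b)
    return logp.sum(axis=-1)


def sample_partials(rng: np.random.Generator, k: int, eta: float, size=()) -> np.ndarray:
    b = partial_beta_shapes(k, eta)
    shape = tuple(np.atleast_1d(size)) if size != () else ()
    x = rng.beta(b, b, size=shape + (n_partials(k),))
    return 2.0 * x - 1.0
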