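"""Collapsed Gaussian mixed-model likelihood.

The Gaussian random effects (by-subject intercept+slopes with full
covariance, by-item intercepts) are marginalized analytically, so the
sampler only explores the fixed effects and variance components:

    y ~ N(X beta, V),  V = Z_s (I_S kron Sigma_s) Z_s' + sigma_item^2 Z_i Z_i'
                           + sigma_res^2 I_n

Evaluation uses the Woodbury identity on precomputed Gram matrices, so a
single likelihood evaluation costs O(q^3) with q = q_s * S + I random
effects, independent of the number of trials. All entry points accept a
leading batch axis so several MCMC chains evaluate in one call.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["CollapsedLMM"]

_LOG2PI = float(np.log(2.0 * np.pi))


class CollapsedLMM:
    """Precomputed sufficient statistics for a Gaussian LMM.

    Parameters
    ----------
    y : (n,) response vector.
    X : (n, p) fixed-effects design (first column is the intercept).
    subject : (n,) integer codes, or None for no subject effects.
    Zs : (n, q_s) per-trial covariates carried by the subject random
        effects (first column 1 for the random intercept).
    item : (n,) integer codes, or None for no item intercepts.
    """

    def __init__(self, y, X, subject=None, Zs=None, item=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        self.n = y.shape[0]
        self.p = X.shape[1]
        if X.shape[0] != self.n:
            raise ValueError("X and y row counts differ")
        self.yty = float(y @ y)
        self.Xty = X.T @ y
        self.XtX = X.T @ X
        self.fingerprint = hashlib.sha256(y.tobytes()).hexdigest()[:16]

        self.has_subject = subject is not None and Zs is not None and Zs.shape[1] > 0
        self.has_item = item is not None
        self.q_s = 0
        self.S = 0
        self.I = 0

        if self.has_subject:
            subject = np.asarray(subject)
            codes, _ = _codes(subject)
            Zs = np.asarray(Zs, dtype=float)
            self.q_s = Zs.shape[1]
            self.S = int(codes.max()) + 1
        if self.has_item:
            item = np.asarray(item)
            icodes, _ = _codes(item)
            self.I = int(icodes.max()) + 1

        q = self.q_s * self.S + self.I
        self.q = q
        if q:
            U = np.zeros((self.n, q))
            if self.has_subject:
                rows = np.arange(self.n)
                for a in range(self.q_s):
                    U[rows, codes * self.q_s + a] = Zs[:, a]
            if self.has_item:
                U[np.arange(self.n), self.q_s * self.S + icodes] = 1.0
            W = U.T @ U
            self.UtX = U.T @ X
            self.Uty = U.T @ y
            qs, S, I = self.q_s, self.S, self.I
            self.Wss = W[: qs * S, : qs * S].reshape(S, qs, S, qs) if self.has_subject else None
            self.Wsi = (
                W[: qs * S, qs * S :].reshape(S, qs, I)
                if self.has_subject and self.has_item
                else None
            )
            self.Wii = W[qs * S :, qs * S :] if self.has_item else None

    # -- likelihood -----------------------------------------------------

    def loglik(self, beta, A=None, sigma_item=None, sigma_res=None):
        """Batched marginal log likelihood.

        beta : (B, p); A : (B, q_s, q_s) Cholesky factor of Sigma_s
        (diag(sigma_s) @ L_corr); sigma_item, sigma_res : (B,).
        """
        beta = np.atleast_2d(np.asarray(beta, dtype=float))
        B = beta.shape[0]
        sigma_res = np.broadcast_to(np.asarray(sigma_res, dtype=float), (B,))
        s2 = sigma_res**2

        rr = (
            self.yty
            - 2.0 * beta @ self.Xty
            + np.einsum("bi,ij,bj->b", beta, self.XtX, beta)
        )

        if self.q == 0:
            return -0.5 * (self.n * (_LOG2PI + 2.0 * np.log(sigma_res)) + rr / s2)

        qs, S, I = self.q_s, self.S, self.I
        # T = L_D' W L_D assembled blockwise; L_D = blkdiag(I_S kron A, sigma_item I)
        T = np.zeros((B, self.q, self.q))
        if self.has_subject:
            tmp = np.einsum("bca,sctd->bsatd", A, self.Wss)
            Tss = np.einsum("bsatd,bde->bsate", tmp, A).reshape(B, qs * S, qs * S)
            T[:, : qs * S, : qs * S] = Tss
        if self.has_item:
            si = np.broadcast_to(np.asarray(sigma_item, dtype=float), (B,))
            T[:, qs * S :, qs * S :] = (si**2)[:, None, None] * self.Wii
            if self.has_subject:
                Tsi = np.einsum("bca,sci->bsai", A, self.Wsi).reshape(B, qs * S, I)
                Tsi = si[:, None, None] * Tsi
                T[:, : qs * S, qs * S :] = Tsi
                T[:, qs * S :, : qs * S] = np.swapaxes(Tsi, 1, 2)

        M = np.eye(self.q)[None] + T / s2[:, None, None]
        try:
            cholM = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return np.full(B, -np.inf)
        logdet_M = 2.0 * np.log(np.einsum("bii->bi", cholM)).sum(axis=1)
        logdet_V = self.n * 2.0 * np.log(sigma_res) + logdet_M

        v = self.Uty[None, :] - beta @ self.UtX.T  # (B, q)
        w = np.empty_like(v)
        if self.has_subject:
            vs = v[:, : qs * S].reshape(B, S, qs)
            w[:, : qs * S] = np.einsum("bca,bsc->bsa", A, vs).reshape(B, qs * S)
        if self.has_item:
            si = np.broadcast_to(np.asarray(sigma_item, dtype=float), (B,))
            w[:, qs * S :] = si[:, None] * v[:, qs * S :]
        t = np.linalg.solve(cholM, w[..., None])[..., 0]
        quad = (rr - (t**2).sum(axis=1) / s2) / s2
        return -0.5 * (self.n * _LOG2PI + logdet_V + quad)


def _codes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(values, return_inverse=True)
    return codes.astype(int), uniq
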