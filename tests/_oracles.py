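"""Independent oracles used to cross-check pipeline numerics.

These deliberately avoid the code paths they validate: the graphical-LASSO
oracle is an ADMM solver of the same penalized-likelihood objective, the
FDR oracle is a literal step-up enumeration, and the state-matching helper
uses Hungarian assignment on centroid correlations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def admm_glasso(S: np.ndarray, lam: float, rho: float = 1.0, n_iter: int = 2000,
                tol: float = 1e-9) -> np.ndarray:
    """ADMM solution of max logdet(T) - tr(S T) - lam*||T||_1 (off-diagonal)."""
    p = S.shape[0]
    Theta = np.eye(p)
    Z = np.eye(p)
    U = np.zeros((p, p))
    off = ~np.eye(p, dtype=bool)
    for _ in range(n_iter):
        # Theta-update: eigendecomposition of rho*(Z - U) - S
        w, V = np.linalg.eigh(rho * (Z - U) - S)
        theta_eig = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        Theta = (V * theta_eig) @ V.T
        # Z-update: soft-threshold off-diagonals
        A = Theta + U
        Z_new = A.copy()
        Z_new[off] = np.sign(A[off]) * np.maximum(np.abs(A[off]) - lam / rho, 0.0)
        r = np.abs(Z_new - Theta).max()
        s = np.abs(Z_new - Z).max()
        Z = Z_new
        U = U + Theta - Z
        if max(r, s) < tol:
            break
    return (Z + Z.T) / 2.0


def brute_force_bh(p: np.ndarray, q: float) -> np.ndarray:
    """Literal BH step-up: reject p_(1..i*) for the largest i with p_(i) <= i q / m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    i_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            i_star = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:i_star]] = True
    return reject


def match_centroids(est: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Hungarian match of estimated to true centroids; returns matched correlations."""
    k = true.shape[0]
    corr = np.corrcoef(np.vstack([est, true]))[:k, k:]
    row, col = linear_sum_assignment(-np.abs(corr))
    return np.abs(corr[row, col])


def random_spd(p: int, rng: np.random.Generator, cond: float = 10.0) -> np.ndarray:
    """Random well-conditioned SPD matrix with unit-scale diagonal."""
    Q, _ = np.linalg.qr(rng.normal(size=(p, p)))
    eig = np.linspace(1.0, cond, p)
    S = (Q * eig) @ Q.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
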