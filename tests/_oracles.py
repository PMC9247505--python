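"""Independent brute-force oracles used by the test suite.

All routines here build explicit dense matrices and use generic linear
algebra only — deliberately none of the closed-form compound-symmetry
shortcuts the package exploits — so they can serve as an independent
reference for the mixed-model computations.
"""

from __future__ import annotations

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))


def _dense_pieces(d, sigma2, y, X, centers):
    y = np.asarray(y, dtype=float)
    Xd = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    labels, codes = np.unique(np.asarray(centers), return_inverse=True)
    Z = np.zeros((len(y), len(labels)))
    Z[np.arange(len(y)), codes] = 1.0
    Sigma = sigma2 * np.eye(len(y)) + d * (Z @ Z.T)
    Sinv = np.linalg.inv(Sigma)
    return y, Xd, Z, Sigma, Sinv


def dense_gls(d, sigma2, y, X, centers) -> np.ndarray:
    """GLS fixed effects (intercept first) via explicit Sigma inversion."""
    y, Xd, _, _, Sinv = _dense_pieces(d, sigma2, y, X, centers)
    A = Xd.T @ Sinv @ Xd
    return np.linalg.solve(A, Xd.T @ Sinv @ y)


def dense_reml(d, sigma2, y, X, centers) -> float:
    """Restricted log-likelihood profiled over beta, dense-matrix route."""
    y, Xd, _, Sigma, Sinv = _dense_pieces(d, sigma2, y, X, centers)
    beta = dense_gls(d, sigma2, y, X, centers)
    r = y - Xd @ beta
    A = Xd.T @ Sinv @ Xd
    n, p1 = Xd.shape
    return -0.5 * (
        np.linalg.slogdet(Sigma)[1]
        + r @ Sinv @ r
        + np.linalg.slogdet(A)[1]
        + (n - p1) * LOG2PI
    )


def dense_blup(d, sigma2, y, X, centers) -> dict:
    """Per-center BLUP intercepts b = d Z' Sigma^-1 (y - X beta)."""
    y, Xd, Z, _, Sinv = _dense_pieces(d, sigma2, y, X, centers)
    beta = dense_gls(d, sigma2, y, X, centers)
    r = y - Xd @ beta
    b = d * (Z.T @ Sinv @ r)
    labels = np.unique(np.asarray(centers))
    return dict(zip(labels, b))


def ols_normal_equations(y, X) -> np.ndarray:
    """Plain least squares through the normal equations (intercept first)."""
    Xd = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ np.asarray(y, dtype=float))


def grid_search_reml(y, X, centers, objective, n_grid=400,
                     d_range=(1e-6, 0.2), s2_range=(1e-4, 0.2)):
    """Maximize a ReML objective over a log-spaced (d, sigma2) grid.

    Returns the maximizing (d, sigma2) and the grid spacing factors so the
    caller can assert agreement "within one grid cell".
    """
    ds = np.geomspace(*d_range, n_grid)
    s2s = np.geomspace(*s2_range, n_grid)
    best = (-np.inf, None, None)
    for d in ds:
        for s2 in s2s:
            ll = objective(d, s2, y, X, centers)
            if ll > best[0]:
                best = (ll, d, s2)
    step_d = ds[1] / ds[0]
    step_s2 = s2s[1] / s2s[0]
    return best[1], best[2], step_d, step_s2


def damped_eb_iteration(z, gamma_hat, delta2_hat, gamma_bar, tau2, lam, theta,
                        n_steps=2000, damping=0.5):
    """Brute-force fixed point of the EB conditional-posterior-mean recursion,
    iterated with heavy damping for a fixed large number of steps."""
    n = len(z)
    g = gamma_hat.astype(float).copy()
    d2 = delta2_hat.astype(float).copy()
    for _ in range(n_steps):
        g_t = (n * tau2 * gamma_hat + d2 * gamma_bar) / (n * tau2 + d2)
        d2_t = (theta + 0.5 * ((z - g_t) ** 2).sum(axis=0)) / (n / 2 + lam - 1)
        g = damping * g_t + (1 - damping) * g
        d2 = damping * d2_t + (1 - damping) * d2
    return g, d2
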