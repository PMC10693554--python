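"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (dense matrices, brute-force grids,
cold-started coordinate descent) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def balanced_anova_components(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """ANOVA (= REML, for balanced data) variance components of a one-way
    random-effects layout: sigma2 = MSW, sigma_alpha2 = max(0, (MSB - MSW)/m)."""
    labels = np.unique(groups)
    m = len(y) // len(labels)
    grand = y.mean()
    ssw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in labels)
    ssb = sum(m * (y[groups == g].mean() - grand) ** 2 for g in labels)
    msw = ssw / (len(y) - len(labels))
    msb = ssb / (len(labels) - 1)
    return msw, max(0.0, (msb - msw) / m)


def dense_ml_loglik(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray,
    beta: np.ndarray, sigma_alpha: float, sigma: float,
) -> float:
    """Marginal Gaussian log-likelihood with explicitly built covariance."""
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    V = sigma**2 * np.eye(len(y)) + sigma_alpha**2 * Z @ Z.T
    return float(multivariate_normal.logpdf(y, mean=X @ beta, cov=V))


def grid_ml_fit(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Brute-force ML fit: dense GLS over a two-stage grid in ln(theta).

    Returns (beta, sigma_alpha, sigma, loglik). At each theta the GLS beta and
    the profiled sigma^2 are computed with dense linear algebra and the
    likelihood is evaluated with scipy's multivariate normal.
    """
    n = len(y)
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    ZZ = Z @ Z.T

    def profile(theta: float):
        Vs = np.eye(n) + theta * ZZ
        Vinv = np.linalg.inv(Vs)
        A = X.T @ Vinv @ X
        beta = np.linalg.solve(A, X.T @ Vinv @ y)
        r = y - X @ beta
        sigma2 = float(r @ Vinv @ r) / n
        ll = float(
            multivariate_normal.logpdf(y, mean=X @ beta, cov=sigma2 * Vs)
        )
        return beta, sigma2, ll

    grid = np.r_[0.0, np.exp(np.linspace(-10, 6, 801))]
    lls = [profile(t)[2] for t in grid]
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    fine = np.linspace(lo, hi, 4001)
    lls = [profile(t)[2] for t in fine]
    k = int(np.argmax(lls))
    theta = fine[k]
    beta, sigma2, ll = profile(theta)
    return beta, float(np.sqrt(theta * sigma2)), float(np.sqrt(sigma2)), ll


def lasso_cd(
    X: np.ndarray, y: np.ndarray, lam: float,
    tol: float = 1e-12, max_iter: int = 100_000,
) -> tuple[float, np.ndarray]:
    """Cold-started cyclic coordinate descent for
    (1/2n)||y - b0 - X b||^2 + lam * ||b||_1. Returns (b0, b)."""
    n, p = X.shape
    v = (X * X).sum(axis=0) / n
    b0, b = float(y.mean()), np.zeros(p)
    r = y - b0 - X @ b
    for _ in range(max_iter):
        delta = 0.0
        new0 = b0 + r.mean()
        r -= new0 - b0
        delta = abs(new0 - b0)
        b0 = new0
        for j in range(p):
            z = X[:, j] @ r / n + v[j] * b[j]
            new = np.sign(z) * max(abs(z) - lam, 0.0) / v[j]
            if new != b[j]:
                r -= X[:, j] * (new - b[j])
                delta = max(delta, abs(new - b[j]))
                b[j] = new
        if delta < tol:
            break
    return b0, b


def blup_conditional_modes(
    y: np.ndarray, fitted_fixed: np.ndarray, groups: np.ndarray,
    sigma_alpha: float, sigma: float,
) -> dict:
    """Conditional modes of the animal intercepts given a fitted mean."""
    theta = sigma_alpha**2 / sigma**2
    out = {}
    resid = y - fitted_fixed
    for g in np.unique(groups):
        rg = resid[groups == g]
        out[g] = float(len(rg) * theta / (1 + len(rg) * theta) * rg.mean())
    return out


def gaussian_iid_loglik_at_mle(y: np.ndarray) -> float:
    """Closed-form max log-likelihood of an iid normal sample (MLE variance)."""
    n = len(y)
    s2 = float(((y - y.mean()) ** 2).mean())
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
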