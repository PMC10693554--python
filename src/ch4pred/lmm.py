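"""Random-intercept linear mixed model fitted by profiled ML or REML.

The model for methane response y_ij of animal i at measurement round j is

    y_ij = x_ij' beta + alpha_i + eps_ij,
    alpha_i ~ N(0, sigma_alpha^2),  eps_ij ~ N(0, sigma^2),

so the marginal covariance is sigma^2 (I + theta Z Z') with theta =
sigma_alpha^2 / sigma^2 and Z the animal indicator matrix. For a given theta
the GLS coefficients and sigma^2 have closed forms, which reduces estimation
to a one-dimensional search over ln(theta); that search is bracketed and the
boundary solution sigma_alpha = 0 is always considered. Standard errors come
from the inverse expected information for the fixed effects at the optimum.

Both the ML and REML log-likelihood optima are computed on every fit: REML is
the default for reported coefficient tables, while AIC/BIC always use the ML
log-likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import qr as _qr
from scipy.optimize import minimize_scalar

from .dataset_io import ConfigurationError, ModelingMatrix

__all__ = [
    "RankError",
    "RandomInterceptLMM",
    "fit_lmm",
    "predict_fixed",
    "information_criteria",
]

_LOG_THETA_LO, _LOG_THETA_HI = -18.0, 12.0
_SIGMA2_FLOOR = 1e-12


class RankError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class RandomInterceptLMM:
    """A fitted random-intercept model.

    Coefficients are in response units per unit of (typically standardized)
    predictor; ``sigma_alpha`` and ``sigma`` are in response units.
    """

    intercept: float
    intercept_se: float
    beta: np.ndarray
    beta_se: np.ndarray
    sigma_alpha: float
    sigma: float
    loglik_ml: float
    loglik_reml: float
    n_obs: int
    n_groups: int
    column_labels: tuple[str, ...]
    criterion: str

    @property
    def coefficients(self) -> dict[str, float]:
        out = {"(Intercept)": float(self.intercept)}
        out.update({c: float(b) for c, b in zip(self.column_labels, self.beta)})
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "intercept_se": self.intercept_se,
                "beta": list(map(float, self.beta)),
                "beta_se": list(map(float, self.beta_se)),
                "sigma_alpha": self.sigma_alpha,
                "sigma": self.sigma,
                "loglik_ml": self.loglik_ml,
                "loglik_reml": self.loglik_reml,
                "n_obs": self.n_obs,
                "n_groups": self.n_groups,
                "column_labels": list(self.column_labels),
                "criterion": self.criterion,
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "RandomInterceptLMM":
        d = json.loads(text)
        return RandomInterceptLMM(
            intercept=d["intercept"],
            intercept_se=d["intercept_se"],
            beta=np.asarray(d["beta"], dtype=float),
            beta_se=np.asarray(d["beta_se"], dtype=float),
            sigma_alpha=d["sigma_alpha"],
            sigma=d["sigma"],
            loglik_ml=d["loglik_ml"],
            loglik_reml=d["loglik_reml"],
            n_obs=d["n_obs"],
            n_groups=d["n_groups"],
            column_labels=tuple(d["column_labels"]),
            criterion=d["criterion"],
        )


# ---------------------------------------------------------------------------
# grouped sufficient statistics and the profiled likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Grouped:
    """Rows sorted by animal plus reduceat bookkeeping."""

    order: np.ndarray        # permutation sorting rows by group
    starts: np.ndarray       # reduceat start index per group
    sizes: np.ndarray        # records per group
    n_groups: int

    def group_sums(self, arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr, self.starts, axis=0)

    def expand(self, per_group: np.ndarray) -> np.ndarray:
        return np.repeat(per_group, self.sizes, axis=0)


def group_rows(group: np.ndarray) -> _Grouped:
    codes, _ = _factorize(group)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.r_[0, np.flatnonzero(np.diff(sorted_codes)) + 1]
    sizes = np.diff(np.r_[starts, len(sorted_codes)])
    return _Grouped(order=order, starts=starts, sizes=sizes, n_groups=len(starts))


def _factorize(group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniques, codes = np.unique(np.asarray(group), return_inverse=True)
    return codes, uniques


@dataclass(frozen=True)
class _CrossProds:
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    S: np.ndarray   # per-group column sums of X  (G x p)
    t: np.ndarray   # per-group sums of y         (G,)
    sizes: np.ndarray
    n: int
    p: int


def _crossprods(Xs: np.ndarray, ys: np.ndarray, grp: _Grouped) -> _CrossProds:
    return _CrossProds(
        XtX=Xs.T @ Xs,
        Xty=Xs.T @ ys,
        yty=float(ys @ ys),
        S=grp.group_sums(Xs),
        t=grp.group_sums(ys),
        sizes=grp.sizes,
        n=len(ys),
        p=Xs.shape[1],
    )


def _gls(cp: _CrossProds, theta: float):
    """GLS coefficients, generalized RSS and log|V*| at variance ratio theta."""
    c = theta / (1.0 + cp.sizes * theta)
    A = cp.XtX - (cp.S * c[:, None]).T @ cp.S
    b = cp.Xty - cp.S.T @ (c * cp.t)
    beta = np.linalg.solve(A, b)
    q = cp.yty - float(c @ (cp.t * cp.t))
    rss = max(q - float(beta @ b), _SIGMA2_FLOOR)
    logdet_v = float(np.sum(np.log1p(cp.sizes * theta)))
    return beta, A, rss, logdet_v


def _loglik_ml(cp: _CrossProds, theta: float) -> float:
    _, _, rss, logdet_v = _gls(cp, theta)
    n = cp.n
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    return -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet_v + n)


def _loglik_reml(cp: _CrossProds, theta: float) -> float:
    _, A, rss, logdet_v = _gls(cp, theta)
    n, p = cp.n, cp.p
    sigma2 = max(rss / (n - p), _SIGMA2_FLOOR)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + (n - p) * np.log(sigma2)
        + logdet_v
        + logdet_a
        + rss / sigma2
    )


def _maximize_profile(cp: _CrossProds, reml: bool) -> tuple[float, float]:
    """Return (theta_hat, loglik) maximizing the profiled criterion."""
    ll = _loglik_reml if reml else _loglik_ml

    def neg(t: float) -> float:
        return -ll(cp, float(np.exp(t)))

    res = minimize_scalar(
        neg, bounds=(_LOG_THETA_LO, _LOG_THETA_HI), method="bounded",
        options={"xatol": 1e-10},
    )
    best_t, best_ll = float(res.x), -float(res.fun)
    ll0 = ll(cp, 0.0)
    # prefer the boundary when the profile is flat (e.g. singleton groups)
    if ll0 >= best_ll - 1e-8 or best_t <= _LOG_THETA_LO + 1e-6:
        return 0.0, max(ll0, best_ll)
    return float(np.exp(best_t)), best_ll


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise RankError(f"singular design; collinear column(s): {bad}")


def fit_lmm(
    matrix: ModelingMatrix,
    criterion: str = "REML",
    include_random: bool = True,
) -> RandomInterceptLMM:
    """Fit the random-intercept model on a modeling matrix.

    Parameters
    ----------
    matrix
        Design and response; an intercept column is added internally.
    criterion
        ``"REML"`` (default, for reported coefficients) or ``"ML"``. Both
        log-likelihood optima are recorded on the fitted object regardless.
    include_random
        When False the animal intercept is dropped (theta fixed at 0), making
        the fit ordinary least squares with the residual variance MLE.
    """
    if criterion not in ("ML", "REML"):
        raise ConfigurationError("criterion must be 'ML' or 'REML'")
    n, p_design = matrix.n_obs, matrix.n_features
    p = p_design + 1
    if n <= p:
        raise ConfigurationError(f"need n_obs > n_fixed_effects ({n} <= {p})")
    labels = ("(Intercept)",) + tuple(matrix.columns)
    Xfull = np.column_stack([np.ones(n), matrix.X])
    _check_rank(Xfull, labels)

    grp = group_rows(matrix.group)
    Xs, ys = Xfull[grp.order], matrix.y[grp.order]
    cp = _crossprods(Xs, ys, grp)

    if include_random:
        theta_ml, ll_ml = _maximize_profile(cp, reml=False)
        theta_reml, ll_reml = _maximize_profile(cp, reml=True)
    else:
        theta_ml = theta_reml = 0.0
        ll_ml, ll_reml = _loglik_ml(cp, 0.0), _loglik_reml(cp, 0.0)

    theta = theta_reml if criterion == "REML" else theta_ml
    beta, A, rss, _ = _gls(cp, theta)
    dof = (n - p) if criterion == "REML" else n
    sigma2 = max(rss / dof, _SIGMA2_FLOOR)
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    return RandomInterceptLMM(
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        beta=beta[1:].copy(),
        beta_se=se[1:].copy(),
        sigma_alpha=float(np.sqrt(theta * sigma2)),
        sigma=float(np.sqrt(sigma2)),
        loglik_ml=float(ll_ml),
        loglik_reml=float(ll_reml),
        n_obs=n,
        n_groups=grp.n_groups,
        column_labels=tuple(matrix.columns),
        criterion=criterion,
    )


def predict_fixed(model: RandomInterceptLMM, matrix: ModelingMatrix) -> np.ndarray:
    """Fixed-effects-only prediction: intercept + X beta.

    Held-out animals have an unobserved random intercept, which is set to its
    mean of zero; this is the prediction rule used for test animals throughout
    the evaluation protocol.
    """
    if tuple(matrix.columns) != model.column_labels:
        raise ConfigurationError(
            f"column mismatch: model has {model.column_labels}, "
            f"matrix has {tuple(matrix.columns)}"
        )
    return model.intercept + matrix.X @ model.beta


def information_criteria(
    model: RandomInterceptLMM, n_variance_params: int = 2
) -> tuple[float, float]:
    """(AIC, BIC) from the ML log-likelihood.

    k counts the fixed effects (including the intercept) plus the variance
    parameters (sigma_alpha and sigma by default; configurable since
    conventions differ on counting a boundary-prone variance component).
    """
    k = 1 + len(model.beta) + n_variance_params
    aic = -2.0 * model.loglik_ml + 2.0 * k
    bic = -2.0 * model.loglik_ml + k * np.log(model.n_obs)
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# internals shared with the penalized fitter
# ---------------------------------------------------------------------------


def fit_variance_components(
    e: np.ndarray, grp: _Grouped, sorted_input: bool = True
) -> tuple[float, float, float]:
    """ML variance components for a zero-mean residual vector.

    Returns (sigma_alpha, sigma, loglik_ml) where loglik_ml is the marginal
    Gaussian log-likelihood of ``e`` at the fitted (sigma_alpha, sigma).
    ``e`` must already be ordered by group when ``sorted_input``.
    """
    es = e if sorted_input else e[grp.order]
    n = len(es)
    ete = float(es @ es)
    t = grp.group_sums(es)
    sizes = grp.sizes

    def ll(theta: float) -> float:
        c = theta / (1.0 + sizes * theta)
        rss = max(ete - float(c @ (t * t)), _SIGMA2_FLOOR)
        sigma2 = max(rss / n, _SIGMA2_FLOOR)
        logdet = float(np.sum(np.log1p(sizes * theta)))
        return -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)

    def neg(tl: float) -> float:
        return -ll(float(np.exp(tl)))

    res = minimize_scalar(
        neg, bounds=(_LOG_THETA_LO, _LOG_THETA_HI), method="bounded",
        options={"xatol": 1e-10},
    )
    theta, best = float(np.exp(res.x)), -float(res.fun)
    ll0 = ll(0.0)
    if ll0 >= best - 1e-8 or res.x <= _LOG_THETA_LO + 1e-6:
        theta, best = 0.0, max(ll0, best)
    c = theta / (1.0 + sizes * theta)
    rss = max(ete - float(c @ (t * t)), _SIGMA2_FLOOR)
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    return float(np.sqrt(theta * sigma2)), float(np.sqrt(sigma2)), float(best)


def whiten(arr: np.ndarray, theta: float, grp: _Grouped) -> np.ndarray:
    """Apply the correlation whitener (I + theta J)^(-1/2) blockwise.

    Rows must be ordered by group. The transform removes the within-animal
    correlation induced by the random intercept but keeps the residual scale,
    so at theta = 0 it is the identity.
    """
    if theta == 0.0:
        return arr.copy()
    d = (1.0 - 1.0 / np.sqrt(1.0 + grp.sizes * theta)) / grp.sizes
    sums = grp.group_sums(arr)
    if arr.ndim == 1:
        return arr - grp.expand(d * sums)
    return arr - grp.expand(d[:, None] * sums)


def loglik_ml_at(
    e: np.ndarray, sigma_alpha: float, sigma: float, grp: _Grouped
) -> float:
    """Marginal Gaussian log-likelihood of residuals at given variance components."""
    n = len(e)
    sigma2 = max(sigma**2, _SIGMA2_FLOOR)
    theta = sigma_alpha**2 / sigma2
    c = theta / (1.0 + grp.sizes * theta)
    t = grp.group_sums(e)
    quad = (float(e @ e) - float(c @ (t * t))) / sigma2
    logdet = n * np.log(sigma2) + float(np.sum(np.log1p(grp.sizes * theta)))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
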