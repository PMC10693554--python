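"""Sparse fixed-effect estimation in the random-intercept model (L1 and SCAD).

The penalized objective at regularization strength lambda is

    (1/2n) || W(theta) (y - b0 - X beta) ||^2  +  sum_j p_lambda(beta_j)

where W(theta) = (I + theta Z Z')^(-1/2) whitens the within-animal
correlation at the current variance ratio theta = sigma_alpha^2/sigma^2, the
intercept b0 is never penalized, and p_lambda is either the lasso penalty
lambda |b| or the SCAD penalty (quadratic spline with soft-threshold behavior
near zero and no shrinkage of large coefficients, shape parameter a > 2).

Estimation alternates, at each lambda on a decreasing grid with warm starts:

1. given (sigma_alpha, sigma), whiten and run cyclic coordinate descent with
   the penalty's thresholding operator until the largest coefficient change
   falls below tolerance (an active-set strategy with full-sweep KKT checks);
2. given the coefficients, refit (sigma_alpha, sigma) by maximum likelihood
   on the residuals.

Because the whitener excludes the 1/sigma scaling, setting the random effect
aside (theta = 0) makes step 1 exactly plain-lasso coordinate descent, which
is the reduction the tests exploit.

lambda is selected by BIC computed at the penalized estimates, with degrees
of freedom = nonzero penalized coefficients + intercept + two variance
parameters; ties are broken toward the larger lambda (the sparser model).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset_io import ConfigurationError, ModelingMatrix
from . import lmm as _lmm
from .lmm import RandomInterceptLMM, fit_lmm

__all__ = [
    "PenaltySpec",
    "PathEntry",
    "RegularizationPathResult",
    "scad_threshold",
    "scad_penalty",
    "fit_penalized_lmm",
    "select_lambda_bic",
    "refit_selected",
]

logger = logging.getLogger(__name__)

_DEFAULT_SCAD_A = 3.7


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty kind, lambda grid and SCAD shape.

    When ``lambda_grid`` is None a grid of ``n_lambda`` log-spaced values from
    lambda_max (smallest lambda zeroing every penalized coefficient under L1)
    down to ``lambda_min_ratio * lambda_max`` is generated at fit time.
    """

    kind: str = "L1"
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    scad_a: float = _DEFAULT_SCAD_A

    def __post_init__(self):
        if self.kind not in ("L1", "SCAD"):
            raise ConfigurationError("penalty kind must be 'L1' or 'SCAD'")
        if self.scad_a <= 2:
            raise ConfigurationError("SCAD shape parameter a must be > 2")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.ndim != 1 or len(grid) == 0:
                raise ConfigurationError("lambda_grid must be a non-empty 1-D array")
            if (np.diff(grid) >= 0).any():
                raise ConfigurationError("lambda_grid must be strictly decreasing")
            if (grid < 0).any():
                raise ConfigurationError("lambda values must be >= 0")


@dataclass(frozen=True)
class PathEntry:
    lam: float
    intercept: float
    beta: np.ndarray
    df: int
    sigma_alpha: float
    sigma: float
    loglik_ml: float
    bic: float
    converged: bool
    n_outer: int


@dataclass(frozen=True)
class RegularizationPathResult:
    entries: tuple[PathEntry, ...]
    columns: tuple[str, ...]
    n_obs: int
    penalty: PenaltySpec
    selected_index: int

    @property
    def selected(self) -> PathEntry:
        return self.entries[self.selected_index]

    @property
    def selected_support(self) -> tuple[str, ...]:
        entry = self.selected
        return tuple(c for c, b in zip(self.columns, entry.beta) if b != 0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "columns": list(self.columns),
                "n_obs": self.n_obs,
                "penalty": {"kind": self.penalty.kind, "scad_a": self.penalty.scad_a},
                "selected_index": self.selected_index,
                "selected_support": list(self.selected_support),
                "entries": [
                    {
                        "lambda": e.lam,
                        "intercept": e.intercept,
                        "beta": list(map(float, e.beta)),
                        "df": e.df,
                        "sigma_alpha": e.sigma_alpha,
                        "sigma": e.sigma,
                        "loglik_ml": e.loglik_ml,
                        "bic": e.bic,
                        "converged": e.converged,
                    }
                    for e in self.entries
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# thresholding operators
# ---------------------------------------------------------------------------


def soft_threshold(z: float, lam: float) -> float:
    return float(np.sign(z) * max(abs(z) - lam, 0.0))


def scad_threshold(z: float, lam: float, a: float = _DEFAULT_SCAD_A) -> float:
    """SCAD thresholding for a unit-curvature coordinate problem.

    Piecewise: soft thresholding for |z| <= 2 lambda, the interpolating linear
    rule for 2 lambda < |z| <= a lambda, and the identity (no shrinkage) for
    |z| > a lambda.
    """
    if a <= 2:
        raise ConfigurationError("SCAD shape parameter a must be > 2")
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    az = abs(z)
    if az <= 2 * lam:
        return soft_threshold(z, lam)
    if az <= a * lam:
        return float(((a - 1) * z - np.sign(z) * a * lam) / (a - 2))
    return float(z)


def scad_penalty(b: float, lam: float, a: float = _DEFAULT_SCAD_A) -> float:
    """The SCAD penalty function p_lambda(|b|)."""
    ab = abs(b)
    if ab <= lam:
        return lam * ab
    if ab <= a * lam:
        return (2 * a * lam * ab - ab * ab - lam * lam) / (2 * (a - 1))
    return lam * lam * (a + 1) / 2


def _scad_update(z: float, v: float, lam: float, a: float) -> float:
    """Minimize (v/2) b^2 - z b + scad_penalty(b) over b (curvature v > 0).

    Evaluates the stationary point of each penalty region, clipped to its
    region, and returns the candidate with the smallest objective. Reduces to
    ``scad_threshold(z, lam, a)`` when v = 1.
    """
    s = np.sign(z) if z != 0 else 1.0
    az = abs(z)
    candidates = [s * min(max(az - lam, 0.0) / v, lam)]
    denom = (a - 1) * v - 1.0
    if denom > 0:
        b2 = ((a - 1) * az - a * lam) / denom
        candidates.append(s * min(max(b2, lam), a * lam))
    candidates.append(s * max(az / v, a * lam))

    def obj(b: float) -> float:
        return 0.5 * v * b * b - z * b + scad_penalty(b, lam, a)

    best = min(candidates, key=obj)
    return float(best) if obj(best) < obj(0.0) else 0.0


# ---------------------------------------------------------------------------
# coordinate descent (numba-accelerated sweeps with a pure-Python fallback)
# ---------------------------------------------------------------------------


def _scad_update_py(z: float, v: float, lam: float, a: float) -> float:
    return _scad_update(z, v, lam, a)


def _sweep_py(XT, r, beta, v, cols, penalized, is_l1, lam, a):
    n = r.shape[0]
    delta = 0.0
    for j in cols:
        bj = beta[j]
        z = float(XT[j] @ r) / n + v[j] * bj
        if not penalized[j]:
            new = z / v[j]
        elif is_l1:
            new = soft_threshold(z, lam) / v[j]
        else:
            new = _scad_update(z, v[j], lam, a)
        if new != bj:
            r -= XT[j] * (new - bj)
            beta[j] = new
            d = abs(new - bj)
            if d > delta:
                delta = d
    return delta


try:  # pragma: no cover - exercised whenever numba is importable
    from numba import njit

    @njit(cache=False)
    def _scad_update_jit(z, v, lam, a):
        s = 1.0 if z >= 0 else -1.0
        az = abs(z)
        b1 = s * min(max(az - lam, 0.0) / v, lam)
        best, fbest = 0.0, 0.0
        for k in range(3):
            if k == 0:
                b = b1
            elif k == 1:
                denom = (a - 1.0) * v - 1.0
                if denom <= 0:
                    continue
                b = s * min(max(((a - 1.0) * az - a * lam) / denom, lam), a * lam)
            else:
                b = s * max(az / v, a * lam)
            ab = abs(b)
            if ab <= lam:
                pen = lam * ab
            elif ab <= a * lam:
                pen = (2.0 * a * lam * ab - ab * ab - lam * lam) / (2.0 * (a - 1.0))
            else:
                pen = lam * lam * (a + 1.0) / 2.0
            f = 0.5 * v * b * b - z * b + pen
            if f < fbest:
                best, fbest = b, f
        return best

    @njit(cache=False)
    def _sweep_jit(XT, r, beta, v, cols, penalized, is_l1, lam, a):
        n = r.shape[0]
        delta = 0.0
        for ci in range(cols.shape[0]):
            j = cols[ci]
            bj = beta[j]
            dot = 0.0
            for i in range(n):
                dot += XT[j, i] * r[i]
            z = dot / n + v[j] * bj
            if not penalized[j]:
                new = z / v[j]
            elif is_l1:
                az = abs(z) - lam
                if az > 0.0:
                    new = az / v[j] if z > 0 else -az / v[j]
                else:
                    new = 0.0
            else:
                new = _scad_update_jit(z, v[j], lam, a)
            if new != bj:
                d = new - bj
                for i in range(n):
                    r[i] -= XT[j, i] * d
                beta[j] = new
                ad = abs(d)
                if ad > delta:
                    delta = ad
        return delta

    _SWEEP = _sweep_jit
except ImportError:  # pragma: no cover
    _SWEEP = _sweep_py


def _coordinate_descent(
    Xw: np.ndarray,
    w1: np.ndarray,
    yw: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    kind: str,
    lam: float,
    a: float,
    tol: float,
    max_sweeps: int,
) -> tuple[float, np.ndarray, bool]:
    """Active-set coordinate descent on whitened data; returns (b0, beta, ok).

    The intercept rides along as an unpenalized column 0. Full sweeps
    alternate with sweeps over the active (nonzero) set; convergence is
    declared when a full sweep moves no coefficient by more than ``tol``.
    """
    n, p = Xw.shape
    XT = np.ascontiguousarray(np.vstack([w1[None, :], Xw.T]))
    b = np.empty(p + 1)
    b[0], b[1:] = beta0, beta
    v = np.maximum(np.einsum("ji,ji->j", XT, XT) / n, 1e-12)
    penalized = np.ones(p + 1, dtype=np.bool_)
    penalized[0] = False
    r = yw - XT.T @ b
    is_l1 = kind == "L1"
    all_cols = np.arange(p + 1, dtype=np.int64)
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        delta = _SWEEP(XT, r, b, v, all_cols, penalized, is_l1, lam, a)
        sweeps += 1
        if delta < tol:
            converged = True
            break
        active = np.flatnonzero(b).astype(np.int64)
        if 0 not in active:
            active = np.r_[np.int64(0), active]
        while sweeps < max_sweeps:
            delta = _SWEEP(XT, r, b, v, active, penalized, is_l1, lam, a)
            sweeps += 1
            if delta < tol:
                break
    return float(b[0]), b[1:].copy(), converged


def penalized_objective(
    Xw: np.ndarray,
    w1: np.ndarray,
    yw: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    kind: str,
    lam: float,
    a: float = _DEFAULT_SCAD_A,
) -> float:
    """The whitened penalized least-squares objective (used by invariant tests)."""
    n = len(yw)
    r = yw - w1 * beta0 - Xw @ beta
    loss = 0.5 * float(r @ r) / n
    if kind == "L1":
        pen = lam * float(np.abs(beta).sum())
    else:
        pen = float(sum(scad_penalty(b, lam, a) for b in beta))
    return loss + pen


# ---------------------------------------------------------------------------
# path fitting
# ---------------------------------------------------------------------------


def fit_penalized_lmm(
    matrix: ModelingMatrix,
    penalty: PenaltySpec,
    include_random: bool = True,
    max_outer: int = 50,
    cd_tol: float = 1e-6,
    max_sweeps: int = 2000,
    variance_tol: float = 1e-5,
    dfmax: int | None = None,
) -> RegularizationPathResult:
    """Fit the penalized random-intercept model over a lambda path.

    The matrix must be standardized (predictors centered/scaled with training
    statistics). With ``include_random=False`` the animal intercept is dropped
    and the fit is plain penalized least squares.

    ``dfmax`` truncates the path once an entry's nonzero count exceeds it.
    With more candidates than observations the smallest-lambda entries
    near-interpolate the data, so their profiled likelihood (and hence BIC)
    is meaningless; capping the model size at the largest identifiable order
    (floor(n/ln n) is the canonical choice) keeps BIC selection on the
    well-posed part of the path.
    """
    if not matrix.is_standardized:
        raise ConfigurationError("fit_penalized_lmm requires a standardized matrix")
    n, p = matrix.n_obs, matrix.n_features
    grp = _lmm.group_rows(matrix.group)
    Xs = np.asfortranarray(matrix.X[grp.order])
    ys = matrix.y[grp.order]
    ones = np.ones(n)

    # initial variance components from the intercept-only residuals
    if include_random:
        sigma_alpha, sigma, _ = _lmm.fit_variance_components(ys - ys.mean(), grp)
    else:
        sigma_alpha, sigma = 0.0, float(ys.std())
    theta = (sigma_alpha / sigma) ** 2 if sigma > 0 else 0.0

    grid = penalty.lambda_grid
    if grid is None:
        Xw0 = _lmm.whiten(Xs, theta, grp)
        yw0 = _lmm.whiten(ys, theta, grp)
        w10 = _lmm.whiten(ones, theta, grp)
        b0_init = float(w10 @ yw0) / max(float(w10 @ w10), 1e-12)
        resid0 = yw0 - w10 * b0_init
        lam_max = float(np.abs(Xw0.T @ resid0).max()) / n if p else 1.0
        lam_max = max(lam_max, 1e-8)
        grid = np.geomspace(lam_max, penalty.lambda_min_ratio * lam_max,
                            penalty.n_lambda)
    else:
        grid = np.asarray(grid, dtype=float)

    beta = np.zeros(p)
    beta0 = float(ys.mean())
    entries: list[PathEntry] = []
    for lam in grid:
        converged = False
        n_outer = 0
        for outer in range(max_outer):
            n_outer = outer + 1
            Xw = _lmm.whiten(Xs, theta, grp)
            yw = _lmm.whiten(ys, theta, grp)
            w1 = _lmm.whiten(ones, theta, grp)
            beta0, beta, cd_ok = _coordinate_descent(
                Xw, w1, yw, beta0, beta, penalty.kind, float(lam),
                penalty.scad_a, cd_tol, max_sweeps,
            )
            if not include_random:
                e = ys - beta0 - Xs @ beta
                sigma = float(np.sqrt(max(float(e @ e) / n, 1e-12)))
                sigma_alpha, theta = 0.0, 0.0
                converged = cd_ok
                break
            e = ys - beta0 - Xs @ beta
            new_sa, new_s, _ = _lmm.fit_variance_components(e, grp)
            dv = max(abs(new_sa - sigma_alpha), abs(new_s - sigma))
            sigma_alpha, sigma = new_sa, new_s
            theta = (sigma_alpha / sigma) ** 2 if sigma > 0 else 0.0
            if cd_ok and dv < variance_tol * max(1.0, sigma):
                converged = True
                break
        e = ys - beta0 - Xs @ beta
        loglik = _lmm.loglik_ml_at(e, sigma_alpha, sigma, grp)
        df = int(np.count_nonzero(beta))
        df_total = df + 1 + 2  # + intercept + two variance parameters
        bic = -2.0 * loglik + df_total * np.log(n)
        if not converged:
            logger.warning("penalized path entry at lambda=%.4g did not converge", lam)
        entries.append(
            PathEntry(
                lam=float(lam),
                intercept=float(beta0),
                beta=beta.copy(),
                df=df,
                sigma_alpha=float(sigma_alpha),
                sigma=float(sigma),
                loglik_ml=float(loglik),
                bic=float(bic),
                converged=converged,
                n_outer=n_outer,
            )
        )
        if dfmax is not None and df > dfmax:
            logger.info(
                "path truncated at lambda=%.4g: df=%d exceeds dfmax=%d", lam, df, dfmax
            )
            break
    selected = select_lambda_bic(entries, n, dfmax=dfmax)
    return RegularizationPathResult(
        entries=tuple(entries),
        columns=tuple(matrix.columns),
        n_obs=n,
        penalty=penalty,
        selected_index=selected,
    )


def select_lambda_bic(
    entries: Sequence[PathEntry], n_obs: int, dfmax: int | None = None
) -> int:
    """Index of the minimal-BIC converged entry; ties go to the larger lambda.

    Entries are assumed ordered by decreasing lambda, so scanning in order and
    keeping the first strict minimum implements the sparser-model tie-break.
    Entries beyond ``dfmax`` nonzero coefficients are ineligible (their
    profiled likelihood is degenerate when candidates outnumber observations).
    """
    best_idx, best_bic = None, np.inf
    for i, e in enumerate(entries):
        if not e.converged or not np.isfinite(e.bic):
            continue
        if dfmax is not None and e.df > dfmax:
            continue
        if e.bic < best_bic:
            best_idx, best_bic = i, e.bic
    if best_idx is None:
        raise ConfigurationError("no eligible converged entry on the regularization path")
    return best_idx


def refit_selected(
    matrix: ModelingMatrix,
    support: Sequence[str],
    criterion: str = "REML",
) -> RandomInterceptLMM:
    """Unpenalized LMM refit on a selected support (empty -> intercept-only)."""
    return fit_lmm(matrix.restrict(list(support)), criterion=criterion)
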