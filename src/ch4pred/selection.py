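"""Variable-selection routes: SIS prescreen, VIF filter, CV-tuned LASSO,
random-forest + boosting importance, and the conventional animal-only baseline.

These are the selectors that precede the mixed-model refit in the prediction
protocol. Routes based on linear penalties (glmmLasso-style L1, SCAD, plain
LASSO) first prune the ultra-high-dimensional genus space with sure
independence screening (marginal-correlation ranking, keeping floor(n/ln n)
columns by default) followed by an iterative variance-inflation-factor filter
(drop the worst column until every VIF < 5). The tree-ensemble route (RF-B)
skips prescreening: it ranks columns by random-forest importance and,
separately, by gradient-boosting importance, and keeps the union of the two
top-10 lists.

All selectors are deterministic given (matrix, parameters, seed); importance
and correlation ties are broken by column label.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import lasso_path

from .dataset_io import ANIMAL_PREDICTORS, ConfigurationError, ModelingMatrix
from .penalized import PenaltySpec, fit_penalized_lmm

__all__ = [
    "METHODS",
    "SelectionResult",
    "sis_screen",
    "vif_filter",
    "lasso_cv_select",
    "rf_boost_select",
    "conventional_select",
    "select_variables",
]

logger = logging.getLogger(__name__)

METHODS = ("conventional", "glmmLasso", "LASSO", "SCAD", "RF-B")


@dataclass(frozen=True)
class SelectionResult:
    method: str
    selected_columns: tuple[str, ...]
    diagnostics: Mapping[str, object] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(
            {
                "method": self.method,
                "selected_columns": list(self.selected_columns),
                "diagnostics": dict(self.diagnostics),
                "seed": self.seed,
            },
            indent=2,
            default=_default,
        )


def default_sis_keep(n_obs: int) -> int:
    """The canonical screening size floor(n / ln n)."""
    return max(1, int(np.floor(n_obs / np.log(n_obs))))


def sis_screen(
    matrix: ModelingMatrix, n_keep: int | None = None
) -> tuple[tuple[str, ...], np.ndarray]:
    """Sure independence screening by absolute marginal correlation.

    Returns the top ``n_keep`` column labels ranked by |corr(x_j, y)| (ties
    broken by label) together with the ranked correlation magnitudes.
    """
    if n_keep is None:
        n_keep = default_sis_keep(matrix.n_obs)
    if n_keep < 1:
        raise ConfigurationError("n_keep must be >= 1")
    p = matrix.n_features
    if n_keep > p:
        warnings.warn(f"n_keep={n_keep} exceeds p={p}; returning all columns")
        n_keep = p
    y = matrix.y - matrix.y.mean()
    X = matrix.X - matrix.X.mean(axis=0)
    sx = np.sqrt((X * X).sum(axis=0))
    sy = np.sqrt(float(y @ y))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(X.T @ y) / (sx * sy)
    corr = np.nan_to_num(corr, nan=0.0)
    order = np.lexsort((np.asarray(matrix.columns), -corr))
    top = order[:n_keep]
    return tuple(matrix.columns[i] for i in top), corr[top]


def _vif_values(X: np.ndarray, ridge: float) -> np.ndarray:
    """VIF of each column regressed on the others (columns assumed centered)."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    G = Xc.T @ Xc
    vifs = np.empty(p)
    for j in range(p):
        others = np.r_[0:j, j + 1 : p]
        xj = Xc[:, j]
        ss_tot = float(xj @ xj)
        if ss_tot == 0:
            vifs[j] = 1.0
            continue
        Gj = G[np.ix_(others, others)] + ridge * np.eye(p - 1)
        try:
            coef = np.linalg.solve(Gj, G[others, j])
        except np.linalg.LinAlgError:
            vifs[j] = np.inf
            continue
        ss_res = ss_tot - float(G[j, others] @ coef)
        r2 = 1.0 - max(ss_res, 0.0) / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(
    matrix: ModelingMatrix,
    columns: Sequence[str] | None = None,
    threshold: float = 5.0,
) -> tuple[tuple[str, ...], dict[str, float]]:
    """Iteratively drop the worst-VIF column until all VIF < threshold.

    When the candidate count reaches the observation count, exact VIFs are
    ill-defined and a small ridge term stabilizes the regressions (logged).
    Returns the retained columns (original order) and their final VIFs.
    """
    labels = list(columns) if columns is not None else list(matrix.columns)
    if len(labels) < 2:
        return tuple(labels), {c: 1.0 for c in labels}
    sub = matrix.restrict(labels)
    keep = list(range(len(labels)))
    ridge = 0.0
    if matrix.n_obs <= len(labels):
        ridge = 1e-6 * matrix.n_obs
        logger.info("vif_filter: p >= n, using ridge-stabilized VIF (ridge=%g)", ridge)
    while len(keep) > 1:
        X = sub.X[:, keep]
        vifs = _vif_values(X, ridge)
        worst = int(np.lexsort(([labels[k] for k in keep], -vifs))[0])
        if vifs[worst] < threshold:
            break
        del keep[worst]
    final_labels = tuple(labels[k] for k in keep)
    if len(keep) == 1:
        return final_labels, {final_labels[0]: 1.0}
    final_vifs = _vif_values(sub.X[:, keep], ridge)
    return final_labels, {c: float(v) for c, v in zip(final_labels, final_vifs)}


def _grouped_folds(group: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Animal-grouped fold assignment per row (records never straddle folds)."""
    animals = np.unique(group)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(animals)
    fold_of_animal = {a: i % n_folds for i, a in enumerate(perm)}
    return np.array([fold_of_animal[g] for g in group])


def lasso_cv_select(
    matrix: ModelingMatrix,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
) -> SelectionResult:
    """Plain LASSO (no random effect) tuned by animal-grouped cross-validation.

    The lambda path comes from the full training data; each fold refits the
    path and the lambda minimizing mean CV squared error wins (ties toward the
    larger lambda). The support is the set of nonzero coefficients at that
    lambda.
    """
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    y = matrix.y
    if float(np.var(y)) < 1e-12:
        warnings.warn("degenerate response variance; returning empty support")
        return SelectionResult("LASSO", (), {"reason": "degenerate response"}, seed)
    X = matrix.X
    yc = y - y.mean()
    alphas, coefs, _ = lasso_path(X, yc, alphas=n_lambda, eps=1e-3)
    folds = _grouped_folds(matrix.group, n_folds, seed)
    n_eff_folds = len(np.unique(folds))
    mse = np.zeros(len(alphas))
    for f in range(n_eff_folds):
        tr, va = folds != f, folds == f
        ytr_mean = y[tr].mean()
        _, cfs, _ = lasso_path(X[tr], y[tr] - ytr_mean, alphas=alphas)
        pred = ytr_mean + X[va] @ cfs  # (n_va, n_alphas)
        mse += ((y[va][:, None] - pred) ** 2).sum(axis=0)
    mse /= len(y)
    best = int(np.argmin(mse))  # alphas descend; argmin keeps the largest on ties
    support = tuple(
        c for c, b in zip(matrix.columns, coefs[:, best]) if b != 0.0
    )
    return SelectionResult(
        method="LASSO",
        selected_columns=support,
        diagnostics={
            "lambda": float(alphas[best]),
            "cv_mse": float(mse[best]),
            "n_folds": n_eff_folds,
            "fold_of_row": folds,
        },
        seed=seed,
    )


def _top_k(labels: Sequence[str], scores: np.ndarray, k: int) -> list[str]:
    order = np.lexsort((np.asarray(labels), -scores))
    return [labels[i] for i in order[:k]]


def rf_boost_select(
    matrix: ModelingMatrix,
    n_trees: int = 500,
    mtry: int = 40,
    top_k: int = 10,
    seed: int = 0,
    importance: str = "impurity",
    boost_params: Mapping[str, object] | None = None,
) -> SelectionResult:
    """Union of the random-forest and gradient-boosting top-k importance lists.

    Boosting defaults follow the classical gbm configuration: 100 depth-1
    trees with learning rate 0.1. ``importance`` selects impurity-based scores
    (default, cheap) or permutation importance on the training data.
    """
    p = matrix.n_features
    if mtry > p:
        warnings.warn(f"mtry={mtry} exceeds p={p}; clipping to {p}")
        mtry = p
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, random_state=seed
    )
    rf.fit(matrix.X, matrix.y)
    if importance == "permutation":
        perm = permutation_importance(
            rf, matrix.X, matrix.y, n_repeats=5, random_state=seed
        )
        rf_scores = perm.importances_mean
    else:
        rf_scores = rf.feature_importances_
    defaults = {"n_estimators": 100, "max_depth": 1, "learning_rate": 0.1}
    defaults.update(boost_params or {})
    gbm = GradientBoostingRegressor(random_state=seed, **defaults)
    gbm.fit(matrix.X, matrix.y)
    gbm_scores = gbm.feature_importances_

    rf_top = _top_k(matrix.columns, rf_scores, top_k)
    gbm_top = _top_k(matrix.columns, gbm_scores, top_k)
    union = tuple(sorted(set(rf_top) | set(gbm_top)))
    return SelectionResult(
        method="RF-B",
        selected_columns=union,
        diagnostics={
            "rf_top": rf_top,
            "boost_top": gbm_top,
            "rf_importance": {c: float(s) for c, s in zip(matrix.columns, rf_scores)},
            "boost_importance": {c: float(s) for c, s in zip(matrix.columns, gbm_scores)},
        },
        seed=seed,
    )


def conventional_select(family: str) -> SelectionResult:
    """The animal-only baseline: DMI, BW, A:P for ANIM-B; BW, A:P for DMI-B."""
    if family not in ANIMAL_PREDICTORS:
        raise ConfigurationError(f"unknown family {family!r}")
    return SelectionResult(
        method="conventional",
        selected_columns=tuple(ANIMAL_PREDICTORS[family]),
        diagnostics={"family": family},
    )


def select_variables(
    matrix: ModelingMatrix,
    method: str,
    seed: int = 0,
    sis_n_keep: int | None = None,
    vif_threshold: float = 5.0,
    screen: bool = True,
    candidate_columns: Sequence[str] | None = None,
    penalty_kwargs: Mapping[str, object] | None = None,
    rf_kwargs: Mapping[str, object] | None = None,
    lasso_kwargs: Mapping[str, object] | None = None,
) -> SelectionResult:
    """Dispatch one selection route on a standardized training matrix.

    ``candidate_columns`` restricts the candidate pool (used when screening
    was performed once on the full data, the leakage-prone as-written order).
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "conventional":
        return conventional_select(matrix.family)

    work = matrix if candidate_columns is None else matrix.restrict(candidate_columns)
    diagnostics: dict[str, object] = {}
    if method in ("glmmLasso", "SCAD", "LASSO") and screen:
        screened, corr = sis_screen(work, sis_n_keep)
        retained, vifs = vif_filter(work, screened, vif_threshold)
        diagnostics["n_screened"] = len(screened)
        diagnostics["n_after_vif"] = len(retained)
        diagnostics["max_vif"] = max(vifs.values()) if vifs else 1.0
        work = work.restrict(retained)

    if method == "LASSO":
        kwargs = dict(lasso_kwargs or {})
        res = lasso_cv_select(work, seed=seed, **kwargs)
    elif method == "RF-B":
        kwargs = dict(rf_kwargs or {})
        res = rf_boost_select(work, seed=seed, **kwargs)
    else:  # glmmLasso / SCAD: BIC-tuned penalized LMM path
        kwargs = dict(penalty_kwargs or {})
        spec = PenaltySpec(kind="L1" if method == "glmmLasso" else "SCAD", **kwargs)
        path = fit_penalized_lmm(work, spec)
        sel = path.selected
        diagnostics.update(
            {"lambda": sel.lam, "bic": sel.bic, "sigma_alpha": sel.sigma_alpha}
        )
        res = SelectionResult(
            method=method,
            selected_columns=path.selected_support,
            diagnostics=diagnostics,
            seed=seed,
        )
        return res
    merged = dict(diagnostics)
    merged.update(res.diagnostics)
    return SelectionResult(method, res.selected_columns, merged, seed)
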