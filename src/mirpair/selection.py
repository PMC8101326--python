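"""Nested pair-panel extraction from a single L1 logistic regularization path.

Panels of 1..k pairs are read off one LASSO path by controlling the penalty:
the size-j model lives at the largest lambda with exactly j active features,
so smaller panels are prefixes of larger ones (nested structure). The path
is solved by glmnet-style penalized IRLS: an outer quadratic approximation
to the logistic log-likelihood and inner cyclic coordinate descent with
soft-thresholding, warm-started along a log-spaced lambda grid.

Conventions: features are z-scored internally for the penalty; reported
coefficients are back-transformed to the original feature scale; the loss
is the mean (1/n) negative log-likelihood, so ``lambda_max`` — the smallest
penalty at which the null model is optimal — is
``max_j |x_j^T (y - ybar)| / n`` on standardized features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ModelFile
from .pairing import pair_id

__all__ = [
    "LassoPath",
    "NestedPanel",
    "fit_lasso_path",
    "fit_l1_logistic",
    "extract_nested_panel",
    "l1_objective",
    "NestedLassoSelector",
]

TOL = 1e-7
MAX_ITER = 100_000


class ConvergenceError(RuntimeError):
    pass


def l1_objective(X: np.ndarray, y: np.ndarray, b0: float, b: np.ndarray, lam: float) -> float:
    """Penalized mean negative log-likelihood (intercept unpenalized)."""
    eta = b0 + X @ b
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    return nll + lam * float(np.abs(b).sum())


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_solve(Xs, y, lam, b0, b, free, tol=TOL, max_iter=MAX_ITER):
    """Penalized IRLS + coordinate descent at one lambda (standardized X).

    ``free`` masks columns eligible for activation (constant/aliased columns
    stay at zero). Mutates and returns (b0, b, n_sweeps).
    """
    n, p = Xs.shape
    sweeps = 0
    for _outer in range(200):
        eta = b0 + Xs @ b
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(mu * (1.0 - mu), 1e-9)
        z = eta + (y - mu) / w
        wn = w / n
        # inner: coordinate descent on the weighted least squares problem
        r = z - eta
        b_before_outer = b.copy()
        b0_before_outer = b0
        for _inner in range(max_iter):
            sweeps += 1
            if sweeps > max_iter:
                raise ConvergenceError(
                    f"coordinate descent exceeded {max_iter} sweeps at lambda={lam:g}")
            max_delta = 0.0
            active_only = _inner % 5 != 0 and _inner > 0
            for j in range(p):
                if not free[j]:
                    continue
                if active_only and b[j] == 0.0:
                    continue
                wx = wn * Xs[:, j]
                denom = wx @ Xs[:, j]
                if denom <= 0:
                    continue
                num = wx @ r + denom * b[j]
                new = _soft(num, lam) / denom
                if new != b[j]:
                    r -= Xs[:, j] * (new - b[j])
                    max_delta = max(max_delta, abs(new - b[j]))
                    b[j] = new
            swn = wn.sum()
            shift = (wn @ r) / swn
            if shift != 0.0:
                b0 += shift
                r -= shift
                max_delta = max(max_delta, abs(shift))
            if max_delta < tol and not active_only:
                break
        if max(abs(b0 - b0_before_outer),
               float(np.max(np.abs(b - b_before_outer), initial=0.0))) < tol:
            break
    return b0, b, sweeps


@dataclass
class LassoPath:
    """One L1-logistic regularization path over a decreasing lambda grid.

    Coefficients are on the original feature scale; ``entry_order`` lists
    feature names in order of first activation along the path.
    """

    feature_names: list[str]
    lambda_grid: np.ndarray
    intercepts: np.ndarray
    coefs: np.ndarray                       # (n_lambda, p), original scale
    active_sets: list[list[str]]
    entry_order: list[str]
    aliased: dict[str, str] = field(default_factory=dict)
    std_coefs: np.ndarray | None = None     # standardized scale, for diagnostics
    std_intercepts: np.ndarray | None = None

    def n_active(self) -> np.ndarray:
        return np.asarray([len(s) for s in self.active_sets])

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambda_grid, "n_active": self.n_active()})


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    usable = sd > 0
    sd_safe = np.where(usable, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe, usable


def _find_aliases(Xs: np.ndarray, names: list[str], usable: np.ndarray) -> dict[str, str]:
    """Exact duplicate standardized columns: all but the lexicographically
    first are excluded from the path and reported as aliased."""
    groups: dict[bytes, list[int]] = {}
    for j in range(Xs.shape[1]):
        if not usable[j]:
            continue
        groups.setdefault(np.round(Xs[:, j], 12).tobytes(), []).append(j)
    aliased = {}
    for idxs in groups.values():
        if len(idxs) > 1:
            keep = min(idxs, key=lambda j: names[j])
            for j in idxs:
                if j != keep:
                    aliased[names[j]] = names[keep]
    return aliased


def fit_lasso_path(
    X,
    y: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> LassoPath:
    """Fit the L1-penalized logistic path on ``X`` (samples x features).

    ``X`` may be a DataFrame (column names become feature names) or array.
    The grid is log-spaced from ``lambda_max`` down to
    ``lambda_max * lambda_min_ratio``.
    """
    names = list(X.columns) if hasattr(X, "columns") else [str(j) for j in range(np.shape(X)[1])]
    Xa = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(Xa).all():
        raise ValueError("features must be finite (no missing values) for the path fit")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, p = Xa.shape
    Xs, mu, sd, usable = _standardize(Xa)
    if not usable.any():
        raise ValueError("all features are constant; nothing to select")
    aliased = _find_aliases(Xs, names, usable)
    free = usable.copy()
    for dropped in aliased:
        free[names.index(dropped)] = False

    ybar = y.mean()
    scores = np.abs(Xs.T @ (y - ybar)) / n
    lambda_max = float(scores[free].max())
    if lambda_max <= 0:
        raise ValueError("labels carry no signal gradient; cannot set lambda_max")
    grid = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)

    b0 = float(np.log(ybar / (1 - ybar)))
    b = np.zeros(p)
    intercepts = np.empty(n_lambda)
    coefs_std = np.empty((n_lambda, p))
    active_sets: list[list[str]] = []
    entry_order: list[str] = []
    entry_step: dict[str, int] = {}
    for t, lam in enumerate(grid):
        if t == 0:
            # at lambda_max the null model is optimal by construction
            b0, b = float(np.log(ybar / (1 - ybar))), np.zeros(p)
        else:
            b0, b, _ = _cd_solve(Xs, y, lam, b0, b, free, tol=tol, max_iter=max_iter)
        intercepts[t] = b0
        coefs_std[t] = b
        act = [names[j] for j in range(p) if b[j] != 0.0]
        active_sets.append(act)
        for name in act:
            if name not in entry_step:
                entry_step[name] = t

    # entry order: by grid step; ties broken by |coef| at the next grid
    # point (larger first), then lexicographic pair ID
    def _tiebreak(name: str):
        t = entry_step[name]
        t_next = min(t + 1, n_lambda - 1)
        j = names.index(name)
        return (t, -abs(coefs_std[t_next, j]), name)

    entry_order = sorted(entry_step, key=_tiebreak)

    coefs = coefs_std / sd[None, :]
    intercepts_orig = intercepts - coefs @ mu
    return LassoPath(
        feature_names=names,
        lambda_grid=grid,
        intercepts=intercepts_orig,
        coefs=coefs,
        active_sets=active_sets,
        entry_order=entry_order,
        aliased=aliased,
        std_coefs=coefs_std,
        std_intercepts=intercepts,
    )


def fit_l1_logistic(
    X, y: np.ndarray, lam: float, tol: float = TOL, max_iter: int = MAX_ITER
):
    """Single-lambda L1 logistic fit (warm-started from the null model).

    Returns ``(intercept, coefficients)`` on the original feature scale.
    """
    Xa = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    Xs, mu, sd, usable = _standardize(Xa)
    ybar = y.mean()
    lambda_max = float((np.abs(Xs.T @ (y - ybar)) / n)[usable].max())
    b0 = float(np.log(ybar / (1 - ybar)))
    b = np.zeros(p)
    free = usable.copy()
    if lam < lambda_max:
        for step in np.geomspace(lambda_max, lam, 10):
            b0, b, _ = _cd_solve(Xs, y, step, b0, b, free, tol=tol, max_iter=max_iter)
    else:
        b0, b, _ = _cd_solve(Xs, y, lam, b0, b, free, tol=tol, max_iter=max_iter)
    coef = b / sd
    return float(b0 - coef @ mu), coef


@dataclass
class NestedPanel:
    """Models of sizes 1..k sharing a common prefix of pairs."""

    models: list[ModelFile]
    warnings: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [len(m.pairs) for m in self.models]

    def model_of_size(self, k: int) -> ModelFile:
        for m in self.models:
            if len(m.pairs) == k:
                return m
        raise KeyError(f"no model of size {k} in panel (sizes {self.sizes})")


def _as_pair(name: str) -> tuple[str, str]:
    if "|" in name:
        a, b = name.split("|", 1)
        return (a, b)
    # plain feature name: encode as a degenerate canonical pair
    return tuple(sorted((name, name + "~")))  # pragma: no cover


def extract_nested_panel(
    path: LassoPath,
    k_max: int,
    X=None,
    y: np.ndarray | None = None,
    fingerprint: str = "",
) -> NestedPanel:
    """Read nested models of sizes 1..k_max off a fitted path.

    The size-j model uses the first j features of ``entry_order``; its
    lambda is the largest grid lambda whose active set is exactly those j
    features, with its coefficients taken there. If no grid lambda has that
    exact active set (drop/re-entry along the path), the model is refit by
    L1 on those j features at the geometric midpoint of the entry lambdas
    of features j and j+1, and the deviation is recorded as a warning.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    warnings: list[str] = []
    avail = len(path.entry_order)
    if avail < k_max:
        warnings.append(
            f"only {avail} feature(s) ever activate; returning maximal panel "
            f"instead of k_max={k_max}")
        k_max = avail
    if k_max == 0:
        raise ValueError("no features ever activate on the path")

    models: list[ModelFile] = []
    name_to_col = {nm: j for j, nm in enumerate(path.feature_names)}
    entry_lambda = {}
    for nm in path.entry_order:
        for t, act in enumerate(path.active_sets):
            if nm in act:
                entry_lambda[nm] = path.lambda_grid[t]
                break
    for j in range(1, k_max + 1):
        wanted = set(path.entry_order[:j])
        ordered_names = path.entry_order[:j]
        lam_j = None
        coef_row = None
        for t, act in enumerate(path.active_sets):
            if set(act) == wanted:
                lam_j = float(path.lambda_grid[t])
                coef_row = path.coefs[t]
                intercept = float(path.intercepts[t])
                break
        if lam_j is None:
            if X is None or y is None:
                raise ValueError(
                    f"no grid lambda has exactly the first {j} features active; "
                    "pass X and y to allow the midpoint refit")
            nxt = (entry_lambda[path.entry_order[j]]
                   if j < avail else path.lambda_grid[-1])
            lam_j = float(np.sqrt(entry_lambda[ordered_names[-1]] * nxt))
            Xa = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, float)
            cols = [name_to_col[nm] for nm in ordered_names]
            intercept, sub_coef = fit_l1_logistic(Xa[:, cols], y, lam_j)
            coef_row = np.zeros(len(path.feature_names))
            coef_row[cols] = sub_coef
            warnings.append(
                f"size-{j} model refit at midpoint lambda {lam_j:g} "
                "(active set never exact on the grid)")
        pair_list = [_as_pair(nm) for nm in ordered_names]
        coefs = [intercept] + [float(coef_row[name_to_col[nm]]) for nm in ordered_names]
        models.append(ModelFile(
            pairs=pair_list,
            algorithm="lasso_logistic",
            parameters={"n_lambda": len(path.lambda_grid)},
            coefficients=coefs,
            lambda_=lam_j,
            training_fingerprint=fingerprint,
        ))
    return NestedPanel(models, warnings)


class NestedLassoSelector(BaseEstimator):
    """Sklearn-style estimator: fit an L1 logistic path and expose nested panels.

    Parameters
    ----------
    k_max : largest panel size to extract.
    n_lambda, lambda_min_ratio : grid of the regularization path.

    Attributes (after fit)
    ----------------------
    path_ : LassoPath
    panel_ : NestedPanel with models of sizes 1..k_max
    entry_order_ : feature names in activation order
    """

    def __init__(self, k_max: int = 4, n_lambda: int = 100, lambda_min_ratio: float = 0.01):
        self.k_max = k_max
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio

    def fit(self, X, y):
        self.path_ = fit_lasso_path(
            X, y, n_lambda=self.n_lambda, lambda_min_ratio=self.lambda_min_ratio)
        self.panel_ = extract_nested_panel(self.path_, self.k_max, X=X, y=y)
        self.entry_order_ = list(self.path_.entry_order)
        return self

    def get_support_names(self, k: int | None = None) -> list[str]:
        k = k if k is not None else self.k_max
        return [pair_id(*p) for p in self.panel_.model_of_size(
            min(k, len(self.entry_order_))).pairs]
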