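"""Normalizer-free miRNA-pair ratio features and the univariate pair screen.

The core representation: for two miRNAs measured in the same sample, the
log2 ratio ``x_a - x_b`` cancels any sample-wide additive term on the log
scale (dilution, input amount, reference-gene choice), so no endogenous or
spike-in normalizer is needed. On RT-qPCR data the same feature is the
within-sample delta-Ct, ``Ct_b - Ct_a``, under the ideal-efficiency model
``abundance ∝ 2^(-Ct)``.

Pairs are canonically oriented lexicographically (``mirna_a < mirna_b``)
and named ``"a|b"``; sign conventions are absorbed by model coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix

__all__ = [
    "PairMatrix",
    "build_pair_matrix",
    "ct_pair_features",
    "univariate_screen",
    "screen_logistic",
    "PairRatioTransformer",
    "UnivariateScreen",
    "pair_id",
]


def pair_id(a: str, b: str) -> str:
    return f"{a}|{b}"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"a pair needs two distinct miRNAs, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass
class PairMatrix:
    """Pair x sample matrix of log2-ratio features.

    ``values`` is indexed by pair ID ``"a|b"`` with sample IDs as columns;
    ``pairs`` lists the (a, b) tuples in row order; ``labels`` optionally
    carries the 0/1 class of each sample.
    """

    pairs: list[tuple[str, str]]
    values: pd.DataFrame
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.pairs) != self.values.shape[0]:
            raise ValueError("pairs list length must match value rows")
        seen = set()
        for a, b in self.pairs:
            if not a < b:
                raise ValueError(f"pair ({a!r}, {b!r}) not canonically oriented")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a!r}, {b!r})")
            seen.add((a, b))
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[1]:
                raise ValueError("labels length must match number of samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def X(self) -> pd.DataFrame:
        """Samples x pairs orientation for model fitting."""
        return self.values.T

    def subset(self, pairs: list[tuple[str, str]]) -> "PairMatrix":
        ids = [pair_id(*p) for p in pairs]
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise KeyError(f"pair(s) not in matrix: {missing}")
        return PairMatrix(list(pairs), self.values.loc[ids], self.labels)


def build_pair_matrix(
    matrix: ExpressionMatrix,
    mirnas: list[str] | None = None,
    labels: np.ndarray | None = None,
) -> PairMatrix:
    """All C(m, 2) pairwise log2-ratio features over ``mirnas``.

    Feature value for pair (a, b), a < b lexicographically, is
    ``log2expr(a) - log2expr(b)`` per sample; a missing member value makes
    the feature missing for that sample (no imputation).
    """
    if matrix.scale_tag != "log2":
        raise ValueError("build_pair_matrix requires a log2-scale matrix; "
                         "use ct_pair_features for Ct data")
    if mirnas is None:
        mirnas = matrix.mirna_ids
    mirnas = list(mirnas)
    unknown = [m for m in mirnas if m not in matrix.values.index]
    if unknown:
        raise KeyError(f"miRNA ID(s) not in matrix: {unknown[:5]}")
    if len(set(mirnas)) != len(mirnas):
        raise ValueError("duplicate miRNA IDs in pairing request")
    if len(mirnas) < 2:
        raise ValueError("need at least 2 miRNAs to build pairs")
    ordered = sorted(mirnas)
    x = matrix.values.loc[ordered].to_numpy(dtype=float)
    idx_a, idx_b = np.triu_indices(len(ordered), k=1)
    vals = x[idx_a] - x[idx_b]
    pairs = [(ordered[i], ordered[j]) for i, j in zip(idx_a, idx_b)]
    frame = pd.DataFrame(vals, index=[pair_id(a, b) for a, b in pairs],
                         columns=matrix.values.columns)
    return PairMatrix(pairs, frame, labels)


def ct_pair_features(
    ct_matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    labels: np.ndarray | None = None,
) -> PairMatrix:
    """Delta-Ct rendering of pair features: value(a, b) = Ct(b) - Ct(a).

    Under ``abundance ∝ 2^(-Ct)`` this equals the log2 abundance ratio
    a over b, matching the chip-side orientation so chip-trained models
    apply without sign changes.
    """
    if ct_matrix.scale_tag != "ct":
        raise ValueError("ct_pair_features requires a Ct-scale matrix")
    pairs = [canonical_pair(a, b) for a, b in pairs]
    members = sorted({m for p in pairs for m in p})
    missing = [m for m in members if m not in ct_matrix.values.index]
    if missing:
        raise KeyError(f"pair member(s) not in Ct matrix: {missing}")
    ct = ct_matrix.values
    rows = {pair_id(a, b): ct.loc[b].to_numpy() - ct.loc[a].to_numpy() for a, b in pairs}
    frame = pd.DataFrame(rows, index=ct.columns).T
    frame.columns = ct.columns
    return PairMatrix(pairs, frame, labels)


def screen_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Univariate logistic fits ``y ~ 1 + x_j`` for every column, vectorized.

    Newton–Raphson on all features simultaneously (closed-form 2x2 solves).
    Returns slope, Wald SE, two-sided Wald p, plus flags for perfectly
    separating and constant features. Missing feature values are excluded
    per feature. Separating features get ``p = 0`` and an infinite slope of
    the separating sign; constant features get ``p = 1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mask = np.isfinite(X)
    Xf = np.where(mask, X, 0.0)
    yc = y[:, None]

    with np.errstate(invalid="ignore"):
        case_min = np.where(mask & (yc == 1), X, np.inf).min(axis=0)
        case_max = np.where(mask & (yc == 1), X, -np.inf).max(axis=0)
        ctrl_min = np.where(mask & (yc == 0), X, np.inf).min(axis=0)
        ctrl_max = np.where(mask & (yc == 0), X, -np.inf).max(axis=0)
    separated_pos = case_min > ctrl_max   # cases strictly above controls
    separated_neg = case_max < ctrl_min
    separated = separated_pos | separated_neg

    nobs = mask.sum(axis=0)
    mean = Xf.sum(axis=0) / np.maximum(nobs, 1)
    var = (mask * (Xf - mean) ** 2).sum(axis=0) / np.maximum(nobs, 1)
    constant = var == 0

    b0 = np.zeros(p)
    b1 = np.zeros(p)
    fit = ~separated & ~constant
    for _ in range(max_iter):
        eta = b0[None, :] + Xf * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1 - mu) * mask
        r = (yc - mu) * mask
        g0 = r.sum(axis=0)
        g1 = (r * Xf).sum(axis=0)
        s00 = w.sum(axis=0)
        s01 = (w * Xf).sum(axis=0)
        s11 = (w * Xf * Xf).sum(axis=0)
        det = s00 * s11 - s01 * s01
        safe = det > 1e-12
        d0 = np.where(safe, (s11 * g0 - s01 * g1) / np.where(safe, det, 1.0), 0.0)
        d1 = np.where(safe, (s00 * g1 - s01 * g0) / np.where(safe, det, 1.0), 0.0)
        b0 = b0 + np.where(fit, d0, 0.0)
        b1 = b1 + np.where(fit, d1, 0.0)
        if np.max(np.abs(np.where(fit, d1, 0.0)), initial=0.0) < tol and \
           np.max(np.abs(np.where(fit, d0, 0.0)), initial=0.0) < tol:
            break

    eta = b0[None, :] + Xf * b1[None, :]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1 - mu) * mask
    s00 = w.sum(axis=0)
    s01 = (w * Xf).sum(axis=0)
    s11 = (w * Xf * Xf).sum(axis=0)
    det = s00 * s11 - s01 * s01
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, s00 / np.where(det > 0, det, 1.0), np.inf))
        z = np.where(se > 0, b1 / se, 0.0)
    p_val = 2 * stats.norm.sf(np.abs(z))

    beta = b1.copy()
    beta[separated_pos] = np.inf
    beta[separated_neg] = -np.inf
    beta[constant] = np.nan
    p_val = np.where(separated, 0.0, p_val)
    p_val = np.where(constant, 1.0, p_val)
    return {"beta": beta, "se": se, "p_value": p_val,
            "separated": separated, "constant": constant}


def univariate_screen(
    pm: PairMatrix, alpha: float = 0.05, labels: np.ndarray | None = None
) -> tuple[pd.DataFrame, PairMatrix]:
    """Screen pairs by univariate logistic association with class.

    Keeps pairs with two-sided Wald ``p < alpha``. Perfectly separating
    pairs — the most promising biomarkers — are kept with ``p = 0`` and a
    raised ``separated`` flag rather than discarded for the numerical
    artifact of a diverging slope; constant pairs are dropped with ``p = 1``.

    Returns (screen table, filtered PairMatrix).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    y = labels if labels is not None else pm.labels
    if y is None:
        raise ValueError("labels required (pass labels= or set PairMatrix.labels)")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    res = screen_logistic(pm.X().to_numpy(), y)
    kept = (res["p_value"] < alpha) & ~res["constant"]
    table = pd.DataFrame(
        {
            "beta": res["beta"],
            "p_value": res["p_value"],
            "kept": kept,
            "separated": res["separated"],
        },
        index=pm.values.index,
    )
    kept_pairs = [p for p, k in zip(pm.pairs, kept) if k]
    filtered = PairMatrix(kept_pairs, pm.values.loc[kept], y)
    return table, filtered


class PairRatioTransformer(BaseEstimator, TransformerMixin):
    """Sklearn transformer: samples x miRNAs log2 frame -> samples x pair ratios.

    Parameters
    ----------
    mirnas : optional list of miRNA IDs to pair; defaults to all columns
        seen at fit time. Pairs are all C(m, 2) combinations, lexicographic,
        value ``x_a - x_b`` with a < b.
    """

    def __init__(self, mirnas: list[str] | None = None):
        self.mirnas = mirnas

    def fit(self, X: pd.DataFrame, y=None):
        cols = list(self.mirnas) if self.mirnas is not None else list(X.columns)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"miRNA ID(s) not in input: {missing[:5]}")
        if len(cols) < 2:
            raise ValueError("need at least 2 miRNAs to build pairs")
        ordered = sorted(cols)
        self.mirnas_ = ordered
        self.pairs_ = list(itertools.combinations(ordered, 2))
        self.feature_names_out_ = [pair_id(a, b) for a, b in self.pairs_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.mirnas_ if c not in X.columns]
        if missing:
            raise KeyError(f"miRNA ID(s) not in input: {missing[:5]}")
        v = X[self.mirnas_].to_numpy(dtype=float)
        idx_a, idx_b = np.triu_indices(len(self.mirnas_), k=1)
        out = v[:, idx_a] - v[:, idx_b]
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_out_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)


class UnivariateScreen(BaseEstimator, TransformerMixin):
    """Sklearn transformer keeping features univariately associated with class.

    Fits ``label ~ intercept + feature`` per column and keeps features with
    Wald ``p < alpha`` (separating features kept, constants dropped).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        arr = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, float)
        res = screen_logistic(arr, y)
        kept = (res["p_value"] < self.alpha) & ~res["constant"]
        names = list(X.columns) if hasattr(X, "columns") else list(range(arr.shape[1]))
        self.result_ = pd.DataFrame(
            {"beta": res["beta"], "p_value": res["p_value"],
             "kept": kept, "separated": res["separated"]},
            index=names,
        )
        self.kept_ = [n for n, k in zip(names, kept) if k]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]
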