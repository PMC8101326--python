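"""The four classifier families fitted on a fixed miRNA-pair panel.

Families: ``lasso_logistic`` (L1 logistic at the panel's recorded lambda,
not re-tuned), ``logistic`` (unpenalized ML with a tiny-ridge fallback
under perfect separation), ``random_forest`` and ``svm`` (RBF). Defaults
mirror the conventional R package defaults for each family: 500 trees with
sqrt(p) features per split; RBF SVM with cost 1 and gamma 1/p on
internally standardized features. Scores are always oriented so that
higher means more case-like: linear predictor for linear families, case
vote fraction for the forest, signed decision value for the SVM.

Optional age/sex covariates are appended as plain numeric columns
(age standardized, sex coded female=0 / male=1).
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ALGORITHMS, LINEAR_ALGORITHMS, ModelFile
from .pairing import pair_id
from .selection import fit_l1_logistic

__all__ = ["PairPanelClassifier", "fit_model", "predict_scores", "augment_covariates"]


class FeatureContractError(ValueError):
    """Feature names/order at predict time do not match the fitted model."""


def augment_covariates(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    which: tuple[str, ...] = (),
    age_center: float | None = None,
    age_scale: float | None = None,
) -> pd.DataFrame:
    """Append requested clinical covariates to a feature frame.

    ``age`` is standardized (center/scale default to the values computed on
    this frame's samples; pass the training values when transforming a test
    set); ``sex`` is coded female=0, male=1. Missing covariate values are
    refused, naming the offending sample.
    """
    which = tuple(which)
    unknown = set(which) - {"age", "sex"}
    if unknown:
        raise ValueError(f"unsupported covariate(s): {sorted(unknown)}")
    if not which:
        return features
    out = features.copy()
    lookup = meta.set_index("sample_id")
    absent = [s for s in out.index if s not in lookup.index]
    if absent:
        raise KeyError(f"samples without metadata: {absent[:5]}")
    for cov in which:
        vals = lookup.loc[out.index, cov]
        bad = vals.isna()
        if bad.any():
            raise ValueError(
                f"missing {cov} for sample(s): {list(out.index[bad])[:5]}")
        if cov == "age":
            v = vals.to_numpy(dtype=float)
            center = float(np.mean(v)) if age_center is None else age_center
            scale = float(np.std(v)) if age_scale is None else age_scale
            out["age"] = (v - center) / (scale if scale > 0 else 1.0)
        else:
            out["sex"] = (vals == "male").astype(float).to_numpy()
    return out


class PairPanelClassifier(BaseEstimator, ClassifierMixin):
    """A classifier from one of the four families, bound to a fixed pair list.

    Parameters
    ----------
    pairs : list of (mirna_a, mirna_b) tuples or ``"a|b"`` strings fixing
        the feature columns (canonical lexicographic orientation). If None,
        every column of the fit frame containing ``"|"`` is taken as a pair.
    algorithm : one of ``lasso_logistic``, ``logistic``, ``random_forest``,
        ``svm``.
    lambda_ : L1 penalty for ``lasso_logistic`` (required for that family).
    covariates : subset of ("age", "sex") naming extra feature columns that
        must be present in the input frame (use ``augment_covariates``).
    params : family-specific overrides (e.g. ``n_estimators``, ``C``).
    random_state : seed consumed by stochastic families (random forest).
    """

    def __init__(self, pairs=None, algorithm: str = "logistic",
                 lambda_: float | None = None, covariates: tuple[str, ...] = (),
                 params: dict | None = None, random_state: int = 0):
        self.pairs = pairs
        self.algorithm = algorithm
        self.lambda_ = lambda_
        self.covariates = covariates
        self.params = params
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _expected_columns(self, X: pd.DataFrame) -> list[str]:
        if self.pairs is None:
            pair_cols = [c for c in X.columns if "|" in c]
        else:
            pair_cols = [p if isinstance(p, str) else pair_id(*p) for p in self.pairs]
        return pair_cols + list(self.covariates)

    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        expected = self.feature_names_in_
        got = list(X.columns)
        if got != list(expected):
            missing = [c for c in expected if c not in got]
            extra = [c for c in got if c not in expected]
            if missing or extra or sorted(got) != sorted(expected):
                raise FeatureContractError(
                    f"feature mismatch: missing {missing}, extra {extra}, "
                    f"expected order {list(expected)}")
            raise FeatureContractError(
                f"feature order mismatch: expected {list(expected)}, got {got}")
        return X

    # -- sklearn API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {sorted(ALGORITHMS)}")
        expected = self._expected_columns(X)
        missing = [c for c in expected if c not in X.columns]
        if missing:
            raise FeatureContractError(f"fit frame lacks column(s): {missing}")
        X = X[expected]
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2 or counts.min() < 2:
            raise ValueError("need two classes with at least 2 samples each")
        arr = X.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("features must be finite at fit time "
                             "(missing values are refused, not imputed)")
        self.feature_names_in_ = list(expected)
        self.classes_ = np.array([0, 1])
        params = dict(self.params or {})
        self.separation_fallback_ = False

        if self.algorithm == "lasso_logistic":
            if self.lambda_ is None:
                raise ValueError("lasso_logistic requires lambda_ "
                                 "(the panel's recorded penalty)")
            b0, coef = fit_l1_logistic(arr, y, float(self.lambda_))
            self.intercept_, self.coef_ = b0, coef
        elif self.algorithm == "logistic":
            est = LogisticRegression(C=np.inf, solver="lbfgs",
                                     max_iter=int(params.get("max_iter", 5000)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(arr, y)
            eta = est.decision_function(arr)
            # perfectly separated training scores: the ML optimum diverges
            if eta[y == 1].min() > eta[y == 0].max():
                ridge = float(params.get("ridge_fallback", 1e-6))
                est = LogisticRegression(C=1.0 / ridge,
                                         solver="lbfgs", max_iter=10000)
                est.fit(arr, y)
                self.separation_fallback_ = True
                warnings.warn("perfect separation: fell back to ridge "
                              f"penalty {ridge:g}", stacklevel=2)
            self.intercept_ = float(est.intercept_[0])
            self.coef_ = est.coef_[0].copy()
        elif self.algorithm == "random_forest":
            est = RandomForestClassifier(
                n_estimators=int(params.get("n_estimators", 500)),
                max_features=params.get("max_features", "sqrt"),
                random_state=int(self.random_state),
            )
            est.fit(arr, y)
            self.estimator_ = est
        else:  # svm
            self.scaler_ = StandardScaler().fit(arr)
            est = SVC(kernel=params.get("kernel", "rbf"),
                      C=float(params.get("C", 1.0)),
                      gamma=params.get("gamma", "auto"))
            est.fit(self.scaler_.transform(arr), y)
            self.estimator_ = est
        self.training_fingerprint_ = hashlib.sha256(
            arr.tobytes() + y.tobytes()
            + repr((self.algorithm, sorted(params.items()), self.lambda_,
                    self.random_state)).encode()
        ).hexdigest()[:16]
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Per-sample score, higher = more case-like."""
        X = self._check_columns(X)
        arr = X.to_numpy(dtype=float)
        if self.algorithm in LINEAR_ALGORITHMS:
            return self.intercept_ + arr @ self.coef_
        if self.algorithm == "random_forest":
            return self.estimator_.predict_proba(arr)[:, 1]
        return self.estimator_.decision_function(self.scaler_.transform(arr))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        s = self.decision_function(X)
        cut = 0.5 if self.algorithm == "random_forest" else 0.0
        return (s > cut).astype(int)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self.algorithm == "svm":
            raise AttributeError("svm family exposes decision_function only")
        if self.algorithm == "random_forest":
            p1 = self.decision_function(X)
        else:
            p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p1, p1])

    # -- persistence -----------------------------------------------------
    def to_model_file(self) -> ModelFile:
        n_cov = len(self.covariates)
        pair_names = self.feature_names_in_[: len(self.feature_names_in_) - n_cov]
        pairs = [tuple(c.split("|", 1)) for c in pair_names]
        coefs = None
        if self.algorithm in LINEAR_ALGORITHMS:
            coefs = [float(self.intercept_)] + [float(c) for c in self.coef_]
        return ModelFile(
            pairs=pairs,
            algorithm=self.algorithm,
            parameters=dict(self.params or {}),
            coefficients=coefs,
            lambda_=float(self.lambda_) if self.lambda_ is not None else None,
            covariates_used=list(self.covariates),
            training_fingerprint=getattr(self, "training_fingerprint_", ""),
        )


def fit_model(features: pd.DataFrame, labels, algorithm: str,
              params: dict | None = None, seed: int = 0,
              lambda_: float | None = None,
              covariates: tuple[str, ...] = ()) -> PairPanelClassifier:
    """Thin functional wrapper over :class:`PairPanelClassifier`."""
    clf = PairPanelClassifier(algorithm=algorithm, params=params,
                              random_state=seed, lambda_=lambda_,
                              covariates=covariates)
    return clf.fit(features, labels)


def predict_scores(model: PairPanelClassifier, features: pd.DataFrame) -> np.ndarray:
    return model.decision_function(features)


def scores_from_model_file(mf: ModelFile, features: pd.DataFrame) -> np.ndarray:
    """Score samples with a serialized *linear* model (no retraining)."""
    if mf.algorithm not in LINEAR_ALGORITHMS:
        raise ValueError("only linear families can be scored from a model file; "
                         "non-linear families need their fitted estimator")
    cols = [pair_id(*p) for p in mf.pairs] + list(mf.covariates_used)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise FeatureContractError(f"feature(s) absent: {missing}")
    arr = features[cols].to_numpy(dtype=float)
    coefs = np.asarray(mf.coefficients, dtype=float)
    return coefs[0] + arr @ coefs[1:]
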