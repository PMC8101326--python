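import numpy as np
import pandas as pd
import pytest

from mirpair.classifiers import (FeatureContractError, PairPanelClassifier,
                                 augment_covariates, scores_from_model_file)
from mirpair.evaluation import random_split, roc_auc
from mirpair.io import ExpressionMatrix, ModelFile, labels_for
from mirpair.pairing import build_pair_matrix, ct_pair_features, pair_id
from mirpair.simulate import SimConfig, render_ct, simulate_cohort

ALGOS = ("lasso_logistic", "logistic", "random_forest", "svm")


def _toy_separable(n=30):
    rng = np.random.default_rng(1)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = pd.DataFrame({
        "a|b": y * 4.0 + rng.normal(scale=0.2, size=n),
        "c|d": -y * 3.0 + rng.normal(scale=0.2, size=n),
    }, index=[f"s{i}" for i in range(n)])
    return X, y


@pytest.mark.parametrize("algo", ALGOS)
def test_separable_data_training_auc_one(algo):
    X, y = _toy_separable()
    clf = PairPanelClassifier(algorithm=algo, lambda_=0.01, random_state=0)
    clf.fit(X, y)
    assert roc_auc(clf.decision_function(X), y).auc == 1.0


@pytest.mark.parametrize("algo", ALGOS)
def test_same_seed_same_scores_bitwise(algo, default_cohort):
    _, expr, _, truth, y = default_cohort
    pairs = [tuple(p) for p in truth["planted_pairs"]]
    X = build_pair_matrix(expr).X()[[pair_id(*p) for p in pairs]]
    runs = []
    for _ in range(2):
        clf = PairPanelClassifier(pairs=pairs, algorithm=algo, lambda_=0.05,
                                  random_state=7)
        clf.fit(X, y)
        runs.append(clf.decision_function(X))
    assert np.array_equal(runs[0], runs[1])


def test_zero_coefficients_score_zero():
    mf = ModelFile(pairs=[("a", "b")], algorithm="logistic",
                   coefficients=[0.0, 0.0])
    X = pd.DataFrame({"a|b": [1.0, -2.0, 3.5]})
    np.testing.assert_array_equal(scores_from_model_file(mf, X), [0.0, 0.0, 0.0])


def test_sign_reparameterization_identity(rng):
    X = pd.DataFrame({"a|b": rng.normal(size=10), "c|d": rng.normal(size=10)})
    mf = ModelFile(pairs=[("a", "b"), ("c", "d")], algorithm="logistic",
                   coefficients=[0.3, 1.2, -0.7])
    flipped = X.copy()
    flipped["a|b"] = -flipped["a|b"]
    mf_flip = ModelFile(pairs=[("a", "b"), ("c", "d")], algorithm="logistic",
                        coefficients=[0.3, -1.2, -0.7])
    np.testing.assert_allclose(scores_from_model_file(mf, X),
                               scores_from_model_file(mf_flip, flipped),
                               rtol=1e-14)


def test_feature_contract_enforced():
    X, y = _toy_separable()
    clf = PairPanelClassifier(algorithm="logistic").fit(X, y)
    with pytest.raises(FeatureContractError, match="missing"):
        clf.decision_function(X[["a|b"]])
    with pytest.raises(FeatureContractError, match="order"):
        clf.decision_function(X[["c|d", "a|b"]])
    extra = X.copy()
    extra["e|f"] = 0.0
    with pytest.raises(FeatureContractError, match="extra"):
        clf.decision_function(extra)


def test_missing_values_refused_at_fit():
    X, y = _toy_separable()
    X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        PairPanelClassifier(algorithm="logistic").fit(X, y)


def test_separation_triggers_ridge_fallback():
    n = 20
    y = np.array([1] * 10 + [0] * 10)
    X = pd.DataFrame({"a|b": y * 2.0 - 1.0})
    with pytest.warns(UserWarning, match="separation"):
        clf = PairPanelClassifier(algorithm="logistic").fit(X, y)
    assert clf.separation_fallback_
    assert np.isfinite(clf.coef_).all()


def test_permuted_labels_overfit_but_do_not_generalize(default_cohort):
    """Null cohort: training scores look great, holdout AUC is chance."""
    _, expr, meta, truth, y = default_cohort
    rng = np.random.default_rng(13)
    y_perm = rng.permutation(y)
    pairs = [tuple(p) for p in truth["planted_pairs"]]
    X = build_pair_matrix(expr).X()[[pair_id(*p) for p in pairs]]
    n_tr = 140
    clf = PairPanelClassifier(pairs=pairs, algorithm="random_forest",
                              random_state=0)
    clf.fit(X.iloc[:n_tr], y_perm[:n_tr])
    auc_tr = roc_auc(clf.decision_function(X.iloc[:n_tr]), y_perm[:n_tr]).auc
    auc_te = roc_auc(clf.decision_function(X.iloc[n_tr:]), y_perm[n_tr:]).auc
    assert auc_tr > 0.9          # forest memorizes the training half
    assert 0.35 <= auc_te <= 0.65  # and learns nothing transferable


def test_chip_trained_model_transfers_to_ct(default_cohort):
    cfg, expr, meta, truth, y = default_cohort
    pairs = [tuple(p) for p in truth["planted_pairs"]]
    cols = [pair_id(*p) for p in pairs]
    Xchip = build_pair_matrix(expr).X()[cols]
    clf = PairPanelClassifier(pairs=pairs, algorithm="logistic").fit(Xchip, y)
    ct = render_ct(expr, cfg)
    Xct = ct_pair_features(ct, pairs).X()[cols]
    s_chip = clf.decision_function(Xchip)
    s_ct = clf.decision_function(Xct)
    # per-sample drift bounded by the propagated Ct noise:
    # each feature differs by N(0, ct_noise_sd*sqrt(2)); 5 sigma margin
    bound = 5 * cfg.ct_noise_sd * np.sqrt(2) * np.abs(clf.coef_).sum()
    assert np.max(np.abs(s_chip - s_ct)) < bound


# ---------------------------------------------------------------- covariates

def test_covariate_augmentation_shapes(default_cohort):
    _, expr, meta, truth, y = default_cohort
    X = build_pair_matrix(expr).X()[
        [pair_id(*tuple(p)) for p in truth["planted_pairs"]]]
    assert augment_covariates(X, meta, ()) is X
    both = augment_covariates(X, meta, ("age", "sex"))
    assert both.shape[1] == X.shape[1] + 2
    assert set(both["sex"].unique()) <= {0.0, 1.0}
    assert abs(both["age"].mean()) < 1e-9  # standardized


def test_missing_covariate_names_sample(default_cohort):
    _, expr, meta, truth, y = default_cohort
    X = build_pair_matrix(expr).X()[
        [pair_id(*tuple(p)) for p in truth["planted_pairs"]]]
    broken = meta.copy()
    broken.loc[broken["sample_id"] == X.index[3], "age"] = np.nan
    with pytest.raises(ValueError, match=X.index[3]):
        augment_covariates(X, broken, ("age",))


def test_age_signal_boosts_augmented_svm():
    """When age carries independent signal, adding it must not hurt the SVM
    (mean holdout AUC over seeds)."""
    deltas = []
    for seed in range(6):
        cfg = SimConfig(age_effect=10.0, seed=900 + seed)
        expr, meta, truth, = simulate_cohort(cfg)
        y = labels_for(expr.sample_ids, meta)
        pairs = [tuple(p) for p in truth["planted_pairs"]]
        cols = [pair_id(*p) for p in pairs]
        X = build_pair_matrix(expr).X()[cols]
        plan = random_split(meta, 0.7, seed=seed)
        tr, te = plan.train_ids, plan.test_ids
        aucs = {}
        for covs in ((), ("age", "sex")):
            feats = augment_covariates(X, meta, covs)
            clf = PairPanelClassifier(pairs=pairs, algorithm="svm",
                                      covariates=covs)
            clf.fit(feats.loc[tr], labels_for(tr, meta))
            aucs[covs] = roc_auc(clf.decision_function(feats.loc[te]),
                                 labels_for(te, meta)).auc
        deltas.append(aucs[("age", "sex")] - aucs[()])
    assert np.mean(deltas) >= 0


def test_forest_grows_better_with_more_trees():
    diffs = []
    for seed in range(5):
        cfg = SimConfig(seed=700 + seed)
        expr, meta, truth = simulate_cohort(cfg)
        y = labels_for(expr.sample_ids, meta)
        pairs = [tuple(p) for p in truth["planted_pairs"]]
        cols = [pair_id(*p) for p in pairs]
        X = build_pair_matrix(expr).X()[cols]
        plan = random_split(meta, 0.7, seed=seed)
        tr, te = plan.train_ids, plan.test_ids
        aucs = {}
        for n_trees in (1, 500):
            clf = PairPanelClassifier(pairs=pairs, algorithm="random_forest",
                                      params={"n_estimators": n_trees},
                                      random_state=seed)
            clf.fit(X.loc[tr], labels_for(tr, meta))
            aucs[n_trees] = roc_auc(clf.decision_function(X.loc[te]),
                                    labels_for(te, meta)).auc
        diffs.append(aucs[500] - aucs[1])
    assert np.mean(diffs) >= 0


def test_model_file_export_round_trip(tmp_path, default_cohort):
    from mirpair.io import read_model, write_model
    _, expr, _, truth, y = default_cohort
    pairs = [tuple(p) for p in truth["planted_pairs"]]
    X = build_pair_matrix(expr).X()[[pair_id(*p) for p in pairs]]
    clf = PairPanelClassifier(pairs=pairs, algorithm="logistic").fit(X, y)
    mf = clf.to_model_file()
    write_model(mf, tmp_path / "m.json")
    back = read_model(tmp_path / "m.json")
    np.testing.assert_allclose(scores_from_model_file(back, X),
                               clf.decision_function(X), rtol=1e-12)
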