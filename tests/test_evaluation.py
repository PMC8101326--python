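import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirpair.evaluation import random_split, roc_auc, evaluate_subgroup
from mirpair.experiments import auc_bruteforce
from mirpair.classifiers import PairPanelClassifier
from mirpair.io import labels_for
from mirpair.pairing import build_pair_matrix, pair_id
from mirpair.simulate import SimConfig, simulate_cohort


def test_perfectly_ordered_scores_auc_one():
    y = np.array([1, 1, 0, 0])
    assert roc_auc([4.0, 3.0, 2.0, 1.0], y).auc == 1.0
    assert roc_auc([1.0, 2.0, 3.0, 4.0], y).auc == 0.0


def test_all_tied_scores_auc_half():
    y = np.array([1, 0, 1, 0, 0])
    assert roc_auc(np.ones(5), y).auc == 0.5


def test_one_class_absent_refused():
    with pytest.raises(ValueError, match="class"):
        roc_auc([1.0, 2.0], np.array([1, 1]))


def test_curve_endpoints_and_monotone(rng):
    s = rng.normal(size=50)
    y = (rng.random(50) < 0.4).astype(int)
    y[:2] = [0, 1]
    res = roc_auc(s, y)
    assert res.fpr[0] == 0 and res.tpr[0] == 0
    assert res.fpr[-1] == 1 and res.tpr[-1] == 1
    assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()
    # stored AUC is the trapezoidal area of the stored curve
    assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr), abs=1e-12)


def test_auc_equals_bruteforce_counting(rng):
    """Exhaustive concordant-pair oracle on random small instances with ties."""
    for _ in range(200):
        n = int(rng.integers(4, 21))
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            continue
        s = (rng.integers(0, 4, n).astype(float) if rng.random() < 0.5
             else rng.normal(size=n))
        assert abs(roc_auc(s, y).auc - auc_bruteforce(s, y)) < 1e-12


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=4, max_size=30),
       st.integers(0, 2 ** 31 - 1))
def test_auc_complement_and_monotone_invariance(scores, seed):
    scores = np.asarray(scores)
    rng = np.random.default_rng(seed)
    y = np.zeros(len(scores), dtype=int)
    y[: max(1, len(scores) // 3)] = 1
    rng.shuffle(y)
    a = roc_auc(scores, y).auc
    assert roc_auc(-scores, y).auc == pytest.approx(1 - a, abs=1e-12)
    # strictly increasing transform preserves the ranking hence the AUC
    # (scaling by a power of two is exact, so no two scores can collapse)
    assert roc_auc(4.0 * scores, y).auc == pytest.approx(a, abs=1e-12)


# -------------------------------------------------------------------- splits

def test_split_is_stratified_and_deterministic():
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(20)],
        "label": ["case"] * 10 + ["control"] * 10,
    })
    plan = random_split(meta, fraction=0.5, seed=42)
    assert len(plan.train_ids) == 10 and len(plan.test_ids) == 10
    labels = meta.set_index("sample_id")["label"]
    assert sum(labels[s] == "case" for s in plan.train_ids) == 5
    assert sorted(plan.train_ids + plan.test_ids) == sorted(meta["sample_id"])
    again = random_split(meta, fraction=0.5, seed=42)
    assert again.train_ids == plan.train_ids and again.test_ids == plan.test_ids


def test_split_uniformity_over_seeds():
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(40)],
        "label": ["case"] * 20 + ["control"] * 20,
    })
    counts = {s: 0 for s in meta["sample_id"]}
    for seed in range(1000):
        plan = random_split(meta, fraction=0.5, seed=seed)
        for s in plan.train_ids:
            counts[s] += 1
    assert all(400 <= c <= 600 for c in counts.values())


def test_split_refuses_tiny_class():
    meta = pd.DataFrame({"sample_id": ["a", "b", "c"],
                         "label": ["case", "control", "control"]})
    with pytest.raises(ValueError, match="stratify"):
        random_split(meta, fraction=0.5, seed=0)


# ----------------------------------------------------------------- subgroups

def _fitted(default_cohort):
    _, expr, meta, truth, y = default_cohort
    pairs = [tuple(p) for p in truth["planted_pairs"]]
    X = build_pair_matrix(expr).X()[[pair_id(*p) for p in pairs]]
    clf = PairPanelClassifier(pairs=pairs, algorithm="logistic").fit(X, y)
    return clf, X, meta, y


def test_accept_all_filter_equals_whole_cohort(default_cohort):
    clf, X, meta, y = _fitted(default_cohort)
    whole = roc_auc(clf.decision_function(X), y)
    sub = evaluate_subgroup(clf, X, meta, lambda stage: True)
    assert sub.auc == whole.auc
    assert (sub.n_case, sub.n_control) == (whole.n_case, whole.n_control)


def test_single_case_subgroup_degenerate_but_valid(default_cohort):
    clf, X, meta, y = _fitted(default_cohort)
    target = meta.loc[meta["label"] == "case", "sample_id"].iloc[0]
    one_meta = meta.copy()
    # keep exactly one case by tagging it with a unique stage value
    one_meta.loc[one_meta["label"] == "case", "stage"] = "advanced"
    one_meta.loc[one_meta["sample_id"] == target, "stage"] = "early"
    res = evaluate_subgroup(clf, X, one_meta, lambda s: s == "early")
    assert res.n_case == 1
    # with one case, AUC lies on the grid k/(2*n_control)
    assert (res.auc * 2 * res.n_control) == pytest.approx(
        round(res.auc * 2 * res.n_control), abs=1e-9)


def test_empty_case_filter_refused(default_cohort):
    clf, X, meta, y = _fitted(default_cohort)
    with pytest.raises(ValueError, match="case"):
        evaluate_subgroup(clf, X, meta, lambda s: False)


def test_advanced_subgroup_outperforms_early():
    """Stage-attenuated effects: advanced-case AUC beats early-case AUC in
    most replicates."""
    wins = 0
    n_rep = 10
    for seed in range(n_rep):
        cfg = SimConfig(early_attenuation=0.4, stage_fraction_early=0.5,
                        seed=500 + seed)
        expr, meta, truth = simulate_cohort(cfg)
        y = labels_for(expr.sample_ids, meta)
        pairs = [tuple(p) for p in truth["planted_pairs"]]
        X = build_pair_matrix(expr).X()[[pair_id(*p) for p in pairs]]
        clf = PairPanelClassifier(pairs=pairs, algorithm="logistic").fit(X, y)
        early = evaluate_subgroup(clf, X, meta, lambda s: s == "early").auc
        adv = evaluate_subgroup(clf, X, meta, lambda s: s == "advanced").auc
        wins += adv >= early
    assert wins >= 0.8 * n_rep
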