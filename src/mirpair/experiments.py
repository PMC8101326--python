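"""Reproducible validation experiments over the synthetic test bed.

Each function runs one self-contained study — combinatorial identity,
offset-invariance, oracle equivalence, planted-signal recovery,
cross-platform transfer, null calibration — and returns plain numbers.
They are shared by the test suite and by ``scripts/acceptance.py`` so both
exercise the exact same code paths. Oracles (brute-force AUC counting, the
generic convex solver for the L1 path) are implemented here independently
of the production routines they check.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np
from scipy.optimize import minimize

from .classifiers import PairPanelClassifier
from .diffexpr import moderated_t
from .evaluation import random_split, roc_auc
from .io import ExpressionMatrix, labels_for
from .pairing import build_pair_matrix, ct_pair_features, pair_id, screen_logistic, univariate_screen
from .selection import _standardize, extract_nested_panel, fit_lasso_path, l1_objective
from .simulate import SimConfig, quantize, render_ct, simulate_cohort


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


# ---------------------------------------------------------------- pair count
def pair_count_timing(n_mirna: int = 387, n_samples: int = 20, seed: int = 0):
    """Build all pairs of ``n_mirna`` miRNAs; returns (n_pairs, seconds)."""
    rng = np.random.default_rng(seed)
    import pandas as pd
    frame = pd.DataFrame(
        rng.normal(8, 2, size=(n_mirna, n_samples)),
        index=[f"miR-{i:04d}" for i in range(n_mirna)],
        columns=[f"s{j:03d}" for j in range(n_samples)])
    expr = ExpressionMatrix(frame, "log2")
    t0 = time.perf_counter()
    pm = build_pair_matrix(expr)
    elapsed = time.perf_counter() - t0
    return pm.n_pairs, elapsed


# ------------------------------------------------------- offset invariance
def offset_invariance(n_offsets: int = 50, seed: int = 0):
    """Per-sample offsets (up to ±10 log2) applied to the raw matrix.

    Returns a dict with the max absolute deviation of the pair matrix and
    of end-to-end model scores across ``n_offsets`` offset draws (0.0 means
    bit-identical). Offsets lie on the simulator's quantization grid so the
    cancellation is exact in binary64.
    """
    cfg = SimConfig(seed=seed)
    expr, meta, truth = simulate_cohort(cfg)
    y = labels_for(expr.sample_ids, meta)
    pm0 = build_pair_matrix(expr)
    base = pm0.values.to_numpy()

    planted = [tuple(p) for p in truth["planted_pairs"]]
    cols = [pair_id(*p) for p in planted]
    X0 = pm0.X()[cols]
    clf = PairPanelClassifier(pairs=planted, algorithm="logistic").fit(X0, y)
    svm = PairPanelClassifier(pairs=planted, algorithm="svm").fit(X0, y)
    s0 = clf.decision_function(X0)
    v0 = svm.decision_function(X0)

    rng = np.random.default_rng(seed + 1)
    max_dev = 0.0
    max_score_dev = 0.0
    identical = True
    for _ in range(n_offsets):
        off = quantize(rng.uniform(-10, 10, size=expr.shape[1]), cfg.quantum)
        shifted = ExpressionMatrix(expr.values + off[None, :], "log2")
        pm = build_pair_matrix(shifted)
        arr = pm.values.to_numpy()
        identical &= np.array_equal(arr, base)
        max_dev = max(max_dev, float(np.max(np.abs(arr - base))))
        Xs = pm.X()[cols]
        max_score_dev = max(
            max_score_dev,
            float(np.max(np.abs(clf.decision_function(Xs) - s0))),
            float(np.max(np.abs(svm.decision_function(Xs) - v0))))
    return {"bit_identical": identical, "max_pair_deviation": max_dev,
            "max_score_deviation": max_score_dev, "n_offsets": n_offsets}


# ------------------------------------------------------------- AUC oracle
def auc_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive concordant-pair counting with half credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    cases = s[y == 1]
    ctrls = s[y == 0]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def auc_oracle_equivalence(n_instances: int = 200, seed: int = 0):
    """Max |roc_auc − brute force| over random small instances (ties included)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 21))
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[: int(rng.integers(1, n))] ] = 1
        if y.sum() == 0 or y.sum() == n:
            continue
        # half the instances use coarse scores to force ties
        if rng.random() < 0.5:
            s = rng.integers(0, 4, size=n).astype(float)
        else:
            s = rng.normal(size=n)
        got = roc_auc(s, y).auc
        worst = max(worst, abs(got - auc_bruteforce(s, y)))
    return worst


# ----------------------------------------------------------- LASSO oracle
def _l1_logistic_oracle(Xs: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Generic convex solver: split β = β⁺ − β⁻, bound-constrained L-BFGS-B."""
    n, p = Xs.shape

    def f(z):
        b = z[1:1 + p] - z[1 + p:]
        eta = z[0] + Xs @ b
        return (np.mean(np.logaddexp(0, eta) - y * eta)
                + lam * (z[1:].sum()))

    def g(z):
        b = z[1:1 + p] - z[1 + p:]
        eta = z[0] + Xs @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = (mu - y) / n
        gb = Xs.T @ r
        return np.concatenate([[r.sum()], gb + lam, -gb + lam])

    res = minimize(f, np.zeros(1 + 2 * p), jac=g, method="L-BFGS-B",
                   bounds=[(None, None)] + [(0, None)] * (2 * p),
                   options=dict(maxiter=20000, ftol=1e-16, gtol=1e-12))
    return float(res.fun)


def lasso_oracle_equivalence(n_instances: int = 50, seed: int = 0,
                             n_lambda: int = 20):
    """Max objective excess of the path solver over the convex oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(12, 41))
        p = int(rng.integers(2, 9))
        X = rng.normal(size=(n, p))
        beta = rng.normal(scale=1.0, size=p) * (rng.random(p) < 0.6)
        eta = X @ beta + rng.normal(scale=0.5, size=n)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        if y.sum() < 2 or y.sum() > n - 2:
            continue
        done += 1
        path = fit_lasso_path(X, y, n_lambda=n_lambda, lambda_min_ratio=0.05)
        Xs, _, _, _ = _standardize(X)
        for t, lam in enumerate(path.lambda_grid):
            mine = l1_objective(Xs, y, path.std_intercepts[t],
                                path.std_coefs[t], lam)
            worst = max(worst, mine - _l1_logistic_oracle(Xs, y, lam))
    return worst


# -------------------------------------------------- recovery / transfer study
def recovery_study(n_seeds: int = 20, seed: int = 0, config: SimConfig | None = None):
    """The planted-signal study under the standard conditions, one dict per seed.

    Per replicate: simulate the default cohort, split 70/30, build all
    pairwise ratio features on the training half, screen at alpha 0.05,
    fit the L1 path, extract the nested 1..4 panel, and record

    - whether both planted pairs occupy the 2-pair model,
    - whether the panel is strictly nested,
    - holdout AUC of the 4-pair SVM vs a logistic model on the single best
      raw miRNA (best by training moderated-t p-value),
    - holdout AUC of each family on chip features vs on the delta-Ct
      rendering of the same subjects (cross-platform transfer).

    The default cohort is stageless (``stage_fraction_early=0``) so every
    case carries the full planted effect — the study's stated condition;
    stage attenuation is a separate axis exercised by the subgroup
    analyses.
    """
    base = config or SimConfig(stage_fraction_early=0.0)
    out = []
    for s in _sub_seeds(seed, n_seeds):
        cfg = replace(base, seed=s)
        expr, meta, truth = simulate_cohort(cfg)
        plan = random_split(meta, fraction=0.7, seed=s)
        tr, te = plan.train_ids, plan.test_ids
        expr_tr = ExpressionMatrix(expr.values[tr], "log2")
        expr_te = ExpressionMatrix(expr.values[te], "log2")
        ytr = labels_for(tr, meta)
        yte = labels_for(te, meta)

        pm_tr = build_pair_matrix(expr_tr, labels=ytr)
        _, kept = univariate_screen(pm_tr, alpha=0.05)
        Xtr_all = kept.X()
        path = fit_lasso_path(Xtr_all, ytr)
        panel = extract_nested_panel(path, 4, X=Xtr_all, y=ytr)

        planted = {tuple(p) for p in truth["planted_pairs"]}
        two_pair = set(panel.model_of_size(min(2, max(panel.sizes))).pairs)
        recovered = planted <= two_pair

        nested = all(set(a.pairs) < set(b.pairs)
                     for a, b in zip(panel.models, panel.models[1:]))

        kmax = max(panel.sizes)
        pairs4 = panel.model_of_size(kmax).pairs
        cols4 = [pair_id(*p) for p in pairs4]
        pm_te = build_pair_matrix(expr_te)
        Xtr4, Xte4 = pm_tr.X()[cols4], pm_te.X()[cols4]

        aucs_chip = {}
        aucs_ct = {}
        lam = panel.model_of_size(kmax).lambda_
        ct = render_ct(expr, cfg)
        ct_te = ExpressionMatrix(ct.values[te], "ct")
        Xct4 = ct_pair_features(ct_te, pairs4).X()[cols4]
        for algo in ("lasso_logistic", "logistic", "random_forest", "svm"):
            clf = PairPanelClassifier(pairs=pairs4, algorithm=algo,
                                      lambda_=lam, random_state=s)
            clf.fit(Xtr4, ytr)
            aucs_chip[algo] = roc_auc(clf.decision_function(Xte4), yte).auc
            aucs_ct[algo] = roc_auc(clf.decision_function(Xct4), yte).auc

        de = moderated_t(expr_tr, ytr)
        best = de["p_value"].idxmin()
        raw_tr = expr_tr.samples_by_mirnas()[[best]]
        raw_te = expr_te.samples_by_mirnas()[[best]]
        # single-miRNA comparator: plain logistic on the raw value
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=np.inf, max_iter=5000).fit(
            raw_tr.to_numpy(), ytr)
        auc_single = roc_auc(lr.decision_function(raw_te.to_numpy()), yte).auc

        out.append({
            "seed": s,
            "recovered_both_planted": bool(recovered),
            "nested": bool(nested),
            "panel_sizes": panel.sizes,
            "auc_svm4": aucs_chip["svm"],
            "auc_single_mirna": auc_single,
            "auc_chip": aucs_chip,
            "auc_ct": aucs_ct,
        })
    return out


def summarize_recovery(study: list[dict]) -> dict:
    n = len(study)
    rec = np.mean([r["recovered_both_planted"] for r in study])
    nest = np.mean([r["nested"] for r in study])
    win = np.mean([r["auc_svm4"] > r["auc_single_mirna"] for r in study])
    algos = study[0]["auc_chip"].keys()
    loss = {a: float(np.mean([r["auc_chip"][a] - r["auc_ct"][a] for r in study]))
            for a in algos}
    return {
        "n_seeds": n,
        "recovery_rate": float(rec),
        "nesting_rate": float(nest),
        "svm_vs_single_win_rate": float(win),
        "mean_auc_svm4": float(np.mean([r["auc_svm4"] for r in study])),
        "mean_auc_single_mirna": float(np.mean([r["auc_single_mirna"] for r in study])),
        "ct_transfer_mean_auc_loss": loss,
        "ct_transfer_worst_mean_loss": float(max(loss.values())),
    }


# ---------------------------------------------------------- null calibration
def null_screen_fraction(n_pairs: int = 1000, n_samples: int = 200,
                         alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of pure-noise features kept by the univariate screen."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_pairs))
    y = np.array([1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2))
    res = screen_logistic(X, y)
    return float(np.mean(res["p_value"] < alpha))
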