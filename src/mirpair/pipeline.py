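"""End-to-end workflow: split → DE → pair → screen → path → panels → fit → ROC.

Mirrors the full biomarker-discovery sequence: the cohort is split into
training and testing halves; differentially expressed miRNAs are selected
on the training half; all pairwise log2-ratio features are built and
screened by univariate logistic association; one L1 logistic path yields
nested panels of 1..k pairs; each requested classifier family is fitted on
every panel size; models are evaluated on the held-out half and optionally
re-applied to a Ct rendering of the same subjects (cross-platform check)
and to early/advanced case subgroups.

Every stage logs its input/output shapes; the run log records all
effective parameters and seeds so a run can be reproduced exactly. Summary
JSON files contain no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, io, pairing, selection
from .classifiers import PairPanelClassifier, augment_covariates
from .evaluation import evaluate_subgroup, random_split, roc_auc

logger = logging.getLogger("mirpair")

ALL_ALGORITHMS = ("lasso_logistic", "logistic", "random_forest", "svm")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    expression_path: str | None = None
    metadata_path: str | None = None
    ct_path: str | None = None
    out_dir: str = "mirpair_out"
    de_alpha: float = 0.05
    min_abs_lfc: float = 0.0
    candidate_mirnas: str = "de"        # "de" or "all"
    min_candidates: int = 4             # DE fallback: top-N by p if fewer pass
    screen_alpha: float = 0.05
    k_max: int = 4
    algorithms: tuple[str, ...] = ALL_ALGORITHMS
    split_fraction: float = 0.7
    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    covariates: tuple[str, ...] = ()
    subgroup: bool = False

    def __post_init__(self) -> None:
        for name in ("de_alpha", "screen_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        unknown = set(self.algorithms) - set(ALL_ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
        if self.candidate_mirnas not in ("de", "all"):
            raise ValueError("candidate_mirnas must be 'de' or 'all'")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _pair_columns(expr: io.ExpressionMatrix, pairs) -> pd.DataFrame:
    """Samples x pairs frame holding only the requested pair features."""
    v = expr.values
    data = {pairing.pair_id(a, b): v.loc[a].to_numpy() - v.loc[b].to_numpy()
            for a, b in pairs}
    return pd.DataFrame(data, index=expr.sample_ids)


def run_pipeline(config: PipelineConfig,
                 expr: io.ExpressionMatrix | None = None,
                 meta: pd.DataFrame | None = None,
                 ct: io.ExpressionMatrix | None = None) -> dict:
    """Execute the full workflow; returns the report bundle as a dict.

    Inputs may be passed in memory or read from the configured paths.
    Outputs (models, scores, ROC summaries, run log) are written under
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"parameters": asdict(config), "stages": [], "warnings": []}

    @_stage("load")
    def load():
        e = expr if expr is not None else io.read_expression_matrix(
            config.expression_path, scale_tag="log2")
        m = meta if meta is not None else io.read_metadata(config.metadata_path)
        m = io.validate_metadata(m.copy())
        c = ct
        if c is None and config.ct_path:
            c = io.read_expression_matrix(config.ct_path, scale_tag="ct")
        return e, m, c

    expr_m, meta_m, ct_m = load()
    run_log["stages"].append({"stage": "load", "n_mirna": expr_m.shape[0],
                              "n_samples": expr_m.shape[1]})

    @_stage("split")
    def split():
        return random_split(meta_m, fraction=config.split_fraction, seed=config.seed)

    plan = split()
    y_all = io.labels_for(expr_m.sample_ids, meta_m)
    train_cols = [s for s in expr_m.sample_ids if s in set(plan.train_ids)]
    test_cols = [s for s in expr_m.sample_ids if s in set(plan.test_ids)]
    expr_train = io.ExpressionMatrix(expr_m.values[train_cols], "log2")
    expr_test = io.ExpressionMatrix(expr_m.values[test_cols], "log2")
    y_train = io.labels_for(train_cols, meta_m)
    y_test = io.labels_for(test_cols, meta_m)
    run_log["stages"].append({"stage": "split", "n_train": len(train_cols),
                              "n_test": len(test_cols)})

    @_stage("de")
    def de():
        table = diffexpr.moderated_t(expr_train, y_train)
        if config.candidate_mirnas == "all":
            chosen = list(table.sort_values("p_value", kind="stable").index)
        else:
            chosen = diffexpr.select_de(table, config.de_alpha, config.min_abs_lfc)
            if len(chosen) < max(2, config.min_candidates):
                run_log["warnings"].append(
                    f"only {len(chosen)} miRNA(s) pass the DE screen at "
                    f"alpha={config.de_alpha}; falling back to the top "
                    f"{config.min_candidates} by p-value")
                chosen = list(table.sort_values("p_value", kind="stable")
                              .head(config.min_candidates).index)
        return table, chosen

    de_table, de_mirnas = de()
    de_table.to_csv(out_dir / "de_table.tsv", sep="\t", index_label="mirna_id")
    run_log["stages"].append({"stage": "de", "n_de": len(de_mirnas)})

    @_stage("pair")
    def pair():
        return pairing.build_pair_matrix(expr_train, de_mirnas, labels=y_train)

    pm_train = pair()
    run_log["stages"].append({"stage": "pair", "n_pairs": pm_train.n_pairs})

    @_stage("screen")
    def screen():
        return pairing.univariate_screen(pm_train, alpha=config.screen_alpha)

    screen_table, pm_kept = screen()
    screen_table.to_csv(out_dir / "screen.tsv", sep="\t", index_label="pair_id")
    run_log["stages"].append({"stage": "screen", "n_kept": pm_kept.n_pairs})
    if pm_kept.n_pairs < 1:
        raise StageError("screen", ValueError("no pair survives the univariate screen"))

    @_stage("select")
    def select():
        X = pm_kept.X()
        path = selection.fit_lasso_path(
            X, y_train, n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio)
        panel = selection.extract_nested_panel(path, config.k_max, X=X, y=y_train)
        return path, panel

    path, panel = select()
    path.diagnostics().to_csv(out_dir / "path_diagnostics.tsv", sep="\t", index=False)
    (out_dir / "panel.json").write_text(json.dumps(
        [m.to_dict() for m in panel.models], indent=2) + "\n")
    for w in panel.warnings:
        run_log["warnings"].append(f"select: {w}")
    run_log["stages"].append({"stage": "select", "panel_sizes": panel.sizes})

    panel_pairs = sorted({p for m in panel.models for p in m.pairs})
    features_train_all = _pair_columns(expr_train, panel_pairs)
    features_test_all = _pair_columns(expr_test, panel_pairs)
    if config.covariates:
        age_stats = None
        if "age" in config.covariates:
            ages = meta_m.set_index("sample_id").loc[train_cols, "age"]
            age_stats = (float(ages.mean()), float(ages.std(ddof=0)))
        features_train_all = augment_covariates(
            features_train_all, meta_m, config.covariates,
            age_center=age_stats[0] if age_stats else None,
            age_scale=age_stats[1] if age_stats else None)
        features_test_all = augment_covariates(
            features_test_all, meta_m, config.covariates,
            age_center=age_stats[0] if age_stats else None,
            age_scale=age_stats[1] if age_stats else None)

    @_stage("fit_eval")
    def fit_eval():
        models_dir = out_dir / "models"
        models_dir.mkdir(exist_ok=True)
        results = []
        fitted = {}
        for model in panel.models:
            k = len(model.pairs)
            cols = [pairing.pair_id(*p) for p in model.pairs] + list(config.covariates)
            Xtr = features_train_all[cols]
            Xte = features_test_all[cols]
            for algo in config.algorithms:
                clf = PairPanelClassifier(
                    pairs=model.pairs, algorithm=algo,
                    lambda_=model.lambda_, covariates=config.covariates,
                    random_state=config.seed)
                clf.fit(Xtr, y_train)
                fitted[(k, algo)] = clf
                mf = clf.to_model_file()
                io.write_model(mf, models_dir / f"model_k{k}_{algo}.json")
                scores_tr = clf.decision_function(Xtr)
                scores_te = clf.decision_function(Xte)
                roc_tr = roc_auc(scores_tr, y_train)
                roc_te = roc_auc(scores_te, y_test)
                pd.DataFrame({"sample_id": test_cols, "score": scores_te,
                              "label": y_test}).to_csv(
                    out_dir / f"scores_k{k}_{algo}.tsv", sep="\t", index=False)
                roc_te.to_frame().to_csv(
                    out_dir / f"roc_k{k}_{algo}.tsv", sep="\t", index=False)
                entry = {"k": k, "algorithm": algo,
                         "auc_train": roc_tr.auc, "auc_test": roc_te.auc,
                         "lambda": model.lambda_}
                if config.subgroup and meta_m["stage"].notna().any():
                    te_meta = meta_m[meta_m["sample_id"].isin(test_cols)]
                    for name, pred in (("early", lambda s: s == "early"),
                                       ("advanced", lambda s: s == "advanced")):
                        try:
                            sub = evaluate_subgroup(clf, Xte, te_meta, pred)
                            entry[f"auc_test_{name}"] = sub.auc
                        except ValueError:
                            entry[f"auc_test_{name}"] = None
                results.append(entry)
        return results, fitted

    results, fitted = fit_eval()

    ct_results = []
    if ct_m is not None:
        @_stage("ct_eval")
        def ct_eval():
            out = []
            for model in panel.models:
                k = len(model.pairs)
                pm_ct = pairing.ct_pair_features(ct_m, model.pairs)
                Xct = pm_ct.X().loc[[s for s in test_cols
                                     if s in pm_ct.values.columns]]
                if config.covariates:
                    Xct = augment_covariates(
                        Xct, meta_m, config.covariates,
                        age_center=age_stats[0] if age_stats else None,
                        age_scale=age_stats[1] if age_stats else None)
                y_ct = io.labels_for(list(Xct.index), meta_m)
                for algo in config.algorithms:
                    clf = fitted[(k, algo)]
                    scores = clf.decision_function(
                        Xct[list(clf.feature_names_in_)])
                    out.append({"k": k, "algorithm": algo,
                                "auc_ct": roc_auc(scores, y_ct).auc})
            return out

        ct_results = ct_eval()

    report = {"results": results, "ct_results": ct_results,
              "panel_sizes": panel.sizes,
              "entry_order": path.entry_order[:config.k_max],
              "split": plan.to_dict(), "warnings": run_log["warnings"]}
    (out_dir / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out_dir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    return report
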