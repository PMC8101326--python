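"""ROC/AUC computation, stratified cohort splitting, subgroup evaluation.

AUC is the tie-aware Mann–Whitney statistic — the probability that a random
case scores above a random control, with half credit for ties — and is
stored as the trapezoidal area of the enumerated ROC curve, which equals
the U statistic identically. Splits are stratified by class and
deterministic given a seed, mirroring a train/test division "by random
number".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "roc_auc", "random_split", "evaluate_subgroup", "SplitPlan"]


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_case: int
    n_control: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})

    def summary(self) -> dict:
        return {"auc": self.auc, "n_case": self.n_case, "n_control": self.n_control}


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC (higher score = case) with ½-credit tie handling.

    The curve is enumerated at every distinct score threshold (no
    interpolation), so its trapezoidal area is exactly the normalized
    Mann–Whitney U statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_case = int((y == 1).sum())
    n_control = int((y == 0).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be present to draw a ROC curve")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
                     n_case=n_case, n_control=n_control)


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    fraction: float

    def to_dict(self) -> dict:
        return {"train_ids": list(self.train_ids), "test_ids": list(self.test_ids),
                "seed": self.seed, "fraction": self.fraction}


def random_split(meta: pd.DataFrame, fraction: float = 0.7, seed: int = 0) -> SplitPlan:
    """Stratified-by-class random train/test split, deterministic given seed.

    ``fraction`` is the training share within each class (rounded). Both
    halves must end up with at least one sample of each class.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for label in ("control", "case"):
        ids = meta.loc[meta["label"] == label, "sample_id"].tolist()
        n_train = int(round(fraction * len(ids)))
        if n_train < 1 or len(ids) - n_train < 1:
            raise ValueError(
                f"class {label!r} too small ({len(ids)}) to stratify at "
                f"fraction {fraction}")
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in sorted(perm[:n_train]))
        test.extend(ids[i] for i in sorted(perm[n_train:]))
    return SplitPlan(train_ids=train, test_ids=test, seed=seed, fraction=fraction)


def evaluate_subgroup(model, features: pd.DataFrame, meta: pd.DataFrame,
                      case_filter) -> RocResult:
    """ROC over {cases passing ``case_filter(stage)``} ∪ {all controls}.

    ``case_filter`` receives each case's stage value (may be NaN) and
    returns True to retain the case. All controls are always retained.
    """
    lookup = meta.set_index("sample_id")
    keep = []
    for sid in features.index:
        row = lookup.loc[sid]
        if row["label"] == "control":
            keep.append(sid)
        elif case_filter(row.get("stage")):
            keep.append(sid)
    sub = features.loc[keep]
    y = (lookup.loc[keep, "label"] == "case").astype(int).to_numpy()
    if (y == 1).sum() == 0:
        raise ValueError("case_filter removed every case")
    scores = model.decision_function(sub)
    return roc_auc(scores, y)
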