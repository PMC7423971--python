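"""Case/control classification from the V-J matrix.

Random-forest leave-one-out cross validation: each sample's case
probability comes from a forest trained on all other samples; pooled
out-of-fold probabilities give the ROC/AUC (Mann-Whitney form, ties count
one half), with a stratified percentile bootstrap for the confidence
interval and impurity-based variable importance averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .compare import VJMatrix


@dataclass
class RandomForestConfig:
    n_trees: int = 500
    max_features: str | float = "sqrt"  # mtry = sqrt(p), the R randomForest default


@dataclass
class LoocvResult:
    predictions: pd.DataFrame  # sample_id, group, label, oof_probability, oof_score
    auc: float
    ci_low: float
    ci_high: float
    importance: pd.Series  # combination -> mean impurity importance across folds
    seed: int
    config: RandomForestConfig = field(default_factory=RandomForestConfig)


def roc_auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_bootstrap_ci(
    scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = pos[rng.integers(0, len(pos), len(pos))]
        ns = neg[rng.integers(0, len(neg), len(neg))]
        aucs[b] = roc_auc(
            np.concatenate([ps, ns]),
            np.concatenate([np.ones(len(ps), int), np.zeros(len(ns), int)]),
        )
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return float(lo), float(hi)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """FPR/TPR pairs at every threshold (descending score)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last point of each tied-score run
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[keep] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[keep] / max(fps[-1], 1)]
    thr = np.r_[np.inf, s[keep]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def loocv_classify(
    m: VJMatrix,
    config: RandomForestConfig | None = None,
    seed: int = 0,
    n_boot: int = 2000,
    case_label: str = "case",
) -> LoocvResult:
    """Leave-one-out random-forest classification of the V-J matrix.

    Requires >= 3 samples per group. Per-fold forests are seeded
    deterministically from ``seed``; the result is reproducible bit-for-bit.

    Pooled LOOCV probabilities carry a stratification artifact: removing a
    case leaves the training fold case-poor, which systematically deflates
    case probabilities (and vice versa), biasing the pooled null AUC well
    below 0.5. The ROC is therefore computed on prevalence-centered scores
    (out-of-fold probability minus the training fold's case fraction) — a
    quantity known before the held-out sample is examined, so out-of-fold
    discipline is preserved. Raw probabilities are reported alongside.
    """
    config = config or RandomForestConfig()
    x = m.values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    y = (m.groups == case_label).to_numpy().astype(int)
    n = len(y)
    if min(int(y.sum()), int(n - y.sum())) < 3:
        raise ValueError("need >= 3 samples per group")
    probs = np.empty(n)
    scores = np.empty(n)
    importances = np.zeros(x.shape[1])
    fold_seeds = np.random.SeedSequence(seed).generate_state(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            random_state=int(fold_seeds[i]),
            n_jobs=1,
        )
        clf.fit(x[mask], y[mask])
        case_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        probs[i] = clf.predict_proba(x[i : i + 1])[0, case_col]
        scores[i] = probs[i] - y[mask].mean()  # center by training-fold prevalence
        importances += clf.feature_importances_
    importances /= n
    auc = roc_auc(scores, y)
    ci_low, ci_high = auc_bootstrap_ci(scores, y, n_boot=n_boot, seed=seed)
    ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    predictions = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "group": m.groups.to_numpy(),
            "label": y,
            "oof_probability": probs,
            "oof_score": scores,
        }
    )
    importance = pd.Series(importances, index=m.values.columns, name="importance")
    return LoocvResult(
        predictions=predictions,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        importance=importance,
        seed=seed,
        config=config,
    )


def signature_importance(result: LoocvResult, top_k: int = 20) -> pd.Series:
    """Top combinations by mean importance (descending, name-tiebroken)."""
    df = result.importance.reset_index()
    df.columns = ["combination", "importance"]
    df = df.sort_values(["importance", "combination"], ascending=[False, True])
    top = df.head(top_k)
    return pd.Series(top["importance"].to_numpy(), index=top["combination"].to_numpy())
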