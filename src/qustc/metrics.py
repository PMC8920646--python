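"""Validation schemes, ROC/AUC metrics and rank-sum feature screening.

Cross-validation pools out-of-fold scores and computes a single ROC/AUC and
confusion matrix on the pooled predictions (micro-averaging).  The 95 % AUC
confidence interval is a stratified bootstrap over the pooled scores.  The
rank-sum screen applies the two-sided Wilcoxon rank-sum test per feature
(exact enumeration for tiny tie-free groups, normal approximation with tie
correction otherwise) and maps p-values to the significance tiers
``~`` (p >= 0.05), ``*`` (p < 0.05) and ``**`` (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split

from .classifiers import predict_scores

__all__ = ["EvalReport", "compute_metrics", "cross_validate", "rank_sum_screen"]


@dataclass
class EvalReport:
    """Pooled classification metrics for one (classifier, scheme) run."""

    accuracy: float  # percent
    sensitivity: float  # percent, on the malignant (positive) class
    specificity: float  # percent
    auc: float
    auc_ci: tuple[float, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    tp: int
    fn: int
    tn: int
    fp: int
    scheme: str = ""
    seed: int | None = None
    n_fits: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must be in [0, 1]")
        if np.any(np.diff(self.roc_fpr) < 0) or np.any(np.diff(self.roc_tpr) < 0):
            raise ValueError("ROC points must be monotone nondecreasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_fpr"] = np.asarray(self.roc_fpr).tolist()
        d["roc_tpr"] = np.asarray(self.roc_tpr).tolist()
        d["auc_ci"] = list(self.auc_ci)
        return d


def compute_metrics(
    y_true,
    scores,
    y_pred=None,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
    scheme: str = "",
    n_fits: int = 0,
) -> EvalReport:
    """ROC/AUC plus confusion metrics on pooled predictions.

    ``y_pred`` are the classifiers' hard labels at their natural threshold;
    when absent, scores are thresholded at ``threshold``.  The AUC CI is a
    seeded stratified bootstrap (``n_boot`` replicates, percentile 2.5/97.5).
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true must contain both classes")
    if y_pred is None:
        y_pred = (scores >= threshold).astype(int)
    y_pred = np.asarray(y_pred).astype(int)

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))

    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(roc_auc_score(y_true, scores))

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y_true == 1)
    neg = np.flatnonzero(y_true == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True),
             rng.choice(neg, len(neg), replace=True)]
        )
        boot[b] = roc_auc_score(y_true[idx], scores[idx])
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    return EvalReport(
        accuracy=100.0 * (tp + tn) / len(y_true),
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        auc=auc,
        auc_ci=ci,
        roc_fpr=fpr,
        roc_tpr=tpr,
        tp=tp, fn=fn, tn=tn, fp=fp,
        scheme=scheme, seed=seed, n_fits=n_fits,
    )


def _splits(scheme: str, X, y, seed: int, n_splits: int, train_fraction: float):
    n = len(y)
    if scheme == "holdout":
        tr, te = train_test_split(
            np.arange(n), train_size=train_fraction, stratify=y, random_state=seed
        )
        return [(tr, te)]
    if scheme == "kfold":
        counts = np.bincount(np.asarray(y).astype(int))
        if counts[counts > 0].min() < n_splits:
            raise ValueError(
                f"each class needs >= {n_splits} members for {n_splits}-fold "
                f"stratified CV, got counts {counts.tolist()}"
            )
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return list(cv.split(X, y))
    if scheme == "loocv":
        return list(LeaveOneOut().split(X))
    raise ValueError(f"unknown scheme {scheme!r}")


def cross_validate(
    X,
    y,
    estimator,
    scheme: str = "kfold",
    n_splits: int = 10,
    train_fraction: float = 0.6,
    resampler=None,
    leakage_mode: str = "dataset",
    seed: int = 0,
    n_boot: int = 2000,
) -> EvalReport:
    """Evaluate a classifier under holdout / stratified k-fold / LOOCV.

    ``leakage_mode="dataset"`` resamples the full dataset before splitting
    (common in applied studies, but it leaks synthetic samples into test
    folds); ``"fold"`` resamples inside each training fold only, keeping
    test folds untouched.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    if leakage_mode not in ("dataset", "fold"):
        raise ValueError("leakage_mode must be 'dataset' or 'fold'")
    if resampler is not None and leakage_mode == "dataset":
        import warnings

        warnings.warn(
            "resampling the full dataset before cross-validation leaks synthetic "
            "samples into test folds; use leakage_mode='fold' for unbiased "
            "estimates",
            UserWarning,
            stacklevel=2,
        )
        res = resampler.fit_resample(X, y)
        X, y = res.X, res.y

    pooled_scores = np.empty(len(y))
    pooled_pred = np.empty(len(y), dtype=int)
    n_fits = 0
    for tr, te in _splits(scheme, X, y, seed, n_splits, train_fraction):
        X_tr, y_tr = X[tr], y[tr]
        if resampler is not None and leakage_mode == "fold":
            res = resampler.fit_resample(X_tr, y_tr)
            X_tr, y_tr = res.X, res.y
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"a class is absent from a training fold of size {len(tr)}")
        model = clone(estimator).fit(X_tr, y_tr)
        pooled_scores[te] = predict_scores(model, X[te])
        pooled_pred[te] = model.predict(X[te])
        n_fits += 1

    if scheme == "holdout":
        # metrics on the single held-out test set
        te = _splits("holdout", X, y, seed, n_splits, train_fraction)[0][1]
        return compute_metrics(
            y[te], pooled_scores[te], pooled_pred[te], seed=seed,
            scheme=f"holdout({train_fraction:.2f})", n_fits=n_fits, n_boot=n_boot,
        )
    label = f"kfold({n_splits})" if scheme == "kfold" else "loocv"
    return compute_metrics(
        y, pooled_scores, pooled_pred, seed=seed, scheme=label, n_fits=n_fits,
        n_boot=n_boot,
    )


def rank_sum_screen(benign: pd.DataFrame, malignant: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per feature with significance tiers.

    Uses exact enumeration when the pooled group size is <= 12 and tie-free,
    otherwise the normal approximation with tie correction.  Returns a frame
    indexed by feature with columns ``p`` and ``tier``.
    """
    if benign.shape[0] < 2 or malignant.shape[0] < 2:
        raise ValueError("both groups need at least 2 members")
    if list(benign.columns) != list(malignant.columns):
        raise ValueError("group tables must share identical columns")
    rows = {}
    for col in benign.columns:
        x = np.asarray(benign[col], dtype=float)
        y = np.asarray(malignant[col], dtype=float)
        pooled = np.concatenate([x, y])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= 12 and tie_free) else "asymptotic"
        p = float(
            scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        )
        tier = "**" if p < 0.001 else ("*" if p < 0.05 else "~")
        rows[col] = {"p": p, "tier": tier}
    return pd.DataFrame.from_dict(rows, orient="index")
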