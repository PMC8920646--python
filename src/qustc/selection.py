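"""Sequential forward selection with a misclassification-rate criterion.

Greedy wrapper search: starting from the empty set, each round evaluates
every remaining feature joined to the current subset with cross-validated
misclassification of the wrapped classifier, and accepts the best candidate
only if it *strictly* lowers the criterion; ties between candidates break
toward the lower feature index.  The search stops at the first round with no
improvement (or when all features are selected), so the accepted criterion
sequence is strictly decreasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = ["SFSTrace", "SequentialForwardSelector", "sequential_forward_selection"]


@dataclass
class SFSTrace:
    """Accepted features, criterion after each acceptance, and the full log."""

    selected: list[int]
    selected_names: list[str]
    criteria: list[float]
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("accepted features must be unique")
        if any(b >= a for a, b in zip(self.criteria, self.criteria[1:])):
            raise ValueError("criterion must be strictly decreasing across steps")


class SequentialForwardSelector(BaseEstimator):
    """Greedy forward feature selector wrapping any sklearn classifier.

    Parameters
    ----------
    estimator
        Classifier to evaluate subsets with (cloned per evaluation).
    cv
        Maximum number of stratified folds for the inner misclassification
        estimate (reduced to the smaller class count when necessary).
    random_state
        Seed for the inner fold shuffling (fixed across candidate
        evaluations so subsets are compared on identical folds).

    Attributes
    ----------
    support_ : boolean mask of selected features
    selected_idx_ : list of selected feature indices, in acceptance order
    selected_names_ : matching names when the input is a DataFrame
    trace_ : :class:`SFSTrace`
    """

    def __init__(self, estimator, cv: int = 10, random_state: int = 0):
        self.estimator = estimator
        self.cv = cv
        self.random_state = random_state

    def _criterion(self, X, y, cols) -> float:
        counts = np.bincount(y)
        n_splits = min(self.cv, counts[counts > 0].min())
        if n_splits < 2:
            raise ValueError("each class needs >= 2 members for the inner CV")
        cvgen = StratifiedKFold(
            n_splits=int(n_splits), shuffle=True, random_state=self.random_state
        )
        # a subset the classifier cannot be fit on (e.g. zero-variance
        # features under a Mahalanobis metric) scores as fully misclassified
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acc = cross_val_score(
                    clone(self.estimator), X[:, cols], y, cv=cvgen, error_score=0.0
                )
        except ValueError:
            # every fold failed to fit (sklearn raises rather than scoring)
            return 1.0
        return float(1.0 - acc.mean())

    def fit(self, X, y):
        names = list(X.columns) if hasattr(X, "columns") else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("labels are degenerate (single class)")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        y = y.astype(int)

        remaining = list(range(X.shape[1]))
        selected: list[int] = []
        criteria: list[float] = []
        log: list[dict] = []
        best = np.inf
        while remaining:
            cand_crit = [self._criterion(X, y, selected + [c]) for c in remaining]
            log.append(
                {"subset": list(selected),
                 "candidates": dict(zip(remaining, cand_crit))}
            )
            # ties break toward the lower feature index: remaining is sorted
            # ascending and argmin returns the first minimum
            pick = int(np.argmin(cand_crit))
            if cand_crit[pick] < best:
                best = cand_crit[pick]
                selected.append(remaining.pop(pick))
                criteria.append(best)
            else:
                break

        self.n_features_in_ = X.shape[1]
        self.selected_idx_ = selected
        self.selected_names_ = (
            [names[i] for i in selected] if names is not None
            else [str(i) for i in selected]
        )
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[selected] = True
        self.trace_ = SFSTrace(
            selected=selected, selected_names=self.selected_names_,
            criteria=criteria, log=log,
        )
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if hasattr(X, "columns"):
            return X.iloc[:, self.selected_idx_]
        return np.asarray(X)[:, self.selected_idx_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def sequential_forward_selection(
    X, y, estimator, cv: int = 10, seed: int = 0
) -> SFSTrace:
    """Functional wrapper returning just the :class:`SFSTrace`."""
    sel = SequentialForwardSelector(estimator, cv=cv, random_state=seed).fit(X, y)
    return sel.trace_
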