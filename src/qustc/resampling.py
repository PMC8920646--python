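"""SMOTE oversampling, Tomek-link undersampling and their hybrid.

All neighbor searches use Euclidean distance on z-scored features (the 16
descriptors span several orders of magnitude); synthetic samples are
constructed in the original feature space.

* **SMOTE** draws each synthetic minority sample on the segment between a
  minority sample (cycled round-robin) and one of its T = 5 nearest minority
  neighbors, at a Uniform[0, 1] position.
* **Tomek links** are mutual-nearest-neighbor pairs of opposite classes; in
  undersampler mode the majority member of each link is removed.
* **SMOTE-Tomek** (default order) first removes majority members of Tomek
  links, then SMOTEs the minority up to the reduced majority count, leaving
  the classes exactly balanced.  The alternative order (SMOTE first, Tomek
  as post-hoc cleaning) is available via ``order="smote_first"``.

Estimator classes follow the ``fit_resample`` idiom; module functions are
thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ResampleResult",
    "SMOTE",
    "TomekLinks",
    "SMOTETomek",
    "smote",
    "tomek_links",
    "smote_tomek",
]


@dataclass
class ResampleResult:
    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # "original" | "synthetic" per row
    removed_indices: np.ndarray  # indices (into the input) removed by Tomek
    seed: int | None = None

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _zscore(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd


def _minority_majority(y: np.ndarray) -> tuple[int, int]:
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) != 2:
        raise ValueError(f"need exactly two classes, got {vals}")
    order = np.argsort(counts)
    return int(vals[order[0]]), int(vals[order[1]])


class SMOTE(BaseEstimator):
    """Synthetic minority oversampling by nearest-neighbor interpolation.

    Parameters
    ----------
    n_neighbors
        T, the number of minority nearest neighbors candidates (default 5).
    target_count
        Desired minority count after oversampling; ``None`` balances to the
        majority count.
    random_state
        Seed for neighbor choice and interpolation positions.
    """

    def __init__(self, n_neighbors: int = 5, target_count: int | None = None,
                 random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.target_count = target_count
        self.random_state = random_state

    def fit_resample(self, X, y) -> ResampleResult:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        minority, majority = _minority_majority(y)
        min_idx = np.flatnonzero(y == minority)
        d = len(min_idx)
        if d < 2:
            raise ValueError("minority class must have at least 2 members")
        target = self.target_count
        if target is None:
            target = int(np.sum(y == majority))
        if target < d:
            raise ValueError(f"target_count {target} below minority count {d}")
        t_eff = self.n_neighbors
        if t_eff > d - 1:
            warnings.warn(
                f"T={self.n_neighbors} exceeds minority size - 1; reduced to {d - 1}",
                UserWarning, stacklevel=2,
            )
            t_eff = d - 1
        n_syn = target - d
        if n_syn == 0:
            return ResampleResult(
                X=X.copy(), y=y.copy(),
                provenance=np.full(len(y), "original"),
                removed_indices=np.array([], dtype=int), seed=self.random_state,
            )

        Z = _zscore(X)
        nn = NearestNeighbors(n_neighbors=t_eff + 1).fit(Z[min_idx])
        _, neigh = nn.kneighbors(Z[min_idx])  # first column is self
        neigh = neigh[:, 1:]

        rng = np.random.default_rng(self.random_state)
        synth = np.empty((n_syn, X.shape[1]))
        for t in range(n_syn):
            i = t % d  # round-robin over the minority samples
            j = neigh[i, rng.integers(t_eff)]
            lam = rng.uniform()
            xi = X[min_idx[i]]
            xj = X[min_idx[j]]
            synth[t] = xi + lam * (xj - xi)

        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_syn, minority, dtype=y.dtype)])
        prov = np.concatenate(
            [np.full(len(y), "original"), np.full(n_syn, "synthetic")]
        )
        return ResampleResult(
            X=X_out, y=y_out, provenance=prov,
            removed_indices=np.array([], dtype=int), seed=self.random_state,
        )


class TomekLinks(BaseEstimator):
    """Remove majority members of mutual-nearest-neighbor opposite-class pairs."""

    def fit_resample(self, X, y) -> ResampleResult:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        links = self.find_links(X, y)
        _, majority = _minority_majority(y)
        removed = sorted({i for pair in links for i in pair if y[i] == majority})
        keep = np.setdiff1d(np.arange(len(y)), removed)
        return ResampleResult(
            X=X[keep], y=y[keep],
            provenance=np.full(len(keep), "original"),
            removed_indices=np.asarray(removed, dtype=int),
        )

    @staticmethod
    def find_links(X, y) -> list[tuple[int, int]]:
        """All Tomek links as index pairs (sorted within pair)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ValueError("need exactly two classes")
        Z = _zscore(X)
        nn = NearestNeighbors(n_neighbors=2).fit(Z)
        _, idx = nn.kneighbors(Z)
        nearest = idx[:, 1]  # nearest other sample
        links = set()
        for i, j in enumerate(nearest):
            if y[i] != y[j] and nearest[j] == i:
                links.add(tuple(sorted((i, int(j)))))
        return sorted(links)


class SMOTETomek(BaseEstimator):
    """Hybrid resampler: Tomek-link undersampling then SMOTE to full balance.

    ``order="smote_first"`` instead SMOTEs to balance and then removes
    majority members of any links among the augmented data.
    """

    def __init__(self, n_neighbors: int = 5, random_state: int = 0,
                 order: str = "tomek_first"):
        self.n_neighbors = n_neighbors
        self.random_state = random_state
        self.order = order

    def fit_resample(self, X, y) -> ResampleResult:
        if self.order not in ("tomek_first", "smote_first"):
            raise ValueError("order must be 'tomek_first' or 'smote_first'")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.order == "tomek_first":
            stage1 = TomekLinks().fit_resample(X, y)
            stage2 = SMOTE(
                n_neighbors=self.n_neighbors, random_state=self.random_state
            ).fit_resample(stage1.X, stage1.y)
            return ResampleResult(
                X=stage2.X, y=stage2.y, provenance=stage2.provenance,
                removed_indices=stage1.removed_indices, seed=self.random_state,
            )
        stage1 = SMOTE(
            n_neighbors=self.n_neighbors, random_state=self.random_state
        ).fit_resample(X, y)
        stage2 = TomekLinks().fit_resample(stage1.X, stage1.y)
        keep = np.setdiff1d(np.arange(len(stage1.y)), stage2.removed_indices)
        return ResampleResult(
            X=stage2.X, y=stage2.y, provenance=stage1.provenance[keep],
            removed_indices=stage2.removed_indices, seed=self.random_state,
        )


def smote(X, y, T: int = 5, target_count: int | None = None, seed: int = 0):
    return SMOTE(n_neighbors=T, target_count=target_count,
                 random_state=seed).fit_resample(X, y)


def tomek_links(X, y):
    return TomekLinks().fit_resample(X, y)


def smote_tomek(X, y, T: int = 5, seed: int = 0, order: str = "tomek_first"):
    return SMOTETomek(n_neighbors=T, random_state=seed, order=order).fit_resample(X, y)
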