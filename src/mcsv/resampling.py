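"""Class-imbalance handling for pre-ictal (minority) vs inter-ictal windows.

Pre-ictal time is typically a small fraction of a recording (around 15:1
inter-ictal to pre-ictal), so the training set is rebalanced with one of:

* ROS  — random oversampling of the minority class with replacement;
* RUS  — random undersampling of the majority class without replacement;
* borderline-SMOTE (variant 1) — synthetic minority samples interpolated
  from minority points whose neighbourhood is majority-dominated.

All resamplers return equal class counts and never alter original rows.
They are meant to be applied to *training folds only*; row ids are carried
through so leakage can be asserted downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["LabeledDataset", "ros", "rus", "bsmote"]

PIL, IIL = 1, 0


@dataclass
class LabeledDataset:
    """Flattened feature-map windows with labels and provenance ids."""

    X: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray | None = None
    row_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same length")
        if self.row_ids is None:
            self.row_ids = np.arange(len(self.y))
        if self.patient_ids is None:
            self.patient_ids = np.zeros(len(self.y), dtype=int)

    def class_counts(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(*np.unique(self.y, return_counts=True))}

    def _take(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.X[idx], self.y[idx], np.asarray(self.patient_ids)[idx], np.asarray(self.row_ids)[idx]
        )


def _split_classes(data: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    counts = data.class_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present for resampling")
    minority = min(counts, key=counts.get)  # ties resolve to the smaller label
    min_idx = np.nonzero(data.y == minority)[0]
    maj_idx = np.nonzero(data.y != minority)[0]
    return min_idx, maj_idx


def ros(data: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Duplicate minority rows with replacement until class counts equal."""
    min_idx, maj_idx = _split_classes(data)
    deficit = len(maj_idx) - len(min_idx)
    if deficit == 0:
        return data._take(np.arange(len(data.y)))
    rng = np.random.default_rng(seed)
    extra = rng.choice(min_idx, size=deficit, replace=True)
    return data._take(np.concatenate([np.arange(len(data.y)), extra]))


def rus(data: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Subsample the majority class without replacement to the minority size."""
    min_idx, maj_idx = _split_classes(data)
    rng = np.random.default_rng(seed)
    keep = rng.choice(maj_idx, size=len(min_idx), replace=False)
    idx = np.sort(np.concatenate([min_idx, keep]))
    return data._take(idx)


def bsmote(
    data: LabeledDataset,
    k_neighbors: int = 5,
    m_neighbors: int = 10,
    seed: int = 0,
    clip_ranges: tuple[np.ndarray, np.ndarray] | None = None,
) -> LabeledDataset:
    """Borderline-SMOTE-1 oversampling of the minority class.

    Minority points whose ``m_neighbors``-neighbourhood (over the whole
    training set) contains more majority than minority points — but is not
    pure majority (those are treated as noise) — are *danger* points.  New
    samples are ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)`` toward one of the
    danger point's ``k_neighbors`` nearest minority neighbours, until the
    classes balance.  If the minority class is too small for the
    neighbourhood queries, falls back to ROS with a warning.  Optional
    ``clip_ranges = (lo, hi)`` clamps synthetic rows to per-feature bounds.
    """
    min_idx, maj_idx = _split_classes(data)
    deficit = len(maj_idx) - len(min_idx)
    if deficit == 0:
        return data._take(np.arange(len(data.y)))
    if len(min_idx) <= k_neighbors:
        warnings.warn(
            "minority class too small for borderline-SMOTE; falling back to ROS",
            stacklevel=2,
        )
        return ros(data, seed=seed)

    X_min = data.X[min_idx]
    m = min(m_neighbors, len(data.y) - 1)
    nn_all = NearestNeighbors(n_neighbors=m + 1).fit(data.X)
    _, neigh = nn_all.kneighbors(X_min)
    maj_mask = data.y[neigh[:, 1:]] != data.y[min_idx[0]]
    n_maj = maj_mask.sum(axis=1)
    danger = (n_maj >= m / 2) & (n_maj < m)
    source = np.nonzero(danger)[0]
    if len(source) == 0:
        # No borderline points (minority well separated): sample from the
        # whole minority interior instead.
        source = np.arange(len(min_idx))

    nn_min = NearestNeighbors(n_neighbors=min(k_neighbors + 1, len(min_idx))).fit(X_min)
    _, min_neigh = nn_min.kneighbors(X_min[source])

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(source), size=deficit)
    nn_col = rng.integers(1, min_neigh.shape[1], size=deficit)
    u = rng.random((deficit, 1))
    base = X_min[source[picks]]
    target = X_min[min_neigh[picks, nn_col]]
    synth = base + u * (target - base)
    if clip_ranges is not None:
        synth = np.clip(synth, clip_ranges[0], clip_ranges[1])

    minority_label = data.y[min_idx[0]]
    return LabeledDataset(
        np.vstack([data.X, synth]),
        np.concatenate([data.y, np.full(deficit, minority_label)]),
        np.concatenate([np.asarray(data.patient_ids), np.asarray(data.patient_ids)[min_idx[source[picks]]]]),
        np.concatenate([np.asarray(data.row_ids), np.full(deficit, -1)]),
    )
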