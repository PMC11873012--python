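"""Layer-wise linear readout and accuracy-pattern comparison.

A linear SVM is trained on (normalized, subsampled) unit activations to
predict object identity; accuracy is tabulated per stimulus condition
(e.g., size x azimuth cell) into an :class:`AccuracyMatrix`, which can be
compared to a reference observer's matrix by L1 distance (mean absolute
cell difference) or Pearson correlation (scale- and shift-invariant).
Across classification runs and unit-population scales, the layer at which
the comparison is extremal is accumulated into a histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadoutConfig:
    n_train: int = 5000
    n_test: int = 5000
    occluded_fraction: float = 0.0
    n_runs: int = 5
    scales: tuple[int, ...] = (1_000, 5_000, 10_000, 50_000, 100_000)
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0 or self.n_runs <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.occluded_fraction <= 1.0:
            raise ValueError("occluded_fraction must lie in [0, 1]")


@dataclass
class AccuracyMatrix:
    """Per-condition classification accuracy.

    ``cells`` is a pandas Series indexed by condition values (MultiIndex for
    several transformation axes), with accuracies in [0, 1].
    """

    cells: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.cells.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def values(self) -> np.ndarray:
        return self.cells.to_numpy(dtype=float)

    def overall(self, weights: pd.Series | None = None) -> float:
        if weights is None:
            return float(self.values.mean())
        w = weights.reindex(self.cells.index).to_numpy(dtype=float)
        return float(np.average(self.values, weights=w))

    def table(self) -> pd.DataFrame:
        """2-D pivot for two-axis condition grids."""
        if self.cells.index.nlevels != 2:
            raise ValueError("table() needs exactly two condition axes")
        return self.cells.unstack()

    def to_csv(self, path) -> None:
        self.cells.rename("accuracy").to_csv(path)


def zscore(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Normalize units to zero mean / unit SD using *training* statistics.

    Units with zero training SD carry no information and are dropped (and
    logged).  Returns (train_z, test_z, kept_column_indices).
    """
    train = np.asarray(train, dtype=np.float64)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all units are degenerate (zero variance)")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("zscore: dropped %d zero-variance units", n_dropped)
    kept = np.nonzero(keep)[0]
    train_z = (train[:, keep] - mu[keep]) / sd[keep]
    test_z = None
    if test is not None:
        test = np.asarray(test, dtype=np.float64)
        test_z = (test[:, keep] - mu[keep]) / sd[keep]
    return train_z, test_z, kept


def train_readout(
    activations: np.ndarray,
    labels: np.ndarray,
    *,
    C: float = 1.0,
    seed: int = 0,
) -> LinearSVC:
    """Margin-based linear classifier on the (normalized) activations."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    svm = LinearSVC(C=C, tol=1e-4, random_state=seed)
    svm.fit(np.asarray(activations), labels)
    return svm


def evaluate(
    classifier,
    activations: np.ndarray,
    labels: np.ndarray,
    conditions: pd.DataFrame,
    *,
    meta: dict | None = None,
) -> AccuracyMatrix:
    """Per-condition fraction correct.

    ``conditions`` has one row per test trial and one column per
    transformation axis; every condition cell must contain at least one
    trial.
    """
    conditions = pd.DataFrame(conditions).reset_index(drop=True)
    pred = classifier.predict(np.asarray(activations))
    correct = pd.Series(pred == np.asarray(labels), name="correct")
    grouped = correct.groupby([conditions[c] for c in conditions.columns]).mean()
    counts = correct.groupby([conditions[c] for c in conditions.columns]).size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"empty condition cells: {list(empty.index)}")
    return AccuracyMatrix(grouped, meta=dict(meta or {}))


def _aligned(reference: AccuracyMatrix, candidate: AccuracyMatrix):
    a = reference.cells.sort_index()
    b = candidate.cells.reindex(a.index)
    if b.isna().any() or len(a) != len(candidate.cells):
        raise ValueError("accuracy matrices do not share the same condition cells")
    return a.to_numpy(dtype=float), b.to_numpy(dtype=float)


def compare_l1(reference: AccuracyMatrix, candidate: AccuracyMatrix) -> float:
    """Mean absolute accuracy difference over matched condition cells."""
    a, b = _aligned(reference, candidate)
    return float(np.abs(a - b).mean())


def compare_pearson(reference: AccuracyMatrix, candidate: AccuracyMatrix) -> float:
    """Pearson r over flattened matched cells (scale/shift invariant)."""
    a, b = _aligned(reference, candidate)
    if len(a) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r undefined for a constant accuracy pattern")
    return float(stats.pearsonr(a, b)[0])


def extrema_histogram(curves: np.ndarray, mode: str = "min") -> np.ndarray:
    """Count, per layer, how often each layer is the arg-extremum of a curve.

    ``curves`` is (n_curves, n_layers), one curve per run x scale.  Ties are
    broken toward the shallower layer.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if curves.size == 0:
        raise ValueError("need at least one curve")
    if mode == "min":
        args = curves.argmin(axis=1)
    elif mode == "max":
        args = curves.argmax(axis=1)
    else:
        raise ValueError("mode must be 'min' or 'max'")
    return np.bincount(args, minlength=curves.shape[1])


def pixel_baseline(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    test_images: np.ndarray,
    test_labels: np.ndarray,
    conditions: pd.DataFrame,
    *,
    C: float = 1.0,
    seed: int = 0,
    meta: dict | None = None,
) -> AccuracyMatrix:
    """Same readout protocol with raw pixels as the feature vector."""
    xtr = np.asarray(train_images).reshape(len(train_images), -1)
    xte = np.asarray(test_images).reshape(len(test_images), -1)
    xtr_z, xte_z, _ = zscore(xtr, xte)
    svm = train_readout(xtr_z, train_labels, C=C, seed=seed)
    meta = dict(meta or {})
    meta.setdefault("features", "pixels")
    return evaluate(svm, xte_z, test_labels, conditions, meta=meta)
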