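"""Searchlight decoding: spherical neighborhoods, PCA features, and
cross-validated linear-SVM classification accuracy per voxel.

A sphere of fixed mm radius slides over every in-mask voxel.  The gray-matter
values of the voxels inside the sphere form a subjects x voxels matrix; PCA
reduces it to the components needed to retain a fixed fraction of variance,
and a linear soft-margin SVM classifies exposure group with stratified
k-fold cross-validation.  The pooled held-out accuracy is assigned to the
center voxel, producing a 3-D accuracy map.  Voxels that are both
significant in the covariate-adjusted group t-map and classify above an
accuracy threshold form the "constrained" region carried into the cognitive
representation stage; significant voxels classifying at or below the
threshold are "excluded".

By default PCA is fitted inside each training fold and applied to the held
out fold, so no test information leaks into the features.  A ``pca_global``
switch instead fits PCA once on all subjects before cross-validation, which
reproduces the literal reduce-then-classify ordering some pipelines use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

try:  # the low-level libsvm binding skips per-call validation overhead,
    # which dominates the cost of the many tiny fits a searchlight makes;
    # results are identical to SVC (same C library, tested against it)
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - depends on sklearn internals
    _libsvm = None

from .containers import BrainMask, CohortVolumes, unmask


def _svm_fit_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, C: float
) -> np.ndarray:
    """Linear soft-margin SVM class predictions for one CV fold."""
    if _libsvm is not None:
        model = _libsvm.fit(
            np.ascontiguousarray(train_x, dtype=np.float64),
            np.ascontiguousarray(train_y, dtype=np.float64),
            svm_type=0, kernel="linear", C=float(C),
        )
        return _libsvm.predict(
            np.ascontiguousarray(test_x, dtype=np.float64),
            *model[:7], svm_type=0, kernel="linear",
        )
    clf = SVC(kernel="linear", C=C)
    clf.fit(train_x, train_y)
    return clf.predict(test_x)


@dataclass
class SearchlightSpec:
    """Tunable settings of the searchlight stage."""

    radius_mm: float = 2.0
    variance_retained: float = 0.8
    folds: int = 10
    svm_regularization: float = 1.0
    accuracy_threshold: float = 0.6
    pca_global: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_retained <= 1.0):
            raise ValueError("variance_retained must be in (0, 1]")
        if not (0.5 < self.accuracy_threshold <= 1.0):
            raise ValueError("accuracy_threshold must be in (0.5, 1]")
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be non-negative")
        if self.svm_regularization <= 0:
            raise ValueError("svm_regularization must be positive")


@dataclass
class AccuracyMap:
    """Per in-mask voxel cross-validated classification accuracy."""

    accuracy: np.ndarray  # (n_voxels,) in mask order
    neighborhood_size: np.ndarray
    mask: BrainMask
    spec: SearchlightSpec
    flagged: np.ndarray | None = None  # zero-variance / degenerate voxels

    def volume(self) -> np.ndarray:
        return unmask(self.accuracy, self.mask)


@dataclass
class RegionPartition:
    """Split of the significant t-map voxels by classification accuracy."""

    constrained: np.ndarray  # bool volumes
    excluded: np.ndarray
    accuracy_threshold: float
    significance_level: float | None = None

    def __post_init__(self) -> None:
        if (self.constrained & self.excluded).any():
            raise ValueError("constrained and excluded voxel sets overlap")


def neighborhood_index(
    mask: BrainMask, radius_mm: float, affine: np.ndarray | None = None
) -> list[np.ndarray]:
    """For each in-mask voxel, the in-mask voxels within ``radius_mm``.

    Distances are Euclidean mm between voxel centers, taken from the affine
    (the mask's own affine by default); the center voxel is always included.
    Returns one array of flat in-mask positions per in-mask voxel, in mask
    order.
    """
    if affine is None:
        affine = mask.affine
    scales = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))  # mm per voxel step
    max_steps = np.floor(radius_mm / scales).astype(int)
    if radius_mm < scales.min():
        warnings.warn(
            f"radius {radius_mm} mm is below the voxel size; neighborhoods are single voxels"
        )
    offsets = []
    for di in range(-max_steps[0], max_steps[0] + 1):
        for dj in range(-max_steps[1], max_steps[1] + 1):
            for dk in range(-max_steps[2], max_steps[2] + 1):
                step = np.array([di, dj, dk], dtype=float) * scales
                if np.dot(step, step) <= radius_mm**2 + 1e-12:
                    offsets.append((di, dj, dk))
    offsets = np.array(offsets, dtype=int)

    dims = mask.data.shape
    coords = mask.indices  # (n_vox, 3)
    # position of every voxel within the mask ordering; -1 outside
    flat_pos = -np.ones(dims, dtype=np.int64)
    flat_pos[tuple(coords.T)] = np.arange(len(coords))

    neighbor_pos = np.full((len(coords), len(offsets)), -1, dtype=np.int64)
    for c, off in enumerate(offsets):
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < dims), axis=1)
        neighbor_pos[ok, c] = flat_pos[tuple(shifted[ok].T)]
    return [row[row >= 0] for row in neighbor_pos]


def _pca_reduce(
    train: np.ndarray, test: np.ndarray | None, variance_retained: float
) -> tuple[np.ndarray, np.ndarray | None, bool]:
    """Center on the training mean, project onto the leading principal
    components that reach the retained-variance fraction.

    Returns (train_features, test_features, degenerate_flag); a
    zero-variance neighborhood yields a single all-zero feature, flagged.
    """
    mean = train.mean(axis=0)
    Xc = train - mean
    # economy SVD: components are right singular vectors
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        zeros_tr = np.zeros((train.shape[0], 1))
        zeros_te = np.zeros((test.shape[0], 1)) if test is not None else None
        return zeros_tr, zeros_te, True
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, variance_retained - 1e-12) + 1)
    comps = Vt[:k]
    train_f = Xc @ comps.T
    test_f = (test - mean) @ comps.T if test is not None else None
    return train_f, test_f, False


def searchlight_features(
    data: np.ndarray, variance_retained: float = 0.8
) -> tuple[np.ndarray, bool]:
    """PCA features of one neighborhood's subjects x voxels matrix.

    Data are centered (not scaled); the retained component count is the
    smallest k whose cumulative explained variance reaches the threshold.
    Returns ``(features, degenerate)`` where ``degenerate`` marks a
    zero-variance neighborhood (single all-zero feature).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a subjects x voxels matrix with >= 2 subjects")
    feats, _, degenerate = _pca_reduce(data, None, variance_retained)
    return feats, degenerate


def _stratified_folds(
    labels: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("cv_accuracy requires exactly two classes")
    if counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds with a class of size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    regularization: float = 1.0,
    seed: int = 0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Pooled stratified k-fold accuracy of a linear soft-margin SVM.

    Accuracy is the fraction of all subjects classified correctly when held
    out, pooled over folds (not the mean of per-fold accuracies).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if splits is None:
        splits = _stratified_folds(labels, folds, seed)
    _, y = np.unique(labels, return_inverse=True)
    y = y.astype(float)
    correct = 0
    for train_idx, test_idx in splits:
        pred = _svm_fit_predict(
            features[train_idx], y[train_idx], features[test_idx], regularization
        )
        correct += int((pred == y[test_idx]).sum())
    return correct / len(labels)


def accuracy_map(
    cohort: CohortVolumes,
    mask: BrainMask,
    labels: np.ndarray,
    spec: SearchlightSpec | None = None,
    neighbors: list[np.ndarray] | None = None,
) -> AccuracyMap:
    """Run the searchlight over every in-mask voxel.

    Per voxel: gather the spherical neighborhood, reduce to PCA features
    (per training fold unless ``spec.pca_global``), and score a linear SVM
    by stratified cross-validation.  Degenerate voxels (zero variance) are
    flagged, never fatal.  Deterministic under a fixed ``spec.seed``.
    """
    spec = spec or SearchlightSpec()
    labels = np.asarray(labels)
    Y = cohort.masked_matrix(mask)
    if neighbors is None:
        neighbors = neighborhood_index(mask, spec.radius_mm)
    splits = _stratified_folds(labels, spec.folds, spec.seed)
    y = (labels == np.unique(labels)[0]).astype(float)

    n_vox = len(neighbors)
    acc = np.zeros(n_vox)
    sizes = np.array([len(nb) for nb in neighbors])
    flagged = np.zeros(n_vox, dtype=bool)
    C = spec.svm_regularization

    for v in range(n_vox):
        block = Y[:, neighbors[v]]
        if spec.pca_global:
            feats, degenerate = searchlight_features(block, spec.variance_retained)
            if degenerate:
                flagged[v] = True
                acc[v] = 0.5
                continue
            acc[v] = cv_accuracy(feats, y, regularization=C, splits=splits)
            continue
        correct = 0
        for train_idx, test_idx in splits:
            tr_f, te_f, degenerate = _pca_reduce(
                block[train_idx], block[test_idx], spec.variance_retained
            )
            if degenerate:
                flagged[v] = True
                # an uninformative fold: predict the training majority class
                maj = np.bincount(y[train_idx].astype(int)).argmax()
                correct += int((y[test_idx] == maj).sum())
                continue
            pred = _svm_fit_predict(tr_f, y[train_idx], te_f, C)
            correct += int((pred == y[test_idx]).sum())
        acc[v] = correct / len(y)
    return AccuracyMap(acc, sizes, mask, spec, flagged)


def constrain_regions(
    acc_map: AccuracyMap,
    significance: np.ndarray,
    threshold: float | None = None,
) -> RegionPartition:
    """Partition the significant t-map voxels by classification accuracy.

    constrained = significant and accuracy strictly above the threshold;
    excluded = significant and accuracy at or below it.  Together they tile
    the significance mask exactly.
    """
    threshold = acc_map.spec.accuracy_threshold if threshold is None else threshold
    acc_vol = acc_map.volume()
    significance = np.asarray(significance, dtype=bool)
    if significance.shape != acc_vol.shape:
        raise ValueError("significance mask grid does not match accuracy map")
    constrained = significance & (acc_vol > threshold)
    excluded = significance & ~(acc_vol > threshold)
    if not constrained.any():
        warnings.warn("constrained set is empty; representation stage will be skipped")
    return RegionPartition(constrained, excluded, threshold)
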