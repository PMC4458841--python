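"""Cross-subject prediction of voxel connectivity preference from coordinates.

Samples are (voxel, subject) pairs: features are the voxel's grid coordinates
centered on the ROI centroid (identical across subjects, who share the
template space), labels are the subject's PRC- vs PHC-preference signs, and
chunks are subjects.  A linear SVM is evaluated by leave-one-subject-out
(LOSO) cross-validation; significance comes from a permutation null that
relabels the training chunks and reruns the full LOSO scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .group_maps import PreferenceMap


@dataclass
class VoxelSampleSet:
    """(voxel, subject) samples over a common ROI mask."""

    features: np.ndarray          # (n_voxels, 3) centered coordinates
    labels: np.ndarray            # (n_subjects, n_voxels) in {+1, -1}
    chunk_ids: list               # subject ids, one per row of labels
    roi_mask: np.ndarray
    voxel_coords: np.ndarray      # (n_voxels, 3) raw grid coordinates

    @property
    def n_voxels(self) -> int:
        return self.features.shape[0]

    @property
    def n_chunks(self) -> int:
        return len(self.chunk_ids)


@dataclass
class LosoResult:
    """Leave-one-subject-out accuracies and per-(voxel, fold) predictions."""

    fold_accuracies: np.ndarray   # (n_folds,)
    predictions: np.ndarray       # (n_folds, n_voxels) in {+1, -1}
    chunk_ids: list

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


@dataclass
class PermutationResult:
    null_accuracies: np.ndarray
    observed: float
    n_iter: int
    rng_seed: int

    @property
    def p(self) -> float:
        return (1 + int((self.null_accuracies >= self.observed).sum())) / (1 + self.n_iter)


@dataclass
class ConsistencyMap:
    """Per-voxel proportion of folds with a correct prediction."""

    values: np.ndarray            # 3D, NaN outside the ROI
    roi_mask: np.ndarray


@dataclass
class PredictedParcels:
    """Majority-vote subregion masks; exact vote ties stay unassigned."""

    al_ec_mask: np.ndarray
    pm_ec_mask: np.ndarray
    unassigned: np.ndarray = field(default=None)


def assemble_samples(subject_maps: list[PreferenceMap],
                     roi_mask: np.ndarray) -> VoxelSampleSet:
    """Build the coordinate/label sample set from per-subject preference maps."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    coords = np.argwhere(roi_mask)
    labels = np.empty((len(subject_maps), len(coords)), dtype=np.int8)
    for i, pmap in enumerate(subject_maps):
        if not roi_mask[pmap.mask].all() or (roi_mask & ~pmap.mask).any():
            raise ValueError(f"subject map {i} does not cover the ROI mask")
        lab = pmap.labels[roi_mask]
        if np.any(lab == 0):
            raise ValueError(f"subject map {i} has unlabeled ROI voxels")
        labels[i] = lab
    features = coords - coords.mean(axis=0)
    return VoxelSampleSet(features.astype(float), labels,
                          [f"chunk-{i}" for i in range(len(subject_maps))],
                          roi_mask, coords)


def _fit_predict(x_train, y_train, x_test, svm_cost: float) -> np.ndarray:
    # class_weight="balanced" removes the majority-class channel: without it a
    # leave-one-subject-out scheme is anti-conservative/conservative on label
    # noise because the held-out chunk's majority is anti-correlated with the
    # training majority
    clf = LinearSVC(C=svm_cost, dual=False, tol=1e-3, max_iter=200,
                    class_weight="balanced")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x_train, y_train)
    return clf.predict(x_test).astype(np.int8)


def loso_svm(ds: VoxelSampleSet, svm_cost: float = 1.0,
             train_labels: np.ndarray | None = None) -> LosoResult:
    """Leave-one-subject-out linear-SVM classification of voxel labels.

    Each fold trains on the pooled (voxel, subject) samples of all chunks but
    one and scores the held-out chunk's voxels against that subject's own
    labels.  ``train_labels`` optionally substitutes a relabelled copy for
    training only (used by the permutation null); testing always uses the
    true labels.  Deterministic given the sample set.
    """
    if ds.n_chunks < 2:
        raise ValueError("need >= 2 chunks for leave-one-subject-out")
    y_train_src = ds.labels if train_labels is None else train_labels
    n_folds = ds.n_chunks
    accs = np.empty(n_folds)
    preds = np.empty((n_folds, ds.n_voxels), dtype=np.int8)
    x = np.tile(ds.features, (n_folds - 1, 1))
    for fold in range(n_folds):
        train_chunks = [c for c in range(n_folds) if c != fold]
        y = y_train_src[train_chunks].reshape(-1)
        if len(np.unique(y)) < 2:
            raise ValueError(f"training fold {fold} contains a single label")
        pred = _fit_predict(x, y, ds.features, svm_cost)
        preds[fold] = pred
        accs[fold] = float((pred == ds.labels[fold]).mean())
    return LosoResult(accs, preds, list(ds.chunk_ids))


def permutation_null(ds: VoxelSampleSet, observed: LosoResult,
                     n_iter: int = 1000, seed: int = 0, svm_cost: float = 1.0,
                     strict: bool = True, scheme: str = "relabel") -> PermutationResult:
    """Permutation null for the LOSO mean accuracy.

    Each iteration replaces the training labels, reruns the full LOSO scheme
    against the true test labels, and records the mean accuracy.
    ``p = (1 + #{null >= observed}) / (1 + n_iter)`` -- never below the
    ``1/(1+n_iter)`` floor.

    Schemes (see the methods note for the calibration comparison):

    * ``"relabel"`` (default): every label -- training and testing -- is a
      fresh fair coin each iteration.  The null statistic is then an exact
      exchangeable copy of the observed one when the true labels carry no
      spatial structure, giving uniform p-values under the null.  In a LOSO
      scheme each chunk enters both training (other folds) and testing (its
      own fold), so a null that relabels only the training side does not
      reproduce the observed statistic's fold dependence.
    * ``"relabel_train"``: fresh coins for training chunks only; tests
      against the true labels.
    * ``"permute_train"``: permutes each training chunk's labels, preserving
      per-chunk class counts.  Markedly conservative on label-noise data
      because a linear SVM's constant-prediction component depends on the
      pooled class imbalance, which this scheme holds fixed.
    """
    if n_iter < 100:
        msg = f"n_iter={n_iter} < 100 gives an unusably coarse null"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    if scheme not in ("relabel", "relabel_train", "permute_train"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    coin = np.array([-1, 1], dtype=ds.labels.dtype)
    null = np.empty(n_iter)
    for it in range(n_iter):
        if scheme == "relabel":
            labels = rng.choice(coin, size=ds.labels.shape)
            ds_it = VoxelSampleSet(ds.features, labels, ds.chunk_ids,
                                   ds.roi_mask, ds.voxel_coords)
            null[it] = loso_svm(ds_it, svm_cost).mean_accuracy
            continue
        if scheme == "relabel_train":
            perm = rng.choice(coin, size=ds.labels.shape)
        else:
            perm = np.empty_like(ds.labels)
            for c in range(ds.n_chunks):
                perm[c] = ds.labels[c, rng.permutation(ds.n_voxels)]
        null[it] = loso_svm(ds, svm_cost, train_labels=perm).mean_accuracy
    return PermutationResult(null, observed.mean_accuracy, n_iter, seed)


def consistency_map(res: LosoResult, ds: VoxelSampleSet) -> ConsistencyMap:
    """Proportion of folds predicting each voxel's label correctly."""
    correct = (res.predictions == ds.labels).mean(axis=0)
    values = np.full(ds.roi_mask.shape, np.nan)
    values[ds.roi_mask] = correct
    return ConsistencyMap(values, ds.roi_mask)


def predicted_parcels(res: LosoResult, roi_mask: np.ndarray) -> PredictedParcels:
    """Majority vote over fold predictions -> al-EC / pm-EC / unassigned."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if res.predictions.size == 0:
        raise ValueError("empty LOSO result")
    vote = res.predictions.sum(axis=0)
    al = np.zeros(roi_mask.shape, dtype=bool)
    pm = np.zeros(roi_mask.shape, dtype=bool)
    tie = np.zeros(roi_mask.shape, dtype=bool)
    al[roi_mask] = vote > 0
    pm[roi_mask] = vote < 0
    tie[roi_mask] = vote == 0
    return PredictedParcels(al_ec_mask=al, pm_ec_mask=pm, unassigned=tie)
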