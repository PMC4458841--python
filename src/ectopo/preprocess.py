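"""Volume-level preparation: spike flagging, smoothing, task residualization,
and ROI conditioning (intensity thresholding, seed-border erosion)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cohort import TaskSpec, task_regressors

#: head radius (mm) used to convert rotations to worst-case surface
#: displacement, the common artifact-detection convention
HEAD_RADIUS_MM = 65.0

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class SpikeSet:
    """Volumes flagged as global-intensity or motion outliers."""

    flagged_volumes: set = field(default_factory=set)
    reasons: dict = field(default_factory=dict)  # volume -> "intensity" | "motion"

    def indicator_matrix(self, n_volumes: int) -> np.ndarray:
        """(n_volumes, n_flagged) 0/1 indicators, one column per flagged volume."""
        idx = sorted(self.flagged_volumes)
        out = np.zeros((n_volumes, len(idx)))
        for j, i in enumerate(idx):
            if not 0 <= i < n_volumes:
                raise ValueError(f"flagged volume {i} outside [0, {n_volumes})")
            out[i, j] = 1.0
        return out


@dataclass
class DesignMatrix:
    """Task + nuisance design with named columns and an intercept."""

    values: np.ndarray
    column_names: list


def detect_spikes(bold_global_mean: np.ndarray, motion: np.ndarray,
                  intensity_pct: float = 1.3, motion_mm: float = 0.3) -> SpikeSet:
    """Flag outlier volumes by global intensity and scan-to-scan motion.

    Volume ``i`` is flagged "intensity" when its global mean deviates from the
    run mean by more than ``intensity_pct`` percent, and "motion" when the
    scan-to-scan displacement exceeds ``motion_mm`` (the Euclidean norm of the
    volume-to-volume difference of the six realignment parameters, rotations
    converted to mm at a 65 mm head radius).  Intensity flags take precedence
    in ``reasons`` when both fire.
    """
    g = np.asarray(bold_global_mean, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if g.ndim != 1 or len(g) < 2 or motion.shape != (len(g), 6):
        raise ValueError("need a global-mean series and a matching (t, 6) motion table "
                         f"of length >= 2, got {g.shape} and {motion.shape}")
    mean_g = g.mean()
    if mean_g == 0:
        raise ZeroDivisionError("global mean intensity is zero; percent deviation undefined")
    spikes = SpikeSet()
    pct = np.abs(g - mean_g) / abs(mean_g) * 100.0
    for i in np.flatnonzero(pct > intensity_pct):
        spikes.flagged_volumes.add(int(i))
        spikes.reasons[int(i)] = "intensity"
    params_mm = motion.copy()
    params_mm[:, 3:] *= HEAD_RADIUS_MM
    disp = np.linalg.norm(np.diff(params_mm, axis=0), axis=1)
    for i in np.flatnonzero(disp > motion_mm) + 1:
        i = int(i)
        if i not in spikes.flagged_volumes:
            spikes.flagged_volumes.add(i)
            spikes.reasons[i] = "motion"
    return spikes


def gaussian_smooth(bold: np.ndarray, fwhm_mm: float = 1.5,
                    voxel_mm: float = 0.8) -> np.ndarray:
    """Spatial Gaussian smoothing of each volume of a 4D (or single 3D) grid.

    ``sigma = fwhm / (2 sqrt(2 ln 2)) / voxel_mm`` voxels; ``fwhm_mm = 0``
    returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    bold = np.asarray(bold)
    if fwhm_mm == 0:
        return bold.copy()
    sigma = fwhm_mm / _FWHM_TO_SIGMA / voxel_mm
    sigmas = (sigma, sigma, sigma) + ((0,) if bold.ndim == 4 else ())
    return ndimage.gaussian_filter(bold.astype(float, copy=False), sigma=sigmas)


def build_task_design(events: TaskSpec, motion: np.ndarray, spikes: SpikeSet,
                      tr: float, n_volumes: int) -> DesignMatrix:
    """HRF-convolved condition columns + 6 motion + spike indicators + intercept."""
    events.validate(n_volumes * tr)
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise ValueError(f"motion must be ({n_volumes}, 6), got {motion.shape}")
    task_cols, conds = task_regressors(events, tr, n_volumes)
    spike_cols = spikes.indicator_matrix(n_volumes)
    values = np.column_stack([task_cols, motion, spike_cols,
                              np.ones((n_volumes, 1))])
    names = (list(conds)
             + [f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
             + [f"spike_{i}" for i in sorted(spikes.flagged_volumes)]
             + ["intercept"])
    return DesignMatrix(values, names)


def _drop_duplicate_columns(x: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    keep, seen = [], set()
    for j in range(x.shape[1]):
        key = x[:, j].tobytes()
        if key not in seen:
            seen.add(key)
            keep.append(j)
    return x[:, keep], [names[j] for j in keep]


def remove_task_effects(bold: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Per-voxel OLS residuals of the BOLD data against the design.

    Accepts a 4D grid (x, y, z, t) or any array whose last axis is time.
    Exactly duplicated columns are collapsed before fitting; a remaining
    rank deficiency is an error naming the offending columns.
    """
    bold = np.asarray(bold, dtype=float)
    x, names = _drop_duplicate_columns(np.asarray(design.values, dtype=float),
                                       list(design.column_names))
    t = bold.shape[-1]
    if x.shape[0] != t:
        raise ValueError(f"design has {x.shape[0]} rows but data has {t} volumes")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {x.shape[1]} columns): {names}")
    y = bold.reshape(-1, t).T                      # (t, V)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid.T.reshape(bold.shape)


def threshold_roi_intensity(mask: np.ndarray, bold: np.ndarray) -> np.ndarray:
    """Drop ROI voxels with low temporal-mean intensity (signal dropout).

    Removes voxels whose mean intensity across timepoints falls below
    (ROI mean across voxels) - 2 * (ROI SD across voxels).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    tmean = np.asarray(bold, dtype=float)[mask].mean(axis=-1)
    cutoff = tmean.mean() - 2.0 * tmean.std()
    keep = tmean >= cutoff
    if not keep.any():
        raise ValueError("intensity thresholding removed every ROI voxel")
    out = np.zeros_like(mask)
    out[mask] = keep
    return out


def erode_seed_border(seed_mask: np.ndarray, target_mask: np.ndarray,
                      gap_voxels: int = 2) -> np.ndarray:
    """Remove seed voxels within Chebyshev distance ``gap_voxels`` of the target.

    Guards seed-target correlations against shared smoothing support; the
    returned seed has minimum Chebyshev distance > ``gap_voxels`` from every
    target voxel.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    if (seed_mask & target_mask).any():
        raise ValueError("seed and target masks overlap")
    if gap_voxels == 0:
        return seed_mask.copy()
    size = 2 * gap_voxels + 1
    near_target = ndimage.maximum_filter(target_mask.astype(np.uint8), size=size) > 0
    out = seed_mask & ~near_target
    if not out.any():
        raise ValueError(f"eroding a {gap_voxels}-voxel border emptied the seed")
    return out
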