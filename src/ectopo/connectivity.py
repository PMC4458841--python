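"""First-level seed-to-voxel intrinsic connectivity.

Per (subject, seed) pair: seed averaging, nuisance regression, zero-phase
band-pass filtering (0.01-0.1 Hz), Pearson correlation, Fisher z transform
and per-map Z-standardization.  Processing order is sequential (nuisance
regression, then band-pass, then correlation) for transparency; the band-pass
is a second-order Butterworth applied forward-backward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

_CLIP = 1.0 - 1e-7


@dataclass
class FisherZMap:
    """Per-voxel Fisher-z connectivity values for one (subject, seed) pair.

    ``values`` is a 3D grid, NaN outside ``target_mask``; ``qc_zero_variance``
    lists voxels whose filtered series had zero variance (their z is 0).
    """

    values: np.ndarray
    target_mask: np.ndarray
    subject_id: str = ""
    seed_id: str = ""
    band: tuple[float, float] = (0.01, 0.1)
    df_effective: int = 0
    qc_zero_variance: list = field(default_factory=list)

    def data(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Values over ``mask`` (default: the full target mask), 1D."""
        return self.values[self.target_mask if mask is None else mask]


def mean_timeseries(residuals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Unweighted mean time series across the voxels of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return np.asarray(residuals, dtype=float)[mask].mean(axis=0)


def regress_nuisance(data: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """OLS residual of series (last axis = time) against [nuisance, intercept].

    With an empty nuisance set this reduces to mean-centering.
    """
    data = np.asarray(data, dtype=float)
    t = data.shape[-1]
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.size == 0:
        nuisance = np.empty((t, 0))
    if nuisance.shape[0] != t:
        raise ValueError(f"nuisance has {nuisance.shape[0]} rows for {t} volumes")
    if nuisance.shape[1] >= t:
        raise ValueError("more nuisance regressors than timepoints")
    x = np.column_stack([nuisance, np.ones(t)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("nuisance matrix is rank deficient")
    y = data.reshape(-1, t).T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return (y - x @ beta).T.reshape(data.shape)


def bandpass(data: np.ndarray, low: float = 0.01, high: float = 0.1,
             tr: float = 2.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Removes DC exactly (the series is mean-centered before filtering and the
    filter has zero gain at 0 Hz); pass-band amplitudes are preserved within
    a few percent, stop bands attenuated by >= 90%.
    """
    nyq = 0.5 / tr
    if not 0 <= low < high:
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    data = np.asarray(data, dtype=float)
    data = data - data.mean(axis=-1, keepdims=True)
    b, a = sps.butter(2, [low / nyq, high / nyq], btype="band")
    return sps.filtfilt(b, a, data, axis=-1)


def fisher_z(r) -> np.ndarray | float:
    """Fisher transform z = atanh(r), clipping |r| to 1 - 1e-7 first."""
    r = np.clip(np.asarray(r, dtype=float), -_CLIP, _CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _correlate_with_seed(seed: np.ndarray, voxels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of ``voxels`` (V, t) with ``seed`` (t,).

    Returns (r, zero_variance_mask); zero-variance rows get r = 0.
    """
    seed = seed - seed.mean()
    v = voxels - voxels.mean(axis=1, keepdims=True)
    s_norm = np.linalg.norm(seed)
    v_norm = np.linalg.norm(v, axis=1)
    zero = (v_norm == 0) | (s_norm == 0)
    denom = np.where(zero, 1.0, v_norm * s_norm)
    r = (v @ seed) / denom
    r[zero] = 0.0
    return r, zero


def effective_df(n_volumes: int, n_nuisance: int, band: tuple[float, float],
                 tr: float) -> int:
    """Rough effective df of a band-limited correlation estimate."""
    return max(2, round(n_volumes * 2.0 * (band[1] - band[0]) * tr) - n_nuisance)


def seed_to_voxel_map(seed_series: np.ndarray, residuals: np.ndarray,
                      nuisance: np.ndarray, target_mask: np.ndarray,
                      band: tuple[float, float] = (0.01, 0.1), tr: float = 2.0,
                      subject_id: str = "", seed_id: str = "") -> FisherZMap:
    """Fisher-z map of seed-to-voxel correlations over a target mask.

    Both the seed series and every target voxel series are nuisance-regressed
    and band-pass filtered before the bivariate Pearson correlation; zero
    variance voxels get z = 0 and are recorded in the QC list.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    voxels = np.asarray(residuals, dtype=float)[target_mask]
    series = np.vstack([np.asarray(seed_series, dtype=float)[None, :], voxels])
    series = regress_nuisance(series, nuisance)
    series = bandpass(series, band[0], band[1], tr)
    r, zero = _correlate_with_seed(series[0], series[1:])
    values = np.full(target_mask.shape, np.nan)
    values[target_mask] = fisher_z(r)
    nuisance = np.asarray(nuisance, dtype=float)
    q = 0 if nuisance.size == 0 else nuisance.shape[1]
    return FisherZMap(
        values=values, target_mask=target_mask, subject_id=subject_id,
        seed_id=seed_id, band=tuple(band),
        df_effective=effective_df(series.shape[-1], q, band, tr),
        qc_zero_variance=[tuple(v) for v in np.argwhere(target_mask)[zero]],
    )


def z_standardize(fz_map: FisherZMap, reference_mask: np.ndarray) -> FisherZMap:
    """Standardize a map to mean 0, SD 1 over a reference mask.

    The reference mask must lie within the map's target mask and contain at
    least two voxels; a zero-SD (constant) map is an error.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() < 2:
        raise ValueError("reference mask needs >= 2 voxels")
    if (reference_mask & ~fz_map.target_mask).any():
        raise ValueError("reference mask extends outside the map's target mask")
    ref = fz_map.values[reference_mask]
    sd = ref.std()
    if sd == 0:
        raise ValueError("constant map: zero SD over the reference mask")
    values = np.where(fz_map.target_mask, (fz_map.values - ref.mean()) / sd, np.nan)
    return FisherZMap(values, fz_map.target_mask, fz_map.subject_id,
                      fz_map.seed_id, fz_map.band, fz_map.df_effective,
                      list(fz_map.qc_zero_variance))
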