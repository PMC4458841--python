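"""Voxelwise group inference on Fisher-z connectivity maps.

One-sample and paired t maps, nonparametric cluster-extent thresholding
(sign-flip max-cluster-size permutation), voxelwise preference labelling and
derivation of the anterior-lateral / posterior-medial EC seed regions from
significant paired-contrast clusters.

Cluster inference is one-sided per contrast direction: clusters are the
26-connected components of the normal-equivalent z map above ``z_thresh``,
and the familywise null is the distribution of the maximum cluster size over
subject-level sign flips (exact under exchangeability).  The opposite
direction is obtained by negating the contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .connectivity import FisherZMap

#: 26-neighbourhood connectivity for cluster components
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GroupStatMap:
    """Per-voxel t statistics and one-sided normal-equivalent z."""

    t_values: np.ndarray
    z_equiv: np.ndarray
    df: int
    mask: np.ndarray
    contrast_id: str = ""
    subject_data: np.ndarray | None = None   # (n_subjects, V) values behind the map


@dataclass
class ClusterTable:
    """Suprathreshold clusters with familywise permutation p-values."""

    table: pd.DataFrame                       # cluster_id, size, peak_z, x, y, z, p_fwe
    cluster_masks: list = field(default_factory=list)
    alpha: float = 0.05
    n_perm: int = 0

    def significant(self) -> pd.DataFrame:
        return self.table[self.table.p_fwe < self.alpha]

    def significant_mask(self) -> np.ndarray:
        out = None
        for i, m in enumerate(self.cluster_masks):
            if self.table.p_fwe.iloc[i] < self.alpha:
                out = m.copy() if out is None else (out | m)
        if out is None:
            raise ValueError("no significant clusters")
        return out

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PreferenceMap:
    """Binary PRC- vs PHC-preference labelling of a contrast map.

    ``labels``: +1 where the PRC-minus-PHC contrast is > 0 or exactly 0
    (deterministic tie rule -> PRC-preferring), -1 where it is < 0, 0 outside
    the mask.  ``magnitude`` holds |t| (or |difference| for subject maps).
    """

    labels: np.ndarray
    magnitude: np.ndarray
    mask: np.ndarray

    PRC_PREFERRING = 1
    PHC_PREFERRING = -1


@dataclass
class SeedRegionPair:
    """Disjoint al-EC / pm-EC seed masks inside the EC."""

    al_ec_mask: np.ndarray
    pm_ec_mask: np.ndarray


def _t_to_one_sided_z(t: np.ndarray, df: int) -> np.ndarray:
    """Normal-equivalent z of the one-sided t tail probability (monotone in t)."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    finite = np.isfinite(t)
    with np.errstate(invalid="ignore"):
        z[finite] = -special.ndtri_exp(stats.t.logsf(t[finite], df))
    z[~finite] = t[~finite]
    return z


def _stack_maps(maps: list[FisherZMap]) -> tuple[np.ndarray, np.ndarray]:
    mask = maps[0].target_mask
    for m in maps[1:]:
        if not np.array_equal(m.target_mask, mask):
            raise ValueError("maps do not share a common target mask")
    return np.vstack([m.values[mask] for m in maps]), mask


def one_sample_t(maps: list[FisherZMap], contrast_id: str = "") -> GroupStatMap:
    """Voxelwise one-sample t map across subjects.

    Voxels with zero variance across subjects get a signed infinite sentinel
    (0 when the values are exactly 0); such voxels are excluded from cluster
    formation.
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 subject maps")
    data, mask = _stack_maps(maps)
    return _group_t_from_data(data, mask, contrast_id)


def _group_t_from_data(data: np.ndarray, mask: np.ndarray,
                       contrast_id: str = "") -> GroupStatMap:
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} voxel(s) with zero across-subject variance; "
                      "set to a +/-inf sentinel and excluded from clustering")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, np.sign(mean) * np.inf, mean / (sd / np.sqrt(n)))
    t[zero & (mean == 0)] = 0.0
    df = n - 1
    t3 = np.full(mask.shape, np.nan)
    z3 = np.full(mask.shape, np.nan)
    t3[mask] = t
    z3[mask] = _t_to_one_sided_z(t, df)
    return GroupStatMap(t3, z3, df, mask, contrast_id, subject_data=data)


def paired_t(maps_a: list[FisherZMap], maps_b: list[FisherZMap],
             contrast_id: str = "") -> GroupStatMap:
    """Voxelwise paired t map (a - b) across subject-matched map lists."""
    if len(maps_a) != len(maps_b):
        raise ValueError("paired map lists differ in length")
    for ma, mb in zip(maps_a, maps_b):
        if ma.subject_id != mb.subject_id:
            raise ValueError(
                f"subject mismatch in paired maps: {ma.subject_id!r} vs {mb.subject_id!r}")
    data_a, mask = _stack_maps(maps_a)
    data_b, mask_b = _stack_maps(maps_b)
    if not np.array_equal(mask, mask_b):
        raise ValueError("paired map lists do not share a target mask")
    return _group_t_from_data(data_a - data_b, mask, contrast_id)


def _clusters_above(z3: np.ndarray, mask: np.ndarray, z_thresh: float):
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = np.isfinite(z3[mask]) & (z3[mask] > z_thresh)
    lab, n = ndimage.label(supra, structure=_STRUCTURE)
    return lab, n


def cluster_threshold(stat_map: GroupStatMap, z_thresh: float = 2.3,
                      alpha: float = 0.05, n_perm: int = 1000,
                      seed: int = 0, strict: bool = True) -> ClusterTable:
    """Cluster-extent thresholding with a sign-flip max-size permutation null.

    Clusters are 26-connected components of ``z_equiv > z_thresh``.  The null
    distribution of the maximum cluster size is built by flipping the signs of
    whole subject-level maps (for a paired contrast the subject maps are the
    per-subject differences, so a sign flip is a within-subject condition
    swap).  ``p_fwe = (1 + #{null max >= size}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        msg = f"n_perm={n_perm} < 100 gives an unusably coarse null"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    data = stat_map.subject_data
    if data is None:
        raise ValueError("stat map carries no subject-level data for permutation")
    mask = stat_map.mask
    lab, n_clus = _clusters_above(stat_map.z_equiv, mask, z_thresh)

    rows, masks = [], []
    if n_clus:
        n = data.shape[0]
        # equivalent t threshold: z > z_thresh  <=>  t > t_crit
        t_crit = stats.t.isf(stats.norm.sf(z_thresh), n - 1)
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        ss = np.einsum("sv,sv->v", data, data)          # invariant under sign flips
        sums = signs @ data                              # (n_perm, V)
        null_max = np.zeros(n_perm, dtype=int)
        grid = np.zeros(mask.shape, dtype=bool)
        vox_idx = np.nonzero(mask)
        for p in range(n_perm):
            mean = sums[p] / n
            var = np.maximum(ss / n - mean ** 2, 0.0) * (n / (n - 1))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_p = mean / np.sqrt(var / n)
            supra = np.isfinite(t_p) & (t_p > t_crit)
            if supra.any():
                grid[:] = False
                grid[vox_idx] = supra
                lab_p, k = ndimage.label(grid, structure=_STRUCTURE)
                if k:
                    null_max[p] = np.bincount(lab_p.ravel())[1:].max()
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n_clus + 1))
        order = np.argsort(sizes)[::-1]
        for rank, ci in enumerate(order, start=1):
            cmask = lab == (ci + 1)
            size = int(sizes[ci])
            zvals = np.where(cmask, stat_map.z_equiv, -np.inf)
            peak = np.unravel_index(np.nanargmax(np.where(np.isfinite(zvals), zvals, -np.inf)),
                                    mask.shape)
            p_fwe = (1 + int((null_max >= size).sum())) / (1 + n_perm)
            rows.append(dict(cluster_id=rank, size=size,
                             peak_z=float(stat_map.z_equiv[peak]),
                             x=int(peak[0]), y=int(peak[1]), z=int(peak[2]),
                             p_fwe=p_fwe))
            masks.append(cmask)
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "peak_z",
                                        "x", "y", "z", "p_fwe"])
    return ClusterTable(table, masks, alpha=alpha, n_perm=n_perm)


def _negate(stat_map: GroupStatMap) -> GroupStatMap:
    return _group_t_from_data(-stat_map.subject_data, stat_map.mask,
                              contrast_id=f"-({stat_map.contrast_id})")


def paired_cluster_analysis(maps_a: list[FisherZMap], maps_b: list[FisherZMap],
                            z_thresh: float = 2.3, alpha: float = 0.05,
                            n_perm: int = 1000, seed: int = 0,
                            strict: bool = True) -> tuple[GroupStatMap, ClusterTable, ClusterTable]:
    """Paired contrast with clusters of both signs thresholded separately."""
    pmap = paired_t(maps_a, maps_b, contrast_id="a>b")
    pos = cluster_threshold(pmap, z_thresh, alpha, n_perm, seed, strict)
    neg = cluster_threshold(_negate(pmap), z_thresh, alpha, n_perm, seed + 1, strict)
    return pmap, pos, neg


def preference_map(paired: GroupStatMap) -> PreferenceMap:
    """Sign-based group preference labelling of a paired (PRC - PHC) t map."""
    labels = np.zeros(paired.mask.shape, dtype=np.int8)
    t = paired.t_values
    labels[paired.mask] = np.where(t[paired.mask] < 0,
                                   PreferenceMap.PHC_PREFERRING,
                                   PreferenceMap.PRC_PREFERRING)
    magnitude = np.where(paired.mask, np.abs(t), np.nan)
    return PreferenceMap(labels, magnitude, paired.mask.copy())


def subject_preference_map(map_prc: FisherZMap, map_phc: FisherZMap) -> PreferenceMap:
    """Per-subject preference labelling by the sign of z_PRC - z_PHC."""
    if not np.array_equal(map_prc.target_mask, map_phc.target_mask):
        raise ValueError("subject maps do not share a target mask")
    mask = map_prc.target_mask
    diff = map_prc.values - map_phc.values
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask] = np.where(diff[mask] < 0, PreferenceMap.PHC_PREFERRING,
                            PreferenceMap.PRC_PREFERRING)
    magnitude = np.where(mask, np.abs(diff), np.nan)
    return PreferenceMap(labels, magnitude, mask.copy())


def derive_subregion_seeds(pos_clusters: ClusterTable, neg_clusters: ClusterTable,
                           ec_mask: np.ndarray) -> SeedRegionPair:
    """al-EC / pm-EC seed masks from significant paired-contrast clusters.

    al-EC is the union of significant PRC>PHC clusters, pm-EC of PHC>PRC
    clusters, both restricted to the EC mask.  If either side has no
    significant cluster the caller should fall back to classifier-predicted
    masks; this function raises with that instruction.
    """
    ec_mask = np.asarray(ec_mask, dtype=bool)
    try:
        al = pos_clusters.significant_mask() & ec_mask
        pm = neg_clusters.significant_mask() & ec_mask
    except ValueError as err:
        raise ValueError(
            "no significant cluster for one contrast direction; fall back to "
            "classifier-predicted subregion masks") from err
    if not al.any() or not pm.any():
        raise ValueError(
            "significant clusters lie outside the EC mask; fall back to "
            "classifier-predicted subregion masks")
    return SeedRegionPair(al_ec_mask=al, pm_ec_mask=pm)
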