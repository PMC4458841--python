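"""Gradient quantification along ROI axes.

Equal partitioning of elongated ROIs (longitudinal halves by whole coronal
slices; per-slice transverse halves and quintiles), cell-mean extraction,
within-subject 2x2x2 factorial ANOVA via contrast scores, follow-up paired
t-tests, slice profiles, end-slice contrasts and the delta-interaction
comparing EC-subregion and neocortical-seed gradients along the subiculum
long axis.

Partition conventions (deterministic, applied identically everywhere):

* the longitudinal cut never divides a slice; it minimizes the voxel-count
  imbalance, ties resolved by giving the anterior half more slices;
* within each coronal slice voxels are ordered along the slice's first
  principal axis oriented lateral -> medial; equal-count contiguous bins,
  remainder voxels assigned one each to the most lateral bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import transverse_order
from .connectivity import FisherZMap

ANTERIOR = "anterior"
POSTERIOR = "posterior"
LATERAL = "lateral"    # also proximal, for the subiculum
MEDIAL = "medial"      # also distal


@dataclass
class SectionAssignment:
    """Per-voxel section membership of one elongated ROI."""

    voxels: np.ndarray                    # (N, 3) int
    slice_index: np.ndarray               # (N,) y of each voxel
    longitudinal: np.ndarray | None = None   # (N,) ANTERIOR/POSTERIOR
    transverse_half: np.ndarray | None = None  # (N,) LATERAL/MEDIAL
    transverse_quintile: np.ndarray | None = None  # (N,) 1..5
    mask: np.ndarray | None = None

    def cell_mask(self, longitudinal: str | None = None,
                  transverse: str | None = None) -> np.ndarray:
        sel = np.ones(len(self.voxels), dtype=bool)
        if longitudinal is not None:
            sel &= self.longitudinal == longitudinal
        if transverse is not None:
            sel &= self.transverse_half == transverse
        return sel


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float


@dataclass
class SliceProfile:
    """Across-subject mean +/- SEM of section means along one axis."""

    axis: str                              # "longitudinal" | "transverse"
    table: pd.DataFrame                    # seed_id, position, mean, sem, n


def _ordered_slices(mask: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Coronal slices of a mask as (y, ordered (k,3) voxels), ascending y."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    for y in np.unique(np.nonzero(mask)[1]):
        coords = np.argwhere(mask[:, y, :])
        order = transverse_order(coords)
        vox = np.column_stack([coords[order, 0],
                               np.full(len(coords), y, dtype=int),
                               coords[order, 1]])
        out.append((int(y), vox))
    return out


def split_longitudinal(roi_mask: np.ndarray) -> SectionAssignment:
    """Anterior/posterior halves by whole coronal slices, counts balanced.

    Anterior is the larger-y half.  The cut position minimizes the absolute
    voxel-count imbalance between halves; ties give the anterior half more
    slices.
    """
    slices = _ordered_slices(roi_mask)
    if len(slices) < 2:
        raise ValueError("ROI spans a single coronal slice; no longitudinal split")
    counts = np.array([len(v) for _, v in slices])
    total = counts.sum()
    # k = number of posterior (low-y) slices; pick k minimizing imbalance,
    # ties -> smallest k (more slices anterior)
    best_k, best_imb = None, None
    cum = np.cumsum(counts)
    for k in range(1, len(slices)):
        imb = abs(cum[k - 1] - (total - cum[k - 1]))
        if best_imb is None or imb < best_imb:
            best_k, best_imb = k, imb
    voxels = np.vstack([v for _, v in slices])
    slice_index = np.concatenate([np.full(len(v), y) for y, v in slices])
    longitudinal = np.concatenate([
        np.full(len(v), POSTERIOR if i < best_k else ANTERIOR, dtype=object)
        for i, (_, v) in enumerate(slices)])
    return SectionAssignment(voxels, slice_index, longitudinal=longitudinal,
                             mask=np.asarray(roi_mask, dtype=bool))


def _bin_counts(n: int, n_bins: int) -> list[int]:
    base, rem = divmod(n, n_bins)
    return [base + (1 if b < rem else 0) for b in range(n_bins)]


def split_transverse_per_slice(roi_mask: np.ndarray, n_bins: int) -> SectionAssignment:
    """Per-coronal-slice equal-count transverse bins, bin 1 most lateral."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    slices = _ordered_slices(roi_mask)
    if not slices:
        raise ValueError("empty ROI mask")
    vox_all, slice_idx, bins = [], [], []
    for y, vox in slices:
        if len(vox) < n_bins:
            raise ValueError(
                f"coronal slice y={y} has {len(vox)} voxels < {n_bins} bins")
        counts = _bin_counts(len(vox), n_bins)
        b = np.repeat(np.arange(1, n_bins + 1), counts)
        vox_all.append(vox)
        slice_idx.append(np.full(len(vox), y))
        bins.append(b)
    voxels = np.vstack(vox_all)
    bins = np.concatenate(bins)
    assignment = SectionAssignment(voxels, np.concatenate(slice_idx),
                                   mask=np.asarray(roi_mask, dtype=bool))
    if n_bins == 2:
        assignment.transverse_half = np.where(bins == 1, LATERAL, MEDIAL).astype(object)
    else:
        assignment.transverse_quintile = bins
    return assignment


def assign_sections(roi_mask: np.ndarray, n_bins: int = 5) -> SectionAssignment:
    """Combined longitudinal halves, transverse halves and transverse bins."""
    lon = split_longitudinal(roi_mask)
    halves = split_transverse_per_slice(roi_mask, 2)
    quint = split_transverse_per_slice(roi_mask, n_bins)
    # all three use the same deterministic per-slice ordering
    assert np.array_equal(lon.voxels, halves.voxels)
    assert np.array_equal(lon.voxels, quint.voxels)
    lon.transverse_half = halves.transverse_half
    lon.transverse_quintile = quint.transverse_quintile
    return lon


def section_means(fz_map: FisherZMap, sections: SectionAssignment,
                  seed_id: str | None = None) -> pd.DataFrame:
    """Mean z per (longitudinal, transverse) cell for one subject map."""
    if sections.longitudinal is None or sections.transverse_half is None:
        raise ValueError("sections must carry longitudinal and transverse halves")
    values = fz_map.values[tuple(sections.voxels.T)]
    if np.isnan(values).any():
        raise ValueError("section voxels fall outside the map's target mask")
    rows = []
    for lon in (ANTERIOR, POSTERIOR):
        for trans in (LATERAL, MEDIAL):
            sel = sections.cell_mask(lon, trans)
            if not sel.any():
                raise ValueError(f"empty section cell ({lon}, {trans})")
            rows.append(dict(subject_id=fz_map.subject_id,
                             seed_id=seed_id or fz_map.seed_id,
                             longitudinal=lon, transverse=trans,
                             mean_z=float(values[sel].mean())))
    return pd.DataFrame(rows)


def cell_means_table(maps_by_seed: dict[str, list[FisherZMap]],
                     sections: SectionAssignment) -> pd.DataFrame:
    """Subject x seed x section cell means for a set of seed map lists."""
    return pd.concat([section_means(m, sections, seed_id=seed)
                      for seed, maps in maps_by_seed.items() for m in maps],
                     ignore_index=True)


_EFFECTS = {
    "seed": ("seed", None, None),
    "longitudinal": (None, "lon", None),
    "transverse": (None, None, "trans"),
    "seed x longitudinal": ("seed", "lon", None),
    "seed x transverse": ("seed", None, "trans"),
    "longitudinal x transverse": (None, "lon", "trans"),
    "seed x longitudinal x transverse": ("seed", "lon", "trans"),
}


def _contrast_scores(table: pd.DataFrame, effect: str) -> np.ndarray:
    """Per-subject +/-1 contrast score over the 8 cells for one effect."""
    seeds = sorted(table.seed_id.unique())
    if len(seeds) != 2:
        raise ValueError(f"need exactly 2 seeds, got {seeds}")
    use_seed, use_lon, use_trans = _EFFECTS[effect]
    piv = table.pivot_table(index="subject_id",
                            columns=["seed_id", "longitudinal", "transverse"],
                            values="mean_z")
    expected = [(s, l, t) for s in seeds for l in (ANTERIOR, POSTERIOR)
                for t in (LATERAL, MEDIAL)]
    missing = [c for c in expected if c not in piv.columns or piv[c].isna().any()]
    if missing:
        raise ValueError(f"incomplete cells: {missing}")
    pattern = np.array([
        (1.0 if use_seed is None else (1.0 if s == seeds[0] else -1.0))
        * (1.0 if use_lon is None else (1.0 if l == ANTERIOR else -1.0))
        * (1.0 if use_trans is None else (1.0 if t == LATERAL else -1.0))
        for (s, l, t) in expected
    ])
    cells = piv[expected].to_numpy(dtype=float)
    return cells @ pattern / 8.0


def rm_anova_2x2x2(table: pd.DataFrame) -> list[AnovaResult]:
    """All-within 2x2x2 repeated-measures ANOVA via contrast scores.

    Each main effect and interaction has df1 = 1, so its F equals the squared
    one-sample t of the per-subject +/-1 contrast score over the 8 cells;
    df = (1, n - 1) and p comes from the F distribution.
    """
    results = []
    n = table.subject_id.nunique()
    for effect in _EFFECTS:
        scores = _contrast_scores(table, effect)
        mean = scores.mean()
        sd = scores.std(ddof=1)
        if sd == 0:
            f_val = 0.0 if mean == 0 else np.inf
        else:
            f_val = float((mean / (sd / np.sqrt(n))) ** 2)
        p = float(stats.f.sf(f_val, 1, n - 1)) if np.isfinite(f_val) else 0.0
        results.append(AnovaResult(effect, f_val, (1, n - 1), p))
    return results


def anova_effect(results: list[AnovaResult], effect: str) -> AnovaResult:
    for r in results:
        if r.effect == effect:
            return r
    raise KeyError(effect)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t with the degenerate all-equal case mapped to (t=0, p=1)."""
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def paired_followup(table: pd.DataFrame, cell_a: dict, cell_b: dict) -> tuple[float, float]:
    """Paired t-test across subjects between two (possibly partial) cells.

    Cells are dicts over columns (seed_id, longitudinal, transverse); rows
    matching a partial cell are averaged per subject first.  Returns (t,
    two-sided p).
    """
    def per_subject(cell: dict) -> pd.Series:
        sel = table
        for key, val in cell.items():
            sel = sel[sel[key] == val]
        if sel.empty:
            raise ValueError(f"no rows match cell {cell}")
        return sel.groupby("subject_id").mean_z.mean()

    a = per_subject(cell_a)
    b = per_subject(cell_b)
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need >= 2 subjects with both cells")
    return _paired_t(a[common].to_numpy(), b[common].to_numpy())


def slice_profiles(maps_by_seed: dict[str, list[FisherZMap]],
                   sections: SectionAssignment, axis: str) -> SliceProfile:
    """Across-subject mean +/- SEM per slice (longitudinal) or per bin.

    ``axis="longitudinal"``: one position per coronal slice.
    ``axis="transverse"``: bins 1..k pooled across slices (1 most lateral).
    """
    if axis == "longitudinal":
        positions = sections.slice_index
    elif axis == "transverse":
        if sections.transverse_quintile is None:
            raise ValueError("sections carry no transverse bins")
        positions = sections.transverse_quintile
    else:
        raise ValueError(f"unknown axis {axis!r}")
    rows = []
    for seed, maps in maps_by_seed.items():
        for pos in np.unique(positions):
            sel = positions == pos
            subj_means = [float(m.values[tuple(sections.voxels[sel].T)].mean())
                          for m in maps]
            rows.append(dict(seed_id=seed, position=int(pos),
                             mean=float(np.mean(subj_means)),
                             sem=float(stats.sem(subj_means)) if len(subj_means) > 1 else 0.0,
                             n=len(subj_means)))
    return SliceProfile(axis, pd.DataFrame(rows))


def end_slices_contrast(maps_a: list[FisherZMap], maps_b: list[FisherZMap],
                        sections: SectionAssignment, k: int = 8,
                        end: str = ANTERIOR) -> tuple[float, float]:
    """Paired t of seed-a vs seed-b mean connectivity over the k end slices."""
    ys = np.unique(sections.slice_index)
    if len(ys) < k:
        raise ValueError(f"ROI has {len(ys)} slices < k={k}")
    chosen = ys[-k:] if end == ANTERIOR else ys[:k]
    sel = np.isin(sections.slice_index, chosen)
    vox = tuple(sections.voxels[sel].T)
    a = np.array([float(m.values[vox].mean()) for m in maps_a])
    b = np.array([float(m.values[vox].mean()) for m in maps_b])
    return _paired_t(a, b)


def delta_interaction(ec_table: pd.DataFrame, ctx_table: pd.DataFrame,
                      ec_pair: tuple[str, str] | None = None,
                      ctx_pair: tuple[str, str] | None = None) -> AnovaResult:
    """Seed-pair (delta-EC vs delta-neocortex) x longitudinal-section ANOVA.

    For each subject and longitudinal section, delta_EC is the al-EC minus
    pm-EC connectivity difference and delta_ctx the PRC minus PHC difference
    (each averaged over transverse cells).  The 2x2 within-subject
    interaction F equals the squared paired t of the difference of the
    anterior-minus-posterior slopes.  ``ec_pair`` / ``ctx_pair`` give the
    minuend/subtrahend seed ids (default: alphabetical order).
    """
    def slopes(table: pd.DataFrame, pair: tuple[str, str] | None) -> pd.Series:
        seeds = list(pair) if pair is not None else sorted(table.seed_id.unique())
        if len(seeds) != 2 or not set(seeds) <= set(table.seed_id.unique()):
            raise ValueError(f"need exactly 2 seeds present in the table, got {seeds}")
        piv = table.pivot_table(index="subject_id",
                                columns=["seed_id", "longitudinal"],
                                values="mean_z")
        delta = (piv[seeds[0]] - piv[seeds[1]])
        return delta[ANTERIOR] - delta[POSTERIOR]

    s_ec = slopes(ec_table, ec_pair)
    s_ctx = slopes(ctx_table, ctx_pair)
    if not s_ec.index.equals(s_ctx.index):
        raise ValueError("subject sets of the two tables differ")
    d = (s_ec - s_ctx).to_numpy(dtype=float)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        f_val = 0.0 if np.allclose(d, 0) else np.inf
    else:
        f_val = float((d.mean() / (sd / np.sqrt(n))) ** 2)
    p = float(stats.f.sf(f_val, 1, n - 1)) if np.isfinite(f_val) else 0.0
    return AnovaResult("seed-pair x longitudinal", f_val, (1, n - 1), p)
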