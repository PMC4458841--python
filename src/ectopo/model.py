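"""Model/Results facade tying the pipeline stages together.

``ConnectivityTopography`` is built from a cohort (simulated or loaded) and a
choice of seed regions and target ROI; ``fit`` runs first-level connectivity
mapping for every subject, the group statistics (paired-contrast cluster
inference, preference maps, sectional ANOVA) and the cross-subject
coordinate classifier, returning a ``TopographyResults`` object with a
``summary()`` table.

First-level maps are computed by a vectorized path that filters all in-atlas
voxel series once per subject; because seed averaging, nuisance regression
and band-pass filtering are linear, this equals applying
:func:`ectopo.connectivity.seed_to_voxel_map` seed by seed (asserted in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from . import group_maps as gm
from . import topography_stats as ts
from .atlas import CSF, LABEL_CODES, WM, LabeledAtlas
from .cohort import Cohort, SubjectDataset
from .connectivity import (FisherZMap, _correlate_with_seed, bandpass,
                           effective_df, fisher_z, regress_nuisance,
                           z_standardize)
from .preprocess import (build_task_design, detect_spikes, erode_seed_border,
                         gaussian_smooth, remove_task_effects,
                         threshold_roi_intensity)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis parameters (defaults follow the 7T protocol)."""

    fwhm_mm: float = 1.5
    band: tuple[float, float] = (0.01, 0.1)
    intensity_pct: float = 1.3
    motion_mm: float = 0.3
    gap_voxels: int = 2
    roi_intensity_threshold: bool = True
    z_thresh: float = 2.3
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    loso_n_iter: int = 1000
    svm_cost: float = 1.0
    n_bins: int = 5
    run_clusters: bool = True
    run_classifier: bool = True


def _prepare_subject(ds: SubjectDataset, atlas: LabeledAtlas,
                     config: PipelineConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Spike flagging, smoothing, task residualization and filtering.

    Returns (filtered (V, t) series of all in-atlas voxels, in-atlas index
    grid, per-subject QC info).  ``filtered`` is nuisance-regressed and
    band-passed, ready for correlation.
    """
    in_atlas = atlas.in_atlas_mask()
    raw_global = ds.bold[in_atlas].mean(axis=0)
    spikes = detect_spikes(raw_global, ds.motion, config.intensity_pct,
                           config.motion_mm)
    bold = (gaussian_smooth(ds.bold, config.fwhm_mm, atlas.voxel_size)
            if config.fwhm_mm > 0 else ds.bold)
    series = np.asarray(bold[in_atlas], dtype=float)
    design = build_task_design(ds.events, ds.motion, spikes, ds.tr, ds.n_volumes)
    resid = remove_task_effects(series, design)

    flat = atlas.labels[in_atlas]
    nuisance_cols = [resid[flat == WM].mean(axis=0),
                     resid[flat == CSF].mean(axis=0)]
    nuisance = np.column_stack(nuisance_cols + [ds.motion]
                               + [spikes.indicator_matrix(ds.n_volumes)])
    filtered = regress_nuisance(resid, nuisance)
    filtered = bandpass(filtered, config.band[0], config.band[1], ds.tr)
    qc = dict(spikes=sorted(spikes.flagged_volumes), n_nuisance=nuisance.shape[1],
              tmean=series.mean(axis=1))
    return filtered, in_atlas, qc


def _condition_seed(base_mask: np.ndarray, target_mask: np.ndarray,
                    in_atlas: np.ndarray, tmean_flat: np.ndarray,
                    config: PipelineConfig) -> np.ndarray:
    """Per-subject seed conditioning: intensity thresholding + border erosion."""
    mask = np.asarray(base_mask, dtype=bool)
    if config.roi_intensity_threshold:
        tmean = np.zeros(in_atlas.shape)
        tmean[in_atlas] = tmean_flat
        mask = threshold_roi_intensity(mask, tmean[..., None])
    return erode_seed_border(mask, target_mask, config.gap_voxels)


def _first_level_subject_both(ds: SubjectDataset, atlas: LabeledAtlas,
                              seed_masks: dict[str, np.ndarray],
                              config: PipelineConfig
                              ) -> tuple[dict[str, FisherZMap], dict[str, FisherZMap]]:
    """(standardized, raw) Fisher-z maps of every seed over non-seed voxels."""
    filtered, in_atlas, qc = _prepare_subject(ds, atlas, config)
    all_seed_voxels = np.zeros(in_atlas.shape, dtype=bool)
    for m in seed_masks.values():
        all_seed_voxels |= np.asarray(m, dtype=bool)
    target = in_atlas & ~all_seed_voxels
    std_maps, raw_maps = {}, {}
    for seed_id, base_mask in seed_masks.items():
        seed = _condition_seed(base_mask, target, in_atlas, qc["tmean"], config)
        seed_series = filtered[seed[in_atlas]].mean(axis=0)
        r, zero = _correlate_with_seed(seed_series, filtered[target[in_atlas]])
        values = np.full(in_atlas.shape, np.nan)
        values[target] = fisher_z(r)
        fz = FisherZMap(values=values, target_mask=target,
                        subject_id=ds.subject_id, seed_id=seed_id,
                        band=config.band,
                        df_effective=effective_df(ds.n_volumes, qc["n_nuisance"],
                                                  config.band, ds.tr),
                        qc_zero_variance=[tuple(v) for v in
                                          np.argwhere(target)[zero]])
        raw_maps[seed_id] = fz
        std_maps[seed_id] = z_standardize(fz, target)
    return std_maps, raw_maps


def first_level_subject(ds: SubjectDataset, atlas: LabeledAtlas,
                        seed_masks: dict[str, np.ndarray],
                        config: PipelineConfig | None = None,
                        standardize: bool = True) -> dict[str, FisherZMap]:
    """Fisher-z maps of every seed over all non-seed atlas voxels.

    Maps are Z-standardized over the computed voxels (the form entering group
    statistics) unless ``standardize=False``.
    """
    std_maps, raw_maps = _first_level_subject_both(ds, atlas, seed_masks,
                                                   config or PipelineConfig())
    return std_maps if standardize else raw_maps


def restrict_map(fz: FisherZMap, region_mask: np.ndarray) -> FisherZMap:
    """Restrict a map to a region (for group stats over one target ROI)."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if (region_mask & ~fz.target_mask).any():
        raise ValueError("region extends outside the computed map")
    values = np.where(region_mask, fz.values, np.nan)
    return FisherZMap(values, region_mask, fz.subject_id, fz.seed_id,
                      fz.band, fz.df_effective, list(fz.qc_zero_variance))


def first_level_cohort(cohort: Cohort, seed_masks: dict[str, np.ndarray],
                       config: PipelineConfig | None = None,
                       verbose: bool = False, return_raw: bool = False):
    """First-level maps for every subject, streaming one subject at a time.

    Returns ``{seed: [FisherZMap, ...]}`` of standardized maps; with
    ``return_raw=True`` a pair of (standardized, raw) such dicts.
    """
    config = config or PipelineConfig()
    out: dict[str, list[FisherZMap]] = {s: [] for s in seed_masks}
    raw: dict[str, list[FisherZMap]] = {s: [] for s in seed_masks}
    for i in range(len(cohort)):
        ds = cohort.subject(i)
        std_maps, raw_maps = _first_level_subject_both(ds, cohort.atlas,
                                                       seed_masks, config)
        for s in seed_masks:
            out[s].append(std_maps[s])
            raw[s].append(raw_maps[s])
        if verbose:
            print(f"  first level: subject {i + 1}/{len(cohort)} done")
    return (out, raw) if return_raw else out


@dataclass
class TopographyResults:
    """Fitted group-level topography of one seed pair over one target ROI."""

    model: "ConnectivityTopography"
    subject_maps: dict
    paired_map: gm.GroupStatMap | None
    clusters_pos: gm.ClusterTable | None
    clusters_neg: gm.ClusterTable | None
    group_preference: gm.PreferenceMap | None
    sections: ts.SectionAssignment
    cell_means: pd.DataFrame
    anova: list
    loso: clf.LosoResult | None = None
    permutation: clf.PermutationResult | None = None
    consistency: clf.ConsistencyMap | None = None
    parcels: clf.PredictedParcels | None = None
    one_sample: dict = field(default_factory=dict)

    @property
    def seeds(self) -> tuple[str, str]:
        return self.model.seeds

    def anova_effect(self, effect: str) -> ts.AnovaResult:
        return ts.anova_effect(self.anova, effect)

    def subregion_seeds(self) -> gm.SeedRegionPair:
        """al-EC / pm-EC seed masks from the significant paired clusters."""
        return gm.derive_subregion_seeds(self.clusters_pos, self.clusters_neg,
                                         self.model.region_mask)

    def slice_profile(self, axis: str) -> ts.SliceProfile:
        return ts.slice_profiles(self.subject_maps, self.sections, axis)

    def plot_profiles(self, ax=None):
        """Slice-by-slice longitudinal connectivity profile (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.slice_profile("longitudinal").table
        for seed, sub in prof.groupby("seed_id"):
            ax.errorbar(sub.position, sub["mean"], yerr=sub["sem"], label=seed)
        ax.set_xlabel("coronal slice (posterior → anterior)")
        ax.set_ylabel("mean standardized Fisher z")
        ax.legend()
        return ax

    def summary(self) -> str:
        a, b = self.seeds
        n = len(next(iter(self.subject_maps.values())))
        lines = [
            "        Connectivity Topography Results",
            "=" * 52,
            f"Target ROI: {self.model.target}   Seeds: {a} vs {b}",
            f"Subjects: {n}   Target voxels: {int(self.model.region_mask.sum())}",
            "-" * 52,
            "Within-subject ANOVA (2 x 2 x 2)",
            f"{'effect':<34}{'F':>8}{'p':>10}",
        ]
        for r in self.anova:
            lines.append(f"{r.effect:<34}{r.F:>8.2f}{r.p:>10.4g}")
        if self.clusters_pos is not None:
            for name, tab in ((f"{a}>{b}", self.clusters_pos),
                              (f"{b}>{a}", self.clusters_neg)):
                sig = tab.significant()
                best = f", min p_fwe={sig.p_fwe.min():.4g}" if len(sig) else ""
                lines.append(f"Clusters {name}: {len(sig)} significant "
                             f"of {len(tab)} (n_perm={tab.n_perm}){best}")
        if self.loso is not None:
            lines.append(f"LOSO mean accuracy: {self.loso.mean_accuracy:.3f}"
                         + (f"   permutation p: {self.permutation.p:.4g}"
                            f" (n_iter={self.permutation.n_iter})"
                            if self.permutation is not None else ""))
        lines.append("=" * 52)
        return "\n".join(lines)


class ConnectivityTopography:
    """Seed-pair connectivity-topography model over one target ROI.

    Parameters
    ----------
    cohort
        A :class:`~ectopo.cohort.Cohort` (subjects sharing one atlas).
    seeds
        Two seed identifiers; atlas region names ("PRC", "PHC") or keys of
        ``seed_masks``.
    target
        Target ROI name ("EC" or "SUB").
    seed_masks
        Optional explicit seed masks (e.g. derived al-EC / pm-EC regions).
    config
        :class:`PipelineConfig`; defaults follow the acquisition protocol the
        synthetic cohorts emulate.
    """

    def __init__(self, cohort: Cohort, seeds: tuple[str, str] = ("PRC", "PHC"),
                 target: str = "EC", seed_masks: dict | None = None,
                 config: PipelineConfig | None = None):
        self.cohort = cohort
        self.atlas: LabeledAtlas = cohort.atlas
        self.seeds = tuple(seeds)
        self.target = target
        self.config = config or PipelineConfig()
        if seed_masks is None:
            seed_masks = {s: self.atlas.mask(LABEL_CODES[s]) for s in self.seeds}
        self.seed_masks = {s: np.asarray(seed_masks[s], dtype=bool) for s in self.seeds}
        self.region_mask = self.atlas.mask(LABEL_CODES[target])
        self._precomputed: dict | None = None

    @classmethod
    def from_subject_maps(cls, cohort: Cohort, maps_by_seed: dict,
                          target: str, config: PipelineConfig | None = None,
                          raw_maps_by_seed: dict | None = None
                          ) -> "ConnectivityTopography":
        """Build the model around precomputed first-level maps.

        ``raw_maps_by_seed`` optionally supplies the unstandardized maps the
        classifier labels derive from; the standardized maps stand in when
        omitted.
        """
        seeds = tuple(maps_by_seed)
        model = cls(cohort, seeds=seeds, target=target,
                    seed_masks={s: np.zeros(cohort.atlas.grid_shape, dtype=bool)
                                for s in seeds},
                    config=config)
        model._precomputed = (maps_by_seed, raw_maps_by_seed or maps_by_seed)
        return model

    def fit(self, seed: int = 0, verbose: bool = False) -> TopographyResults:
        cfg = self.config
        if self._precomputed is None:
            std, raw = first_level_cohort(self.cohort, self.seed_masks, cfg,
                                          verbose, return_raw=True)
        else:
            std, raw = self._precomputed
        maps = {s: [restrict_map(m, self.region_mask) for m in std[s]]
                for s in self.seeds}
        a, b = self.seeds

        paired = clusters_pos = clusters_neg = pref = None
        if cfg.run_clusters:
            paired, clusters_pos, clusters_neg = gm.paired_cluster_analysis(
                maps[a], maps[b], cfg.z_thresh, cfg.cluster_alpha,
                cfg.n_perm, seed=seed)
            pref = gm.preference_map(paired)
        else:
            paired = gm.paired_t(maps[a], maps[b], contrast_id=f"{a}>{b}")
            pref = gm.preference_map(paired)

        try:
            sections = ts.assign_sections(self.region_mask, cfg.n_bins)
        except ValueError:
            sections = ts.assign_sections(self.region_mask, 2)
        cell_means = ts.cell_means_table(maps, sections)
        anova = ts.rm_anova_2x2x2(cell_means)

        loso = perm = cons = parcels = None
        if cfg.run_classifier:
            # classifier labels come from the raw Fisher-z difference sign;
            # per-map standardization would couple voxels within a subject
            subj_pref = [gm.subject_preference_map(restrict_map(ma, self.region_mask),
                                                   restrict_map(mb, self.region_mask))
                         for ma, mb in zip(raw[a], raw[b])]
            ds = clf.assemble_samples(subj_pref, self.region_mask)
            loso = clf.loso_svm(ds, cfg.svm_cost)
            perm = clf.permutation_null(ds, loso, cfg.loso_n_iter,
                                        seed=seed + 1, svm_cost=cfg.svm_cost)
            cons = clf.consistency_map(loso, ds)
            parcels = clf.predicted_parcels(loso, self.region_mask)

        one_sample = {s: gm.one_sample_t(maps[s], contrast_id=s) for s in self.seeds}
        return TopographyResults(
            model=self, subject_maps=maps, paired_map=paired,
            clusters_pos=clusters_pos, clusters_neg=clusters_neg,
            group_preference=pref, sections=sections, cell_means=cell_means,
            anova=anova, loso=loso, permutation=perm, consistency=cons,
            parcels=parcels, one_sample=one_sample)
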