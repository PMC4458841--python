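"""Synthetic BOLD cohorts with a planted connectivity topography.

Every subject is generated on one shared template atlas (a stand-in for
template registration, which this package does not model).  Two neocortical
seed compartments (PRC, PHC) emit coherent band-limited latent signals; EC
voxels mix them with weights following a smooth logistic gradient running
anterior-lateral -> posterior-medial, and subiculum voxels mix EC-subregion
composite signals along a proximo-distal gradient with extra direct seed
coupling in the longitudinal end slices.  On top of the planted signals each
voxel receives AR(1) noise, slow drift, motion-coupled nuisance, globally
leaking WM/CSF compartment signals, occasional global-intensity spikes, and
HRF-convolved task-evoked responses.

The defaults are the study conditions every downstream statistic is validated
against; see ``docs/methods.md`` for what they emulate and what they do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import expit

from .atlas import CSF, EC, GREY_LABELS, PHC, PRC, SUB, WM, LabeledAtlas

_MIN_VOLUMES = 50


@dataclass(frozen=True)
class TopographySpec:
    """Ground-truth topography planted in the EC and subiculum.

    ``gradient_direction`` is a vector in index space along which the PHC
    weight ``w`` of EC voxels increases (default: toward posterior [-y],
    medial [+x], dorsal [+z]).  ``w(v) = logistic(mixing_steepness *
    <v - centroid, direction>)``.

    ``seed_coupling`` / ``subregion_coupling`` split each EC voxel's planted
    signal between the neocortical seed latents and private EC-subregion
    latents: with couplings (c_s, c_o) the voxel carries
    ``c_s * [(1-w) L_PRC + w L_PHC] + c_o * [(1-w) E_al + w E_pm]``.
    The default (1, 0) is pure direct mixing.  Weak seed coupling with strong
    private components is what lets the subiculum inherit EC-subregion
    gradients that are *not* reducible to PRC/PHC connectivity.

    ``end_coupling`` adds direct PRC (resp. PHC) latent signal to the most
    anterior (resp. posterior) ``end_slices`` subiculum slices.
    ``amplitude`` scales every planted (non-nuisance) signal; 0 gives a null
    cohort with no seed-target connectivity at all.
    """

    gradient_direction: tuple[float, float, float] = (0.6, -1.0, 0.3)
    mixing_steepness: float = 0.25
    sub_transverse_steepness: float = 0.5
    end_coupling: float = 0.4
    end_slices: int = 8
    seed_coupling: float = 1.0
    subregion_coupling: float = 0.0
    amplitude: float = 1.0
    #: reference PHC-weights defining the al-EC-like / pm-EC-like composites
    #: that the subiculum mixes
    w_al_ref: float = 0.2
    w_pm_ref: float = 0.8

    def __post_init__(self):
        if np.linalg.norm(self.gradient_direction) == 0:
            raise ValueError("gradient_direction must be a non-zero vector")
        if self.mixing_steepness < 0 or self.sub_transverse_steepness < 0:
            raise ValueError("steepness parameters must be >= 0")

    @classmethod
    def null(cls) -> "TopographySpec":
        """No planted seed-target connectivity (calibration condition)."""
        return cls(amplitude=0.0, end_coupling=0.0)

    @classmethod
    def subiculum_study(cls) -> "TopographySpec":
        """EC-subregion signals orthogonal to the neocortical seed latents.

        The study plants a double dissociation: the subiculum inherits a
        proximo-distal gradient of EC-subregion signals but a longitudinal
        (end-slice) gradient only of direct PRC/PHC coupling.  Any shared
        component between EC-subregion and seed latents turns the planted
        end-coupling into a true longitudinal effect for the EC seeds as
        well (the leak scales with ``seed_coupling``), so the dissociated
        ground truth requires orthogonal subregion signals.
        """
        return cls(seed_coupling=0.0, subregion_coupling=1.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic nuisance structure of a synthetic run.

    Amplitudes are in BOLD signal units (the planted latents have unit SD
    before scaling); ``spike_magnitude`` is percent of mean intensity.
    """

    ar1_coefficient: float = 0.3
    latent_signal_sd: float = 1.0
    noise_sd: float = 1.0
    drift_amplitude: float = 2.0
    motion_coupling: float = 0.5
    spike_rate: float = 0.02
    spike_magnitude: float = 2.0
    baseline: float = 1000.0
    compartment_sd: float = 1.0    # WM/CSF own fluctuations
    global_leak: float = 0.25      # fraction of compartment signal leaking everywhere

    def __post_init__(self):
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        for name in ("latent_signal_sd", "noise_sd", "drift_amplitude",
                     "motion_coupling", "spike_rate", "spike_magnitude",
                     "compartment_sd", "global_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(ar1_coefficient=0.0, noise_sd=0.0, drift_amplitude=0.0,
                   motion_coupling=0.0, spike_rate=0.0, compartment_sd=0.0,
                   global_leak=0.0)


@dataclass(frozen=True)
class TaskSpec:
    """Event table of the (to-be-residualized) task."""

    events: tuple[tuple[float, float, str], ...] = ()  # (onset s, duration s, condition)
    amplitudes: dict = field(default_factory=dict)     # condition -> signal units

    def conditions(self) -> list[str]:
        return sorted({c for _, _, c in self.events})

    def validate(self, run_length_s: float) -> None:
        for onset, duration, cond in self.events:
            if onset < 0 or onset >= run_length_s:
                raise ValueError(f"event onset {onset} outside run [0, {run_length_s})")
            if duration <= 0:
                raise ValueError(f"event duration must be > 0, got {duration}")
            if cond not in self.amplitudes:
                raise ValueError(f"no amplitude given for condition {cond!r}")

    @classmethod
    def empty(cls) -> "TaskSpec":
        return cls()

    @classmethod
    def default(cls, n_volumes: int = 370, tr: float = 2.0,
                seed: int = 0) -> "TaskSpec":
        """Two alternating conditions, ~12 s ISI with jitter, 3 s events."""
        rng = np.random.default_rng(seed)
        run = n_volumes * tr
        events = []
        t = 10.0
        i = 0
        while t < run - 20.0:
            events.append((round(t, 2), 3.0, "cond_a" if i % 2 == 0 else "cond_b"))
            t += 12.0 + rng.uniform(0.0, 6.0)
            i += 1
        return cls(tuple(events), {"cond_a": 3.0, "cond_b": 2.0})


@dataclass
class GroundTruth:
    """Planted per-voxel mixing weights and the implied labels.

    ``ec_weight`` holds w(v) (PHC-signal weight) over the EC mask, NaN
    elsewhere; ``ec_label`` is PRC for w <= 0.5 (ties deterministically PRC)
    and PHC for w > 0.5.  ``sub_weight`` is the proximo-distal transverse
    weight over the subiculum.
    """

    ec_weight: np.ndarray
    ec_label: np.ndarray          # 0 outside EC, PRC or PHC inside
    sub_weight: np.ndarray
    topo: TopographySpec

    def al_ec_mask(self) -> np.ndarray:
        return self.ec_label == PRC

    def pm_ec_mask(self) -> np.ndarray:
        return self.ec_label == PHC


@dataclass
class SubjectDataset:
    """One subject's 4D BOLD grid plus motion, events and metadata."""

    bold: np.ndarray              # (x, y, z, t)
    tr: float
    n_volumes: int
    motion: np.ndarray            # (t, 6): 3 translations mm, 3 rotations rad
    events: TaskSpec
    subject_id: str
    rng_seed: int
    planted_spikes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    latents: dict = field(default_factory=dict)


def plant_topography(atlas: LabeledAtlas, topo: TopographySpec | None = None) -> GroundTruth:
    """Compute the ground-truth mixing weights for an atlas.

    EC: ``w = logistic(steepness * <v - centroid, g>)`` with ``g`` the unit
    gradient direction; monotone non-decreasing along ``g``.  Subiculum: a
    per-coronal-slice logistic along the slice's transverse axis (proximal ->
    distal).  For a bilateral atlas the x component of the gradient is
    mirrored per hemisphere so "medial" keeps its meaning.
    """
    topo = topo or TopographySpec()
    g = np.asarray(topo.gradient_direction, dtype=float)
    g = g / np.linalg.norm(g)
    shape = atlas.grid_shape
    ec_weight = np.full(shape, np.nan)
    ec_label = np.zeros(shape, dtype=np.int8)
    sub_weight = np.full(shape, np.nan)

    for hemi in atlas.hemisphere_masks():
        ec_mask = atlas.mask(EC) & hemi
        if ec_mask.any():
            coords = np.argwhere(ec_mask).astype(float)
            g_h = g.copy()
            # mirrored hemisphere: medial direction flips in index space
            if atlas.spec.bilateral and coords[:, 0].mean() < atlas.grid_shape[0] / 2:
                g_h[0] = -g_h[0]
            proj = (coords - coords.mean(axis=0)) @ g_h
            w = expit(topo.mixing_steepness * proj)
            idx = tuple(np.argwhere(ec_mask).T)
            ec_weight[idx] = w
            ec_label[idx] = np.where(w > 0.5, PHC, PRC)

        sub_mask = atlas.mask(SUB) & hemi
        if sub_mask.any():
            for y, vox in LabeledAtlas(np.where(hemi, atlas.labels, 0),
                                       atlas.voxel_size, atlas.spec).coronal_slices(SUB).items():
                # voxels already ordered proximal (lateral) -> distal (medial)
                k = len(vox)
                pos = np.arange(k, dtype=float) - (k - 1) / 2.0
                m = expit(topo.sub_transverse_steepness * pos)
                sub_weight[tuple(vox.T)] = m
    return GroundTruth(ec_weight, ec_label, sub_weight, topo)


def _band_limited_latents(rng: np.ndarray, n: int, t: int, tr: float) -> np.ndarray:
    """(n, t) unit-SD Gaussian signals low-pass filtered at 0.1 Hz."""
    nyq = 0.5 / tr
    b, a = sps.butter(2, min(0.1 / nyq, 0.99), btype="low")
    x = sps.filtfilt(b, a, rng.standard_normal((n, t)), axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ar1(rng, n_vox: int, t: int, a: float, sd: float) -> np.ndarray:
    if sd == 0 or n_vox == 0:
        return np.zeros((n_vox, t))
    innov = rng.standard_normal((n_vox, t)) * (sd * math.sqrt(1.0 - a * a))
    if a == 0:
        return innov
    return sps.lfilter([1.0], [1.0, -a], innov, axis=1)


def hrf_double_gamma(t: np.ndarray, peak: float = 5.0, undershoot: float = 15.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at times ``t`` (s).

    Gamma densities with unit scale peaking at ``peak`` and ``undershoot``
    seconds; the undershoot is divided by ``ratio``.  Normalized to peak 1.
    """
    from scipy.stats import gamma

    h = gamma.pdf(t, a=peak + 1.0) - gamma.pdf(t, a=undershoot + 1.0) / ratio
    m = h.max()
    return h / m if m > 0 else h


def task_regressors(task: TaskSpec, tr: float, n_volumes: int) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved boxcar regressors sampled at volume times.

    Boxcars are built on a 0.1 s grid, convolved with the double-gamma HRF
    and decimated to the TR grid.  Returns (n_volumes, n_conditions) and the
    condition names.
    """
    conds = task.conditions()
    if not conds:
        return np.zeros((n_volumes, 0)), []
    dt = 0.1
    run = n_volumes * tr
    n_fine = int(round(run / dt))
    hrf = hrf_double_gamma(np.arange(0, 32.0, dt))
    cols = np.zeros((n_volumes, len(conds)))
    for j, cond in enumerate(conds):
        box = np.zeros(n_fine)
        for onset, duration, c in task.events:
            if c != cond:
                continue
            i0 = int(round(onset / dt))
            i1 = min(n_fine, int(round((onset + duration) / dt)))
            box[i0:i1] = 1.0
        conv = np.convolve(box, hrf)[:n_fine]
        vol_idx = (np.arange(n_volumes) * tr / dt).astype(int)
        cols[:, j] = conv[np.minimum(vol_idx, n_fine - 1)]
    return cols, conds


def simulate_subject(atlas: LabeledAtlas, truth: GroundTruth,
                     noise: NoiseSpec | None = None, task: TaskSpec | None = None,
                     tr: float = 2.0, n_volumes: int = 370, seed: int = 0,
                     subject_id: str | None = None,
                     dtype=np.float64) -> SubjectDataset:
    """Generate one subject's 4D BOLD run; fully reproducible given ``seed``."""
    noise = noise or NoiseSpec()
    task = task if task is not None else TaskSpec.empty()
    if n_volumes < _MIN_VOLUMES:
        raise ValueError(
            f"n_volumes={n_volumes} < {_MIN_VOLUMES}: band-pass filtering and the "
            "group statistics are undefined at shorter run lengths")
    task.validate(n_volumes * tr)
    rng = np.random.default_rng(seed)
    topo = truth.topo
    shape = atlas.grid_shape
    t = n_volumes

    # latent signal bank (order fixed for reproducibility)
    lat = _band_limited_latents(rng, 6, t, tr) * noise.latent_signal_sd
    l_prc, l_phc, e_al, e_pm = lat[0], lat[1], lat[2], lat[3]
    c_wm = lat[4] / max(noise.latent_signal_sd, 1e-12) * noise.compartment_sd
    c_csf = lat[5] / max(noise.latent_signal_sd, 1e-12) * noise.compartment_sd

    amp = topo.amplitude
    comp_al = topo.seed_coupling * ((1 - topo.w_al_ref) * l_prc + topo.w_al_ref * l_phc) \
        + topo.subregion_coupling * ((1 - topo.w_al_ref) * e_al + topo.w_al_ref * e_pm)
    comp_pm = topo.seed_coupling * ((1 - topo.w_pm_ref) * l_prc + topo.w_pm_ref * l_phc) \
        + topo.subregion_coupling * ((1 - topo.w_pm_ref) * e_al + topo.w_pm_ref * e_pm)

    in_atlas = atlas.in_atlas_mask()
    vox = np.argwhere(in_atlas)
    lab = atlas.labels[tuple(vox.T)]
    n_vox = len(vox)

    series = _ar1(rng, n_vox, t, noise.ar1_coefficient, noise.noise_sd)
    series += noise.baseline

    # planted region signals
    is_prc = lab == PRC
    is_phc = lab == PHC
    series[is_prc] += amp * l_prc
    series[is_phc] += amp * l_phc
    is_ec = lab == EC
    if is_ec.any():
        w = truth.ec_weight[tuple(vox[is_ec].T)][:, None]
        seed_part = (1 - w) * l_prc + w * l_phc
        own_part = (1 - w) * e_al + w * e_pm
        series[is_ec] += amp * (topo.seed_coupling * seed_part
                                + topo.subregion_coupling * own_part)
    is_sub = lab == SUB
    if is_sub.any():
        m = truth.sub_weight[tuple(vox[is_sub].T)][:, None]
        series[is_sub] += amp * ((1 - m) * comp_al + m * comp_pm)
        sub_ys = sorted(atlas.coronal_slices(SUB))
        k = topo.end_slices
        ant = set(sub_ys[-k:])
        post = set(sub_ys[:k])
        ys = vox[is_sub, 1]
        end_sig = np.zeros((is_sub.sum(), t))
        end_sig[np.isin(ys, list(ant))] += amp * topo.end_coupling * l_prc
        end_sig[np.isin(ys, list(post))] += amp * topo.end_coupling * l_phc
        series[is_sub] += end_sig

    # WM / CSF compartment signals with a global leak
    series[lab == WM] += c_wm
    series[lab == CSF] += c_csf
    series += noise.global_leak * (c_wm + c_csf)

    # slow drift: per-voxel random combination of linear and quadratic trends
    if noise.drift_amplitude > 0:
        tt = np.linspace(-1.0, 1.0, t)
        basis = np.vstack([tt, 1.5 * tt ** 2 - 0.5])
        coef = rng.standard_normal((n_vox, 2)) * noise.drift_amplitude / 2.0
        series += coef @ basis

    # motion: random-walk realignment parameters and coupled intensity change
    steps = rng.standard_normal((t, 6)) * np.array([0.02] * 3 + [2e-4] * 3)
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)
    if noise.motion_coupling > 0:
        fd = np.abs(np.diff(motion[:, :3], axis=0)).sum(axis=1)
        fd = np.concatenate([[0.0], fd])
        series += (rng.standard_normal((n_vox, 1)) * noise.motion_coupling) * fd

    # task-evoked responses in grey-matter compartments
    x_task, conds = task_regressors(task, tr, t)
    if conds:
        grey = np.isin(lab, GREY_LABELS)
        for j, cond in enumerate(conds):
            a = task.amplitudes[cond]
            gains = rng.normal(a, 0.3 * abs(a), grey.sum())
            series[grey] += gains[:, None] * x_task[:, j]

    # global-intensity spikes
    spikes = np.array([], dtype=int)
    if noise.spike_rate > 0:
        spikes = np.flatnonzero(rng.random(t) < noise.spike_rate)
        for i in spikes:
            mag = noise.spike_magnitude / 100.0 * rng.uniform(1.0, 1.5)
            series[:, i] *= 1.0 + rng.choice([-1.0, 1.0]) * mag

    bold = np.zeros(shape + (t,), dtype=dtype)
    bold[tuple(vox.T)] = series
    return SubjectDataset(
        bold=bold, tr=tr, n_volumes=t, motion=motion, events=task,
        subject_id=subject_id or f"sub-{seed:04d}", rng_seed=seed,
        planted_spikes=spikes,
        latents={"PRC": l_prc, "PHC": l_phc, "E_al": e_al, "E_pm": e_pm,
                 "comp_al": comp_al, "comp_pm": comp_pm},
    )


class Cohort:
    """Lazy collection of subjects sharing one atlas and ground truth.

    Subjects are built on demand from per-subject derived seeds, so large
    cohorts never hold more than one 4D grid in memory unless materialized.
    """

    def __init__(self, atlas: LabeledAtlas, truth: GroundTruth, noise: NoiseSpec,
                 task_seed: int | None, n_subjects: int, seed: int,
                 tr: float = 2.0, n_volumes: int = 370, dtype=np.float64):
        self.atlas = atlas
        self.truth = truth
        self.noise = noise
        self.tr = tr
        self.n_volumes = n_volumes
        self.dtype = dtype
        self._task_seed = task_seed
        ss = np.random.SeedSequence(seed)
        self._subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in ss.spawn(n_subjects)]

    def __len__(self) -> int:
        return len(self._subject_seeds)

    def subject(self, i: int) -> SubjectDataset:
        s = self._subject_seeds[i]
        task = (TaskSpec.default(self.n_volumes, self.tr, seed=s)
                if self._task_seed is not None else TaskSpec.empty())
        return simulate_subject(self.atlas, self.truth, self.noise, task,
                                tr=self.tr, n_volumes=self.n_volumes, seed=s,
                                subject_id=f"sub-{i:02d}", dtype=self.dtype)

    def __iter__(self):
        return (self.subject(i) for i in range(len(self)))

    def materialize(self) -> list[SubjectDataset]:
        return list(self)


def simulate_cohort(n_subjects: int, atlas: LabeledAtlas, truth: GroundTruth,
                    noise: NoiseSpec | None = None, with_task: bool = True,
                    seed: int = 0, tr: float = 2.0, n_volumes: int = 370,
                    dtype=np.float64) -> Cohort:
    """Cohort of exchangeable subjects sharing the planted ground truth.

    Subjects differ in latent signals, noise, motion and task events via
    per-subject seeds derived from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2: group statistics are "
                         "undefined for a single subject")
    return Cohort(atlas, truth, noise or NoiseSpec(),
                  task_seed=seed if with_task else None,
                  n_subjects=n_subjects, seed=seed, tr=tr,
                  n_volumes=n_volumes, dtype=dtype)
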