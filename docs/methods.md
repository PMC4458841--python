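# Methods

This note documents the generative model behind the synthetic cohorts, the
analysis conventions, the numerical choices, and the study conditions the
test suite and `scripts/acceptance.py` run at. It states no result that those
runs do not themselves compute.

## Template atlas

All subjects live in one common voxel grid (default 40×60×24 voxels at
0.8 mm isotropic; index x runs lateral→medial, y posterior→anterior, z
ventral→dorsal, all relative to the hippocampal long axis). Generating every
subject directly in template space stands in for cross-participant
registration, which this package deliberately does not model: it isolates
the statistics under test from registration error.

The EC is a thin curved sheet: one contiguous transverse run of voxels per
coronal (fixed-y) slice, ~45% of the grid's long axis (≥10 slices), run
width tapering 11→5 voxels from anterior to posterior with the centre
drifting medially and dorsally toward posterior slices. The subiculum is a
parallel sheet medial of the EC with a *uniform* slice width; width jitter
there would give the two longitudinal halves different transverse spreads,
which measurably masquerades as a seed × longitudinal interaction of the
per-slice transverse gradient (a pure geometry artifact), so it is excluded
by construction. PRC and PHC are equal-sized blocks lateral-anterior and
posterior of the EC, separated from it by a >2-voxel background corridor so
seed-border erosion is well defined; WM and CSF blocks occupy separate
dorsal/ventral slabs. A `bilateral` flag mirrors the geometry in x;
downstream analyses then treat hemispheres independently.

## Planted topography

EC voxel v carries the PHC-signal weight

    w(v) = logistic(κ · ⟨v − v̄, g⟩),   g ∝ (0.6, −1.0, 0.3),  κ = 0.25/voxel

(g is the unit anterior-lateral → posterior-medial direction in index space;
v̄ the EC centroid). Ground-truth labels: PRC-preferring for w ≤ 0.5
(deterministic tie rule), PHC-preferring otherwise; at the default κ the two
labels split the EC roughly 60/40 because anterior slices are wider. The
subiculum gets a per-slice proximo-distal logistic weight m(u) (slope
0.5/voxel, proximal = lateral) and, in its 8 most anterior (posterior)
slices, extra direct coupling (amplitude 0.4) to the PRC (PHC) latent.

## Signal model

Per subject, six unit-SD band-limited latents (white noise low-passed at
0.1 Hz, second-order Butterworth, forward–backward): L_PRC, L_PHC, two
EC-subregion latents E_al, E_pm, and WM/CSF compartment signals. With
couplings (c_s, c_o) = (`seed_coupling`, `subregion_coupling`):

* PRC voxels: baseline + L_PRC + noise; PHC voxels analogously;
* EC voxel v: c_s·[(1−w)L_PRC + wL_PHC] + c_o·[(1−w)E_al + wE_pm];
* SUB voxel u: (1−m)·A\* + m·P\* + end-coupling terms, where A\*, P\* are the
  EC-subregion composites evaluated at reference weights 0.2 / 0.8;
* all in-atlas voxels: AR(1) noise (φ = 0.3, SD 1), linear+quadratic drift,
  motion-coupled intensity change (random per-voxel gain × framewise
  displacement), a global leak (0.25) of the WM/CSF signals, HRF-convolved
  task responses in grey matter (double-gamma, peak 5 s, undershoot 15 s,
  ratio 6), and multiplicative global-intensity spikes (rate 0.02/volume,
  ≥2% of the 1000-unit baseline). Motion parameters follow a Gaussian random
  walk (0.02 mm / 2·10⁻⁴ rad steps).

The default is pure direct mixing, (c_s, c_o) = (1, 0): EC voxels are exact
convex mixtures of the seed latents plus noise, so recovery of w is the
cleanest possible test of the pipeline. Two named presets change only the
couplings:

* `TopographySpec.null()` sets the planted amplitude to zero — no
  seed-target connectivity at all. This, and not a flat-gradient cohort
  (w ≡ 0.5), is the calibration condition: with mixing present, the
  finite-sample norms of the shared latents give all of a subject's
  preference signs a common offset, so per-voxel labels are not independent
  and a binomial reference for classification accuracy does not apply.
* `TopographySpec.subiculum_study()` sets (c_s, c_o) = (0, 1): EC-subregion
  signals orthogonal to the seed latents. Any shared component turns the
  planted end-coupling into a *true* longitudinal effect for the EC seeds
  (measured at several times the naive covariance estimate), which
  contradicts the dissociation being planted; orthogonality is the only
  self-consistent ground truth for "transverse gradient yes, longitudinal
  gradient no".

## Analysis conventions

* Processing order: smoothing → task-effect OLS residualisation → nuisance
  regression (WM mean, CSF mean, 6 motion parameters, spike indicators) →
  band-pass → correlation. The sequential order (rather than one
  band-limited joint regression) is chosen for transparency; each step is
  linear, so seed averaging commutes with filtering and the vectorised
  pipeline path equals the composed per-seed operations exactly (asserted in
  the test suite).
* Band-pass: second-order Butterworth 0.01–0.1 Hz, zero phase (filtfilt),
  mean removed first. Measured response: ≥90% attenuation one octave below
  the low edge, ≤1% loss at 0.05 Hz.
* Correlations are clipped to |r| ≤ 1 − 10⁻⁷ before `atanh`; zero-variance
  voxels get z = 0 and a QC record.
* Z-standardisation of each Fisher-z map uses all computed (in-atlas,
  non-seed) voxels as the reference. Standardised maps feed every *group*
  statistic. Classifier labels, however, are the sign of the *raw*
  z_PRC − z_PHC difference: per-map standardisation estimates its mean/SD
  from a shared reference and thereby couples voxels within a subject
  (measured: label-count variance 0.8× binomial), which breaks the binomial
  reference for classification accuracy. Raw-difference signs are iid
  fair coins under the null.
* Cluster inference: 26-connected components of the one-sided
  normal-equivalent z above 2.3; familywise control by the max-cluster-size
  distribution over subject-level sign flips (exact under exchangeability;
  for paired contrasts the flipped objects are per-subject difference maps,
  i.e. within-subject condition swaps). Each contrast direction is
  thresholded separately; `p_fwe = (1 + #{null ≥ size})/(1 + n_perm)`, never
  below the floor.
* 2×2×2 repeated-measures ANOVA: every effect in an all-within two-level
  design has one numerator df, so F is computed as the squared one-sample t
  of the per-subject ±1 contrast score, df (1, n−1). This equals the full
  sums-of-squares decomposition to machine precision (checked against an
  independent oracle).
* Partitions: the longitudinal cut never splits a coronal slice and
  minimises voxel-count imbalance (ties → more slices anterior); within a
  slice, voxels are ordered along the slice's first principal axis oriented
  lateral→medial, split into equal-count bins, remainder voxels assigned to
  the most lateral bins. "Equal portions" therefore equalise voxel counts,
  not physical extent.
* Linear SVM: liblinear primal (squared hinge, L2, C = 1, tol 10⁻³,
  max_iter 200, class_weight balanced). The iteration cap matters only for
  label-noise fits, where the objective is flat and convergence is
  immaterial; balanced class weights remove the majority-class channel so
  imbalance cannot masquerade as decodability.
* Permutation null for the LOSO accuracy: the default scheme draws fresh
  fair-coin labels for training *and* testing each iteration. In a LOSO
  scheme every chunk appears in both roles, so the observed mean accuracy
  contains pairwise chunk-alignment terms; a null that relabels only the
  training side cannot reproduce that dependence, and both it and the
  count-preserving within-chunk permutation are measurably miscalibrated on
  label-noise data (conservative p, excess mass at p = 1). Full relabelling
  makes the null statistic an exact exchangeable copy of the observed one
  under label noise — uniform p by construction — while planted topographies
  still drive p to the floor. The train-only variants remain available as
  `scheme="relabel_train"` / `"permute_train"`.
* Deterministic tie rules throughout: preference t = 0 → PRC-preferring;
  classifier vote ties → unassigned; longitudinal-cut ties → anterior.

## Study conditions

* Headline recovery: 15 subjects, grid 40×60×24, 370 volumes at TR 2 s, the
  default planted gradient, task + spikes on; 500 cluster permutations, 500
  classifier-null iterations.
* Null calibration: 200 cohorts (100 in the acceptance script) of 10
  subjects each, grid 20×30×12, 150 volumes, `TopographySpec.null()`, no
  task, no smoothing (smoothing induces spatial label dependence that the
  voxel-level binomial reference does not model), 199 cluster permutations,
  100 classifier-null iterations. The cluster-rate check counts cohorts
  where the PRC>PHC direction yields any surviving cluster — one
  nominal-0.05 test per cohort.
* Subiculum dissociation: 100 cohorts (50 in the acceptance script) of 15
  subjects, grid 28×44×16, 200 volumes, `TopographySpec.subiculum_study()`;
  EC-subregion seeds are the ground-truth al/pm masks so the subiculum
  statistics are assessed independently of EC seed estimation.

Run lengths and grids below the headline condition are scaled-down study
sizes chosen to keep many-cohort calibration studies practical; the
statistics under test are calibrated at any valid run length.

## What the generator does and does not emulate

It emulates the features the pipeline must be robust to: band-limited
coherent signals, autocorrelated voxel noise, drift, motion-correlated
intensity changes, compartment confounds that leak globally, intensity
spikes, and task-evoked responses. It does **not** emulate spatially
correlated physiological noise fields, susceptibility dropout geometry or
distortion, registration error (a single common space is assumed), real
hemodynamic variability across regions, or multi-run sessions. Passing
recovery and calibration here therefore validates the *statistical
machinery* — estimators, nulls, partitions, classifiers — not robustness to
every artifact of real 7T acquisitions.

## Known limitations

* At null-calibration scale (~60 EC voxels) cluster sizes are small
  integers, so attainable familywise levels are discrete and the test is
  somewhat conservative (empirical rate near the lower half of its band).
* The LOSO accuracy's variance exceeds the independent-Bernoulli (binomial)
  reference even with mathematically ideal iid fair-coin labels: on the
  null-calibration EC geometry the measured SD of the mean accuracy is
  0.0251 against the binomial 0.0196 (300 pure-coin cohorts, no fMRI
  simulation involved). The excess is intrinsic to leave-one-subject-out
  with any data-driven classifier — each chunk is test data in one fold and
  training data in the other folds, so fold accuracies carry pairwise
  chunk-alignment covariances. A 95% binomial interval around chance
  consequently covers the observed mean accuracy in only ~87–90% of null
  cohorts, not 95%. The full-relabelling permutation test reproduces this
  dependence exactly and is the calibrated inferential tool; the binomial
  interval should be read as an approximate, slightly anti-conservative
  reference.
* `df_effective` on Fisher-z maps is a rough band-limited estimate recorded
  as metadata; no inference consumes it.
* The ROI intensity threshold removes ~2% of homogeneous-noise voxels by
  construction (mean − 2 SD on near-Gaussian temporal means); with planted
  dropout it removes the dropout voxels first.
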