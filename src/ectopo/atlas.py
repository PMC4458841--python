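"""Template-space atlas construction for the medial temporal lobe strip.

The atlas lives on a regular voxel grid in a single common space shared by
every synthetic subject.  Index conventions (fixed throughout the package,
relative to the hippocampal long axis):

* ``x`` increases lateral -> medial
* ``y`` increases posterior -> anterior (coronal slices are fixed-``y`` planes)
* ``z`` increases ventral -> dorsal

Regions: entorhinal cortex (EC) and subiculum (SUB) are thin sheets elongated
along ``y`` -- one contiguous transverse run of voxels per coronal slice, with
the run width, lateral position and height drifting along the long axis the
way the real EC curves.  Perirhinal (PRC) and parahippocampal (PHC) cortex are
equal-sized blocks placed lateral-anterior and posterior of the EC; white
matter (WM) and CSF blocks sit in separate dorsal/ventral slabs and provide
nuisance compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKGROUND = 0
EC = 1
PRC = 2
PHC = 3
SUB = 4
WM = 5
CSF = 6

LABEL_NAMES = {
    BACKGROUND: "background",
    EC: "EC",
    PRC: "PRC",
    PHC: "PHC",
    SUB: "SUB",
    WM: "WM",
    CSF: "CSF",
}
LABEL_CODES = {name: code for code, name in LABEL_NAMES.items()}

#: regions treated as grey matter (they receive latent signals and task responses)
GREY_LABELS = (EC, PRC, PHC, SUB)


class AtlasSizingError(ValueError):
    """Raised when the requested regions cannot be placed inside the grid."""


@dataclass(frozen=True)
class AtlasSpec:
    """Geometry parameters of the template grid.

    Parameters
    ----------
    grid_shape
        Number of voxels along (x, y, z).
    voxel_size
        Isotropic voxel edge length in mm (0.8 mm matches the acquisition
        resolution this template emulates).
    region_extents
        Optional overrides of the fractional layout parameters; see
        :data:`DEFAULT_EXTENTS`.
    bilateral
        If True the grid is doubled along x and the geometry mirrored, giving
        two hemispheres that downstream analyses treat independently.
    """

    grid_shape: tuple[int, int, int] = (40, 60, 24)
    voxel_size: float = 0.8
    region_extents: dict = field(default_factory=dict)
    bilateral: bool = False

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive integers, got {self.grid_shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


#: fractional layout of the default single-hemisphere template
DEFAULT_EXTENTS = {
    "ec_slices_frac": 0.45,      # EC long-axis extent as a fraction of ny
    "ec_y0_frac": 0.30,
    "ec_width_max_frac": 0.27,   # transverse run width, anterior end (capped at 11)
    "ec_width_min_frac": 0.125,  # posterior end (floored at 3)
    "ec_xc_frac": 0.40,          # anterior transverse centre
    "ec_x_drift_frac": 0.15,     # posterior shift toward medial
    "ec_zc_frac": 0.40,
    "ec_z_drift_frac": 0.12,     # posterior shift toward dorsal
    "sub_slices_frac": 0.50,
    "sub_y0_frac": 0.20,
    "sub_width_frac": 0.18,
    "sub_x0_frac": 0.70,
    "block_wx_frac": 0.12,       # PRC/PHC block dimensions
    "block_wy_frac": 0.20,
    "block_wz_frac": 0.17,
}

_MAX_SLICE_WIDTH = 11
_MIN_SLICE_WIDTH = 3
_MIN_SLICES = 10
_PRC_GAP = 2  # background corridor (voxels) between PRC and EC


@dataclass
class LabeledAtlas:
    """Integer label grid plus per-slice transverse geometry helpers."""

    labels: np.ndarray
    voxel_size: float
    spec: AtlasSpec

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def mask(self, region: int | str) -> np.ndarray:
        code = LABEL_CODES[region] if isinstance(region, str) else int(region)
        return self.labels == code

    def in_atlas_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def grey_mask(self) -> np.ndarray:
        return np.isin(self.labels, GREY_LABELS)

    def voxel_counts(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum())
                for code, name in LABEL_NAMES.items() if code != BACKGROUND}

    def coronal_slices(self, region: int | str) -> dict[int, np.ndarray]:
        """Ordered member voxels of each coronal (fixed-y) slice of a region.

        Returns a mapping ``y -> (k, 3) int array`` with the slice's voxels
        sorted along the slice's transverse direction (see
        :func:`transverse_order`), most lateral first.
        """
        mask = self.mask(region)
        out: dict[int, np.ndarray] = {}
        for y in np.unique(np.nonzero(mask)[1]):
            coords = np.argwhere(mask[:, y, :])  # (k, 2) -> (x, z)
            order = transverse_order(coords)
            vox = np.column_stack([coords[order, 0],
                                   np.full(len(coords), y, dtype=int),
                                   coords[order, 1]])
            out[int(y)] = vox
        return out

    def hemisphere_masks(self) -> list[np.ndarray]:
        """Boolean masks of each hemisphere (one for a unilateral atlas)."""
        nx = self.labels.shape[0]
        if not self.spec.bilateral:
            return [np.ones(self.labels.shape, dtype=bool)]
        left = np.zeros(self.labels.shape, dtype=bool)
        left[: nx // 2] = True
        return [left, ~left]


def transverse_order(coords: np.ndarray) -> np.ndarray:
    """Order of in-slice voxel coordinates along the slice's transverse axis.

    The axis is the first principal component of the (x, z) coordinates,
    sign-oriented so that increasing order runs lateral -> medial (x
    increasing).  Ties are broken lexicographically by (x, z) so the ordering
    is deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 1:
        return np.array([0])
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0 or (axis[0] == 0 and axis[-1] < 0):
        axis = -axis
    proj = centered @ axis
    return np.lexsort((coords[:, -1], coords[:, 0], proj))


def _place(labels: np.ndarray, code: int, xs: slice, y, zs: slice) -> None:
    block = labels[xs, y, zs]
    if np.any(block != BACKGROUND):
        raise AtlasSizingError(
            f"region {LABEL_NAMES[code]} overlaps an existing region; "
            "grid too small for the requested extents")
    labels[xs, y, zs] = code


def make_atlas(spec: AtlasSpec | None = None, seed: int = 0) -> LabeledAtlas:
    """Build the labelled template atlas.

    Deterministic given ``seed``; the seed only jitters the per-slice widths
    and heights of the EC/SUB sheets so repeated cohorts can use slightly
    different geometry.

    Raises
    ------
    AtlasSizingError
        If the regions cannot be placed in the grid (too few long-axis slices,
        runs out of bounds, or overlapping regions).
    """
    spec = spec or AtlasSpec()
    ext = {**DEFAULT_EXTENTS, **spec.region_extents}
    nx, ny, nz = (int(v) for v in spec.grid_shape)
    if spec.bilateral:
        half = make_atlas(AtlasSpec(spec.grid_shape, spec.voxel_size,
                                    spec.region_extents, bilateral=False), seed)
        labels = np.concatenate([half.labels[::-1], half.labels], axis=0)
        return LabeledAtlas(labels, spec.voxel_size, spec)

    rng = np.random.default_rng(seed)
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    # --- EC: curved thin sheet along y -------------------------------------
    n_ec = round(ext["ec_slices_frac"] * ny)
    if n_ec < _MIN_SLICES:
        raise AtlasSizingError(
            f"grid y extent {ny} yields only {n_ec} EC coronal slices (need >= {_MIN_SLICES})")
    y0 = round(ext["ec_y0_frac"] * ny)
    w_max = min(_MAX_SLICE_WIDTH, max(_MIN_SLICE_WIDTH, round(ext["ec_width_max_frac"] * nx)))
    w_min = min(w_max, max(_MIN_SLICE_WIDTH, round(ext["ec_width_min_frac"] * nx)))
    ec_xmin = nx
    for i in range(n_ec):
        y = y0 + i
        if y >= ny:
            raise AtlasSizingError("EC extends beyond the anterior edge of the grid")
        frac_ant = i / (n_ec - 1)
        w = round(w_min + (w_max - w_min) * frac_ant) + int(rng.integers(0, 2))
        w = int(np.clip(w, _MIN_SLICE_WIDTH, _MAX_SLICE_WIDTH))
        xc = round(ext["ec_xc_frac"] * nx + ext["ec_x_drift_frac"] * nx * (1.0 - frac_ant))
        zc = round(ext["ec_zc_frac"] * nz + ext["ec_z_drift_frac"] * nz * (1.0 - frac_ant))
        zc = int(np.clip(zc + int(rng.integers(-1, 2)) * (i % 2), 1, nz - 2))
        x_start = xc - w // 2
        if x_start < 0 or x_start + w > nx:
            raise AtlasSizingError("EC slice run exceeds the lateral-medial grid extent")
        _place(labels, EC, slice(x_start, x_start + w), y, slice(zc, zc + 1))
        ec_xmin = min(ec_xmin, x_start)

    # --- SUB: thin sheet medial of EC --------------------------------------
    n_sub = round(ext["sub_slices_frac"] * ny)
    if n_sub < _MIN_SLICES:
        raise AtlasSizingError(
            f"grid y extent {ny} yields only {n_sub} SUB coronal slices (need >= {_MIN_SLICES})")
    y0s = round(ext["sub_y0_frac"] * ny)
    w_sub = max(_MIN_SLICE_WIDTH, round(ext["sub_width_frac"] * nx))
    x0s = round(ext["sub_x0_frac"] * nx)
    # SUB slice width is uniform along the long axis: per-slice width jitter
    # would give the two longitudinal halves different transverse spreads,
    # which shows up as a spurious seed x longitudinal modulation of the
    # per-slice transverse gradient
    for i in range(n_sub):
        y = y0s + i
        if y >= ny:
            raise AtlasSizingError("SUB extends beyond the anterior edge of the grid")
        frac_ant = i / (n_sub - 1)
        w = int(np.clip(w_sub, _MIN_SLICE_WIDTH, _MAX_SLICE_WIDTH))
        zc = round(ext["ec_zc_frac"] * nz - 0.04 * nz * frac_ant)
        zc = int(np.clip(zc, 1, nz - 2))
        if x0s + w > nx:
            raise AtlasSizingError("SUB slice run exceeds the medial grid edge")
        _place(labels, SUB, slice(x0s, x0s + w), y, slice(zc, zc + 1))

    # --- PRC / PHC: equal-sized neocortical seed blocks --------------------
    wx = max(3, round(ext["block_wx_frac"] * nx))
    wy = max(4, round(ext["block_wy_frac"] * ny))
    wz = max(2, round(ext["block_wz_frac"] * nz))
    # PRC lateral-anterior of EC, separated by a >= _PRC_GAP background corridor
    prc_x1 = ec_xmin - _PRC_GAP - 1   # inclusive upper x
    prc_x0 = prc_x1 - wx + 1
    if prc_x0 < 0:
        raise AtlasSizingError("no room lateral of EC for the PRC block")
    prc_y0 = round(0.45 * ny)
    prc_z0 = round(0.33 * nz)
    if prc_y0 + wy > ny or prc_z0 + wz > nz:
        raise AtlasSizingError("PRC block exceeds grid")
    _place(labels, PRC, slice(prc_x0, prc_x1 + 1), slice(prc_y0, prc_y0 + wy),
           slice(prc_z0, prc_z0 + wz))
    # PHC posterior of EC
    phc_x0 = round(0.28 * nx)
    phc_y1 = y0 - 3   # >= 2 background slices between PHC and EC posteriorly
    phc_y0 = phc_y1 - wy + 1
    if phc_y0 < 0 or phc_x0 + wx > nx:
        raise AtlasSizingError("no room posterior of EC for the PHC block")
    _place(labels, PHC, slice(phc_x0, phc_x0 + wx), slice(phc_y0, phc_y1 + 1),
           slice(prc_z0, prc_z0 + wz))

    # --- WM / CSF nuisance compartments in separate z slabs ----------------
    wm_z0 = round(0.78 * nz)
    csf_z0 = max(0, round(0.04 * nz))
    if wm_z0 + 2 > nz:
        raise AtlasSizingError("no dorsal slab available for WM")
    _place(labels, WM, slice(round(0.08 * nx), round(0.08 * nx) + max(3, nx // 6)),
           slice(round(0.55 * ny), round(0.55 * ny) + max(4, ny // 5)),
           slice(wm_z0, min(nz, wm_z0 + 2)))
    _place(labels, CSF, slice(round(0.70 * nx), round(0.70 * nx) + max(3, nx // 6)),
           slice(round(0.06 * ny), round(0.06 * ny) + max(4, ny // 5)),
           slice(csf_z0, csf_z0 + 2))

    atlas = LabeledAtlas(labels, spec.voxel_size, spec)
    _validate(atlas)
    return atlas


def _validate(atlas: LabeledAtlas) -> None:
    from scipy.spatial.distance import cdist

    ec = np.argwhere(atlas.mask(EC))
    prc = np.argwhere(atlas.mask(PRC))
    # Chebyshev corridor between PRC and EC must exceed the erosion gap
    d = cdist(prc, ec, metric="chebyshev").min()
    if d <= _PRC_GAP:
        raise AtlasSizingError(
            f"PRC-EC Chebyshev distance {d} leaves no {_PRC_GAP}-voxel corridor")
    for region in (EC, SUB):
        slices = atlas.coronal_slices(region)
        if len(slices) < _MIN_SLICES:
            raise AtlasSizingError(f"{LABEL_NAMES[region]} has {len(slices)} slices")
        for y, vox in slices.items():
            if not (_MIN_SLICE_WIDTH <= len(vox) <= _MAX_SLICE_WIDTH):
                raise AtlasSizingError(
                    f"{LABEL_NAMES[region]} slice y={y} has {len(vox)} voxels")
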