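import numpy as np
import pytest

import ectopo as et


@pytest.fixture(scope="session")
def small_atlas():
    return et.make_atlas(et.AtlasSpec(grid_shape=(20, 30, 12)), seed=1)


@pytest.fixture(scope="session")
def small_truth(small_atlas):
    return et.plant_topography(small_atlas)


@pytest.fixture(scope="session")
def tiny_subject(small_atlas, small_truth):
    return et.simulate_subject(small_atlas, small_truth,
                               task=et.TaskSpec.default(80, 2.0, seed=3),
                               n_volumes=80, seed=11)


@pytest.fixture(scope="session")
def tiny_fit(small_atlas, small_truth):
    """A fitted EC-topography model on a 3-subject cohort (shared, read-only)."""
    cohort = et.simulate_cohort(3, small_atlas, small_truth, seed=5, n_volumes=100)
    cfg = et.PipelineConfig(n_perm=100, loso_n_iter=100)
    return et.ConnectivityTopography(cohort, config=cfg).fit(seed=7)


def make_fisher_z_maps(values, mask, seed_id="A"):
    """Stack of FisherZMap objects from an (n_subjects, ...) value array."""
    maps = []
    for i, v in enumerate(values):
        grid = np.full(mask.shape, np.nan)
        grid[mask] = np.asarray(v, dtype=float)[mask] if v.shape == mask.shape else v
        maps.append(et.FisherZMap(values=grid, target_mask=mask,
                                  subject_id=f"sub-{i:02d}", seed_id=seed_id))
    return maps
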