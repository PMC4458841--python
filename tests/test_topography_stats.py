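import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ectopo as et
from ectopo import topography_stats as ts
from conftest import make_fisher_z_maps

# ---------------------------------------------------------------------------
# helpers


def strip_mask(slice_counts, width_axis="x"):
    """Mask with one coronal slice per count, a contiguous run along x."""
    nx = max(slice_counts) + 2
    ny = len(slice_counts) + 2
    mask = np.zeros((nx, ny, 3), dtype=bool)
    for i, k in enumerate(slice_counts):
        mask[1:1 + k, 1 + i, 1] = True
    return mask


def random_cell_table(rng, n_subjects=15, effects=None):
    """Complete 2x2x2 cell-means table with optional planted effect dict."""
    effects = effects or {}
    rows = []
    for s in range(n_subjects):
        for seed in ("A", "B"):
            for lon in (ts.ANTERIOR, ts.POSTERIOR):
                for trans in (ts.LATERAL, ts.MEDIAL):
                    mu = effects.get((seed, lon, trans), 0.0)
                    rows.append(dict(subject_id=f"s{s:02d}", seed_id=seed,
                                     longitudinal=lon, transverse=trans,
                                     mean_z=mu + rng.normal(0, effects.get("sd", 1.0))))
    return pd.DataFrame(rows)


def anova_ss_oracle(table):
    """Full sums-of-squares within-subject 2x2x2 ANOVA (independent oracle).

    Classical decomposition: for each effect, SS_effect from marginal means
    and SS_error from the effect x subject interaction.
    """
    piv = table.pivot_table(index="subject_id",
                            columns=["seed_id", "longitudinal", "transverse"],
                            values="mean_z")
    cells = piv.to_numpy().reshape(-1, 2, 2, 2)  # subject x seed x lon x trans
    n = cells.shape[0]
    grand = cells.mean()
    out = {}
    factors = {"seed": 1, "longitudinal": 2, "transverse": 3}
    names = {
        ("seed",): "seed", ("longitudinal",): "longitudinal",
        ("transverse",): "transverse",
        ("seed", "longitudinal"): "seed x longitudinal",
        ("seed", "transverse"): "seed x transverse",
        ("longitudinal", "transverse"): "longitudinal x transverse",
        ("seed", "longitudinal", "transverse"): "seed x longitudinal x transverse",
    }
    import itertools
    for combo, label in names.items():
        axes = tuple(factors[f] for f in combo)
        keep = (0,) + axes
        drop = tuple(i for i in range(4) if i not in keep)
        # subject x effect-level means
        m = cells.mean(axis=drop) if drop else cells
        # effect means over subjects, with lower-order terms removed by
        # Moebius inversion over subsets
        def effect_term(mat, k):
            # mat: subject x 2^k levels; returns per-(subject, level) effect
            mat = mat.reshape(n, *([2] * k))
            term = mat.copy()
            for sub_k in range(k):
                term -= np.expand_dims(term.mean(axis=sub_k + 1), sub_k + 1)
            return term
        term = effect_term(m, len(axes))
        level_effect = term.mean(axis=0)
        ss_effect = n * (level_effect ** 2).sum() * (8 / (2 ** len(axes))) / 1.0
        resid = term - level_effect
        ss_error = (resid ** 2).sum() * (8 / (2 ** len(axes)))
        df_effect = 1  # every effect in a 2x2x2 design has a single df
        df_error = n - 1
        f = (ss_effect / df_effect) / (ss_error / df_error)
        p = stats.f.sf(f, df_effect, df_error)
        out[label] = (f, p)
    return out


# ---------------------------------------------------------------------------
# partitioning


class TestSplitLongitudinal:
    def test_even_split(self):
        sections = et.split_longitudinal(strip_mask([4] * 10))
        ant = (sections.longitudinal == ts.ANTERIOR).sum()
        assert ant == 20 and (sections.longitudinal == ts.POSTERIOR).sum() == 20

    def test_cut_minimizes_imbalance(self):
        # anterior->posterior counts [5,5,5,9]; ascending y = [9,5,5,5]
        counts = [9, 5, 5, 5]
        sections = et.split_longitudinal(strip_mask(counts))
        # enumeration oracle over all cuts
        best = min(range(1, 4),
                   key=lambda k: abs(sum(counts[:k]) - sum(counts[k:])))
        assert best == 2
        post = (sections.longitudinal == ts.POSTERIOR).sum()
        assert post == sum(counts[:best]) == 14
        assert (sections.longitudinal == ts.ANTERIOR).sum() == 10

    def test_two_slices_split_one_one(self):
        sections = et.split_longitudinal(strip_mask([3, 3]))
        ys = np.unique(sections.slice_index)
        ant_slices = np.unique(sections.slice_index[sections.longitudinal == ts.ANTERIOR])
        assert list(ant_slices) == [ys.max()]

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            et.split_longitudinal(strip_mask([5]))


class TestSplitTransverse:
    def test_five_voxels_five_bins(self):
        sections = et.split_transverse_per_slice(strip_mask([5, 5]), 5)
        for y in np.unique(sections.slice_index):
            sel = sections.slice_index == y
            q = sections.transverse_quintile[sel]
            x = sections.voxels[sel, 0]
            assert sorted(q) == [1, 2, 3, 4, 5]
            assert q[np.argmin(x)] == 1 and q[np.argmax(x)] == 5

    def test_remainder_goes_lateral(self):
        sections = et.split_transverse_per_slice(strip_mask([7]), 2)
        lat = (sections.transverse_half == ts.LATERAL).sum()
        assert (lat, (sections.transverse_half == ts.MEDIAL).sum()) == (4, 3)
        # the lateral half is the low-x run
        assert sections.voxels[sections.transverse_half == ts.LATERAL, 0].max() \
            < sections.voxels[sections.transverse_half == ts.MEDIAL, 0].min()

    def test_slice_smaller_than_bins_rejected(self):
        with pytest.raises(ValueError, match="slice"):
            et.split_transverse_per_slice(strip_mask([4, 6]), 5)


def test_partition_completeness(small_atlas):
    for region in ("EC", "SUB"):
        mask = small_atlas.mask(region)
        sections = et.assign_sections(mask, 2)
        assert len(sections.voxels) == mask.sum()
        assert not pd.DataFrame(sections.voxels).duplicated().any()
        assert set(sections.longitudinal) == {ts.ANTERIOR, ts.POSTERIOR}
        assert set(sections.transverse_half) == {ts.LATERAL, ts.MEDIAL}
        assert sections.transverse_quintile is None or \
            set(sections.transverse_quintile) <= {1, 2}


# ---------------------------------------------------------------------------
# cell means and factorial statistics


class TestSectionMeans:
    def _map_and_sections(self, fill):
        mask = strip_mask([4] * 6)
        sections = et.assign_sections(mask, 2)
        grid = np.zeros(mask.shape)
        grid[tuple(sections.voxels.T)] = fill(sections)
        fz = make_fisher_z_maps(grid[None], mask)[0]
        return fz, sections

    def test_constant_map(self):
        fz, sections = self._map_and_sections(lambda s: 0.7)
        tab = et.section_means(fz, sections, seed_id="A")
        assert np.allclose(tab.mean_z, 0.7)

    def test_anterior_posterior_contrast(self):
        fz, sections = self._map_and_sections(
            lambda s: np.where(s.longitudinal == ts.ANTERIOR, 1.0, -1.0))
        tab = et.section_means(fz, sections, seed_id="A")
        assert np.allclose(tab[tab.longitudinal == ts.ANTERIOR].mean_z, 1.0)
        assert np.allclose(tab[tab.longitudinal == ts.POSTERIOR].mean_z, -1.0)

    def test_two_voxel_cell_average(self):
        assert np.isclose(np.mean([0.2, 0.4]), 0.3)  # the rule section_means applies
        fz, sections = self._map_and_sections(lambda s: 0.3)
        assert np.allclose(et.section_means(fz, sections).mean_z, 0.3)


class TestRmAnova:
    def test_zero_interaction_gives_f_zero_p_one(self):
        rows = []
        for s in range(8):
            base = float(s)  # dyadic values keep the contrast exactly zero
            for seed in ("A", "B"):
                for lon in (ts.ANTERIOR, ts.POSTERIOR):
                    for trans in (ts.LATERAL, ts.MEDIAL):
                        # additive seed and longitudinal effects, no interaction
                        rows.append(dict(subject_id=f"s{s}", seed_id=seed,
                                         longitudinal=lon, transverse=trans,
                                         mean_z=base + (seed == "A") * 0.5
                                         + (lon == ts.ANTERIOR) * 0.25))
        res = et.anova_effect(et.rm_anova_2x2x2(pd.DataFrame(rows)),
                              "seed x longitudinal")
        assert res.F == pytest.approx(0.0, abs=1e-18)
        assert res.p == pytest.approx(1.0)

    def test_interaction_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        table = random_cell_table(rng)
        res = et.anova_effect(et.rm_anova_2x2x2(table), "seed x longitudinal")
        piv = table.pivot_table(index="subject_id",
                                columns=["seed_id", "longitudinal"],
                                values="mean_z", aggfunc="mean")
        dod = (piv[("A", ts.ANTERIOR)] - piv[("A", ts.POSTERIOR)]
               - piv[("B", ts.ANTERIOR)] + piv[("B", ts.POSTERIOR)])
        t = stats.ttest_1samp(dod, 0).statistic
        assert res.F == pytest.approx(t ** 2, abs=1e-10)

    def test_agrees_with_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = random_cell_table(rng)
            mine = {r.effect: (r.F, r.p) for r in et.rm_anova_2x2x2(table)}
            oracle = anova_ss_oracle(table)
            for effect, (f, p) in oracle.items():
                assert mine[effect][0] == pytest.approx(f, abs=1e-8)
                assert mine[effect][1] == pytest.approx(p, abs=1e-8)

    def test_planted_crossover_detected(self):
        # seed A higher anterior, seed B higher posterior: effect 0.4, sd 0.1
        rng = np.random.default_rng(3)
        hits = 0
        eff = {("A", ts.ANTERIOR, ts.LATERAL): 0.4, ("A", ts.ANTERIOR, ts.MEDIAL): 0.4,
               ("B", ts.POSTERIOR, ts.LATERAL): 0.4, ("B", ts.POSTERIOR, ts.MEDIAL): 0.4,
               "sd": 0.1}
        for _ in range(200):
            table = random_cell_table(rng, effects=eff)
            p = et.anova_effect(et.rm_anova_2x2x2(table), "seed x longitudinal").p
            hits += p < 0.001
        assert hits >= 190

    def test_incomplete_cells_reported(self):
        table = random_cell_table(np.random.default_rng(4)).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            et.rm_anova_2x2x2(table)


class TestPairedFollowup:
    def test_identical_cells(self):
        table = random_cell_table(np.random.default_rng(5))
        t, p = et.paired_followup(table, {"seed_id": "A"}, {"seed_id": "A"})
        assert (t, p) == (0.0, 1.0)

    def test_swap_negates_t(self):
        table = random_cell_table(np.random.default_rng(6))
        t1, p1 = et.paired_followup(table, {"seed_id": "A"}, {"seed_id": "B"})
        t2, p2 = et.paired_followup(table, {"seed_id": "B"}, {"seed_id": "A"})
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_hand_computed_value(self):
        rows = []
        for s, d in enumerate((0.1, 0.2, 0.3)):
            rows += [dict(subject_id=f"s{s}", seed_id="A", longitudinal=ts.ANTERIOR,
                          transverse=ts.LATERAL, mean_z=d),
                     dict(subject_id=f"s{s}", seed_id="B", longitudinal=ts.ANTERIOR,
                          transverse=ts.LATERAL, mean_z=0.0)]
        t, p = et.paired_followup(pd.DataFrame(rows), {"seed_id": "A"}, {"seed_id": "B"})
        assert t == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-4)
        assert p == pytest.approx(0.0742, abs=2e-3)


class TestProfilesAndContrasts:
    def _planted_maps(self, n_sub, fill, mask=None, rng=None, sd=0.0):
        mask = strip_mask([5] * 10) if mask is None else mask
        sections = et.assign_sections(mask, 5)
        vals = []
        for _ in range(n_sub):
            grid = np.zeros(mask.shape)
            grid[tuple(sections.voxels.T)] = fill(sections)
            if sd:
                grid[mask] += rng.normal(0, sd, mask.sum())
            vals.append(grid[mask])
        return make_fisher_z_maps(np.array(vals), mask), sections

    def test_monotone_gradient_yields_monotone_profile(self):
        maps, sections = self._planted_maps(
            2, lambda s: s.transverse_quintile.astype(float))
        prof = et.slice_profiles({"A": maps}, sections, "transverse").table
        assert (np.diff(prof.sort_values("position")["mean"]) > 0).all()

    def test_constant_maps_flat_profile_and_consistency(self):
        maps, sections = self._planted_maps(3, lambda s: 0.4)
        for axis in ("longitudinal", "transverse"):
            prof = et.slice_profiles({"A": maps}, sections, axis).table
            assert np.allclose(prof["mean"], 0.4) and np.allclose(prof["sem"], 0.0)

    def test_profile_matches_direct_section_average(self):
        rng = np.random.default_rng(7)
        maps, sections = self._planted_maps(4, lambda s: 0.0, rng=rng, sd=1.0)
        prof = et.slice_profiles({"A": maps}, sections, "longitudinal").table
        y0 = prof.position.iloc[0]
        sel = sections.slice_index == y0
        direct = np.mean([m.values[tuple(sections.voxels[sel].T)].mean() for m in maps])
        assert prof["mean"].iloc[0] == pytest.approx(direct)

    def test_end_slices_equal_whole_roi_when_k_is_total(self):
        rng = np.random.default_rng(8)
        maps_a, sections = self._planted_maps(6, lambda s: 0.0, rng=rng, sd=1.0)
        maps_b, _ = self._planted_maps(6, lambda s: 0.0, rng=rng, sd=1.0)
        t_end, p_end = et.end_slices_contrast(maps_a, maps_b, sections, k=10)
        a = np.array([m.values[m.target_mask].mean() for m in maps_a])
        b = np.array([m.values[m.target_mask].mean() for m in maps_b])
        ref = stats.ttest_rel(a, b)
        assert t_end == pytest.approx(ref.statistic) and p_end == pytest.approx(ref.pvalue)

    def test_identical_maps_give_zero_contrast(self):
        maps, sections = self._planted_maps(4, lambda s: 0.2)
        assert et.end_slices_contrast(maps, maps, sections, k=8) == (0.0, 1.0)

    def test_too_few_slices_rejected(self):
        maps, sections = self._planted_maps(3, lambda s: 0.0)
        with pytest.raises(ValueError, match="slices"):
            et.end_slices_contrast(maps, maps, sections, k=11)

    def test_planted_end_coupling_detected(self):
        # +0.3 z in the anterior 8 slices for seed A only, noise sd 0.1, n=15
        rng = np.random.default_rng(9)
        mask = strip_mask([5] * 16)
        sections = et.assign_sections(mask, 5)
        ys = np.unique(sections.slice_index)
        ant8 = np.isin(sections.slice_index, ys[-8:])
        hits = 0
        for _ in range(200):
            a_vals, b_vals = [], []
            for _s in range(15):
                a = rng.normal(0, 0.1, mask.sum()); a[ant8] += 0.3
                b = rng.normal(0, 0.1, mask.sum())
                a_vals.append(a); b_vals.append(b)
            maps_a = make_fisher_z_maps(np.array(a_vals), mask, "A")
            maps_b = make_fisher_z_maps(np.array(b_vals), mask, "B")
            t, p = et.end_slices_contrast(maps_a, maps_b, sections, k=8)
            hits += (p < 0.05) and (t > 0)
        assert hits >= 180


class TestDeltaInteraction:
    def _tables(self, rng, ec_slope=0.0, ctx_slope=0.3, sd=0.1, n=15):
        def build(seeds, slope):
            rows = []
            for s in range(n):
                for i, seed in enumerate(seeds):
                    sign = 1 if i == 0 else -1
                    for lon in (ts.ANTERIOR, ts.POSTERIOR):
                        for trans in (ts.LATERAL, ts.MEDIAL):
                            mu = sign * slope / 2 * (1 if lon == ts.ANTERIOR else -1)
                            rows.append(dict(subject_id=f"s{s:02d}", seed_id=seed,
                                             longitudinal=lon, transverse=trans,
                                             mean_z=mu + rng.normal(0, sd)))
            return pd.DataFrame(rows)
        return build(("alEC", "pmEC"), ec_slope), build(("PRC", "PHC"), ctx_slope)

    PAIRS = dict(ec_pair=("alEC", "pmEC"), ctx_pair=("PRC", "PHC"))

    def test_equal_deltas_give_f_zero(self):
        rng = np.random.default_rng(10)
        ec, _ = self._tables(rng, sd=0.0, ec_slope=0.3)
        ctx = ec.copy()
        ctx["seed_id"] = ctx.seed_id.map({"alEC": "PRC", "pmEC": "PHC"})
        res = et.delta_interaction(ec, ctx, **self.PAIRS)
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_f_equals_squared_t_of_slope_difference(self):
        rng = np.random.default_rng(11)
        ec, ctx = self._tables(rng)
        res = et.delta_interaction(ec, ctx, **self.PAIRS)

        def slope(tab, s0, s1):
            piv = tab.pivot_table(index="subject_id",
                                  columns=["seed_id", "longitudinal"],
                                  values="mean_z", aggfunc="mean")
            d = piv[s0] - piv[s1]
            return d[ts.ANTERIOR] - d[ts.POSTERIOR]

        diff = slope(ec, "alEC", "pmEC") - slope(ctx, "PRC", "PHC")
        t = stats.ttest_1samp(diff, 0).statistic
        assert res.F == pytest.approx(t ** 2, abs=1e-8)

    def test_differing_longitudinal_profiles_detected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(200):
            ec, ctx = self._tables(rng)
            hits += et.delta_interaction(ec, ctx, **self.PAIRS).p < 0.05
        assert hits >= 180

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        ec, ctx = self._tables(rng)
        with pytest.raises(ValueError, match="subject"):
            et.delta_interaction(ec, ctx[ctx.subject_id != "s00"])


def test_statistics_invariant_to_subject_order():
    rng = np.random.default_rng(14)
    table = random_cell_table(rng)
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    r1 = {r.effect: r.F for r in et.rm_anova_2x2x2(table)}
    r2 = {r.effect: r.F for r in et.rm_anova_2x2x2(shuffled)}
    for k in r1:
        assert r1[k] == pytest.approx(r2[k], rel=1e-12)
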