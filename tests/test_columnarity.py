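"""Cylindrical UVD searchlight, thresholding, consistency, benchmarks."""

import numpy as np
import pytest

import colkit as ck
from colkit.columnarity import CylinderSpec, FULL


def brute_force_columnarity(geom, pref, domain, cyl):
    """Independent oracle: per-window enumeration with explicit loops."""
    idx = np.argwhere(domain)
    out = {}
    for c in idx:
        c = tuple(c)
        members = []
        for o in idx:
            o = tuple(o)
            duv = np.hypot(
                geom.coord_u[c] - geom.coord_u[o], geom.coord_v[c] - geom.coord_v[o]
            )
            if duv > cyl.radius:
                continue
            if cyl.height != FULL:
                if abs(geom.depth_d[c] - geom.depth_d[o]) > float(cyl.height) / 2:
                    continue
            members.append(pref.labels[o])
        counts = np.bincount(members)
        out[c] = counts.max() / len(members)
    return out


class TestCylinderWindow:
    def test_default_radius_spans_one_depth_column(self, slab):
        # 0.6 mm < 0.8 mm in-plane spacing: window is the center's own column.
        w = ck.cylinder_window(slab, (4, 4, 1), slab.gm_mask)
        assert len(w) == 4
        assert np.all(w[:, 0] == 4) and np.all(w[:, 1] == 4)

    def test_radius_085_adds_face_neighbors(self, slab):
        # 0.8 <= 0.85 < 1.13: center column plus 4 face-neighbor columns.
        w = ck.cylinder_window(slab, (4, 4, 1), slab.gm_mask, CylinderSpec(radius=0.85))
        assert len(w) == 5 * 4

    def test_radius_12_adds_diagonal_columns(self, slab):
        # face 0.8 and diagonal 1.13 both <= 1.2
        w = ck.cylinder_window(slab, (4, 4, 1), slab.gm_mask, CylinderSpec(radius=1.2))
        assert len(w) == 9 * 4

    def test_window_contains_center(self, slab):
        w = ck.cylinder_window(slab, (0, 9, 3), slab.gm_mask)
        assert any((tuple(row) == (0, 9, 3)) for row in w)

    def test_finite_height_limits_depth(self, slab):
        w = ck.cylinder_window(
            slab, (4, 4, 1), slab.gm_mask, CylinderSpec(radius=0.6, height=0.3)
        )
        # |dD| <= 0.15 keeps only the center's depth sample (spacing 0.25)
        assert len(w) == 1

    def test_center_outside_domain_raises(self, slab):
        dom = slab.gm_mask.copy()
        dom[4, 4, :] = False
        with pytest.raises(ValueError):
            ck.cylinder_window(slab, (4, 4, 1), dom)

    def test_membership_symmetry_full_depth(self, slab, rng):
        dom = slab.gm_mask & (rng.uniform(size=slab.dims) > 0.3)
        idx = [tuple(i) for i in np.argwhere(dom)[:40]]
        cyl = CylinderSpec(radius=1.0)
        windows = {c: {tuple(r) for r in ck.cylinder_window(slab, c, dom, cyl)}
                   for c in idx}
        for a in idx:
            for b in idx:
                assert (b in windows[a]) == (a in windows[b])


class TestExtendDomain:
    def test_single_voxel_grows_full_depth_column(self, slab):
        dom = np.zeros(slab.dims, bool)
        dom[5, 5, 1] = True  # single mid-depth voxel
        ext = ck.extend_domain(slab, dom)
        assert ext[5, 5].all()
        assert ext.sum() == 4

    def test_full_depth_domain_unchanged(self, slab):
        dom = np.zeros(slab.dims, bool)
        dom[2:4, 2:4, :] = True
        ext = ck.extend_domain(slab, dom)
        assert np.array_equal(ext, dom)

    def test_radius_12_includes_neighbor_columns(self, slab):
        dom = np.zeros(slab.dims, bool)
        dom[5, 5, 0] = True
        ext = ck.extend_domain(slab, dom, CylinderSpec(radius=1.2))
        # center + 4 face + 4 diagonal columns, each full depth
        assert ext.sum() == 9 * 4
        assert ext[4, 4].all() and ext[6, 5].all()

    def test_original_domain_always_contained(self, slab, rng):
        dom = slab.gm_mask & (rng.uniform(size=slab.dims) > 0.8)
        ext = ck.extend_domain(slab, dom)
        assert np.all(ext >= dom)

    def test_empty_domain_warns_empty(self, slab):
        with pytest.warns(UserWarning):
            ext = ck.extend_domain(slab, np.zeros(slab.dims, bool))
        assert not ext.any()


class TestColumnarityMap:
    def test_uniform_label_scores_exactly_one(self, slab):
        pref = ck.PreferenceMap(np.ones(slab.dims, np.int32), 4)
        cm = ck.columnarity_map(slab, pref, slab.gm_mask)
        assert np.all(cm.values() == 1.0)

    def test_window_mode_arithmetic(self):
        # One depth column with labels [1,1,2,3]: every voxel scores 0.5.
        g = ck.make_flat_slab(1, 1, 4, 0.8)
        labels = np.array([1, 1, 2, 3], np.int32).reshape(1, 1, 4)
        cm = ck.columnarity_map(g, ck.PreferenceMap(labels, 4), g.gm_mask)
        assert np.allclose(cm.values(), 0.5)
        assert np.all(cm.modal_label[g.gm_mask] == 1)  # lowest tied... mode=1

    def test_pigeonhole_lower_bound(self, fine_slab):
        pref = ck.random_preference_map(fine_slab, 4, seed=0, upsample_factor=1)
        cm = ck.columnarity_map(fine_slab, pref, fine_slab.gm_mask)
        assert cm.values().min() >= 0.25
        assert np.all(cm.window_size[fine_slab.gm_mask] >= 1)

    def test_matches_brute_force_oracle(self, rng):
        g = ck.make_flat_slab(8, 8, 3, 0.8)  # < 10^3 voxels
        dom = g.gm_mask & (rng.uniform(size=g.dims) > 0.2)
        labels = np.where(dom, rng.integers(1, 5, size=g.dims), 0).astype(np.int32)
        pref = ck.PreferenceMap(labels, 4)
        for cyl in (CylinderSpec(1.0), CylinderSpec(1.7, height=0.5)):
            cm = ck.columnarity_map(g, pref, dom, cyl)
            oracle = brute_force_columnarity(g, pref, dom, cyl)
            for c, want in oracle.items():
                assert cm.index[c] == pytest.approx(want)

    def test_oracle_on_curved_patch(self, rng):
        g = ck.make_curved_patch(10, 4, 3, 0.5, fold_amplitude=1.0, fold_period=6.0)
        labels = np.where(g.gm_mask, rng.integers(1, 5, size=g.dims), 0).astype(np.int32)
        pref = ck.PreferenceMap(labels, 4)
        cyl = CylinderSpec(0.9)
        cm = ck.columnarity_map(g, pref, g.gm_mask, cyl)
        oracle = brute_force_columnarity(g, pref, g.gm_mask, cyl)
        for c, want in oracle.items():
            assert cm.index[c] == pytest.approx(want)

    def test_hexbin_interior_windows_score_one(self, fine_slab):
        pref = ck.hexbin_ideal_map(fine_slab, 1.4, 4, seed=6)
        cm = ck.columnarity_map(fine_slab, pref, fine_slab.gm_mask)
        # windows entirely interior to one bin exist and score exactly 1
        assert (cm.values() == 1.0).any()

    def test_larger_radius_dilutes_random_map(self, fine_slab):
        pref = ck.random_preference_map(fine_slab, 4, seed=7, upsample_factor=1)
        small = ck.columnarity_map(fine_slab, pref, fine_slab.gm_mask,
                                   CylinderSpec(0.4))
        large = ck.columnarity_map(fine_slab, pref, fine_slab.gm_mask,
                                   CylinderSpec(1.0))
        assert large.values().mean() < small.values().mean()


class TestThresholdingAndSummaries:
    @pytest.fixture
    def noisy_setup(self, fine_slab, rng):
        pref = ck.hexbin_ideal_map(fine_slab, 1.0, 4, seed=8)
        labels = pref.labels.copy()
        gm = fine_slab.gm_mask
        flip = rng.uniform(size=gm.sum()) < 0.3
        noise_labels = rng.integers(1, 5, size=gm.sum())
        lab_gm = labels[gm]
        lab_gm[flip] = noise_labels[flip]
        labels[gm] = lab_gm
        noisy = ck.PreferenceMap(labels, 4)
        cm = ck.columnarity_map(fine_slab, noisy, gm)
        return fine_slab, noisy, cm

    def test_threshold_zero_is_identity(self, noisy_setup):
        g, pref, cm = noisy_setup
        out = ck.threshold_columns(cm, pref, 0.0)
        assert np.array_equal(out.labels[g.gm_mask], pref.labels[g.gm_mask])

    def test_threshold_nestedness(self, noisy_setup):
        g, pref, cm = noisy_setup
        surv = {t: ck.threshold_columns(cm, pref, t).labels > 0
                for t in (0.25, 0.50, 0.65)}
        assert np.all(surv[0.65] <= surv[0.50])
        assert np.all(surv[0.50] <= surv[0.25])

    def test_volume_fraction_monotone_non_increasing(self, noisy_setup):
        g, _, cm = noisy_setup
        tab = ck.columnar_volume_fraction(cm, g.gm_mask, np.linspace(0, 1, 21))
        assert tab.volume_pct.iloc[0] == 100.0
        assert np.all(np.diff(tab.volume_pct.to_numpy()) <= 0)

    def test_summary_matches_direct_computation(self, noisy_setup, rng):
        g, _, cm = noisy_setup
        sens = rng.uniform(1, 10, size=g.dims)
        spec = rng.uniform(size=g.dims)
        tab = ck.summarize_by_columnarity(cm, sens, spec, g.gm_mask, [0.5])
        surv = g.gm_mask & (np.nan_to_num(cm.index, nan=-1) >= 0.5)
        assert tab.mean_sensitivity[0] == pytest.approx(sens[surv].mean())
        assert tab.mean_specificity[0] == pytest.approx(spec[surv].mean())
        assert tab.volume_pct[0] == pytest.approx(100 * surv.sum() / g.gm_mask.sum())


class TestConsistency:
    def test_identical_maps_full_consistency(self, fine_slab):
        pref = ck.hexbin_ideal_map(fine_slab, 1.0, 4, seed=9)
        cm = ck.columnarity_map(fine_slab, pref, fine_slab.gm_mask)
        assert ck.consistency_score(cm, pref, cm, pref, 0.5) == 100.0

    def test_disjoint_supports_zero(self, slab):
        idx_a = np.zeros(slab.dims)
        idx_b = np.zeros(slab.dims)
        idx_a[:5], idx_b[5:] = 0.9, 0.9
        dom_a, dom_b = idx_a > 0, idx_b > 0
        def mk(idx, dom):
            return ck.ColumnarityMap(np.where(dom, idx, np.nan),
                                     dom.astype(np.int32),
                                     np.zeros(slab.dims, np.int32), dom)
        pref = ck.PreferenceMap(np.ones(slab.dims, np.int32), 4)
        assert ck.consistency_score(mk(idx_a, dom_a), pref, mk(idx_b, dom_b), pref,
                                    0.5) == 0.0

    def test_partial_agreement_arithmetic(self, slab):
        dom = np.zeros(slab.dims, bool)
        dom[0, 0:10, 0] = True  # 10 shared voxels
        idx = np.where(dom, 0.9, np.nan)
        cm = ck.ColumnarityMap(idx, dom.astype(np.int32),
                               np.zeros(slab.dims, np.int32), dom)
        la = np.where(dom, 1, 0).astype(np.int32)
        lb = la.copy()
        lb[0, 6:10, 0] = 2  # 6 of 10 labels match
        score = ck.consistency_score(cm, ck.PreferenceMap(la, 4),
                                     cm, ck.PreferenceMap(lb, 4), 0.5)
        assert score == pytest.approx(60.0)

    def test_empty_union_is_nan(self, slab):
        dom = np.zeros(slab.dims, bool)
        cm = ck.ColumnarityMap(np.full(slab.dims, np.nan),
                               np.zeros(slab.dims, np.int32),
                               np.zeros(slab.dims, np.int32), dom)
        pref = ck.PreferenceMap(np.zeros(slab.dims, np.int32), 4)
        assert np.isnan(ck.consistency_score(cm, pref, cm, pref, 0.5))


class TestBenchmarkCompare:
    def test_ideal_median_beats_random(self, fine_slab):
        rand = ck.random_preference_map(fine_slab, 4, seed=10, upsample_factor=4)
        ideal = ck.hexbin_ideal_map(fine_slab, 1.0, 4, seed=10)
        cm_r = ck.columnarity_map(fine_slab, rand, fine_slab.gm_mask)
        cm_i = ck.columnarity_map(fine_slab, ideal, fine_slab.gm_mask)
        assert np.median(cm_i.values()) > np.median(cm_r.values())

    def test_equal_inputs_trivially_in_between(self, fine_slab):
        pref = ck.random_preference_map(fine_slab, 4, seed=11)
        cm = ck.columnarity_map(fine_slab, pref, fine_slab.gm_mask)
        stats = ck.benchmark_compare(cm, cm, cm)
        assert stats["median_in_between"]
        assert stats["empirical"]["median"] == stats["random"]["median"]

    def test_noisy_columns_sit_between_benchmarks(self, fine_slab, rng):
        gm = fine_slab.gm_mask
        ideal = ck.hexbin_ideal_map(fine_slab, 1.0, 4, seed=12)
        labels = ideal.labels.copy()
        flip = rng.uniform(size=gm.sum()) < 0.3
        lab = labels[gm]
        lab[flip] = rng.integers(1, 5, size=gm.sum())[flip]
        labels[gm] = lab
        noisy = ck.PreferenceMap(labels, 4)
        rand = ck.random_preference_map(fine_slab, 4, seed=12, upsample_factor=4)
        cm_e = ck.columnarity_map(fine_slab, noisy, gm)
        cm_r = ck.columnarity_map(fine_slab, rand, gm)
        cm_i = ck.columnarity_map(fine_slab, ideal, gm)
        stats = ck.benchmark_compare(cm_e, cm_r, cm_i)
        assert stats["median_in_between"]
        assert stats["random"]["median"] < stats["empirical"]["median"] \
            < stats["ideal"]["median"]
        # whiskers follow the 1.5*IQR convention and bracket the box
        for key in ("empirical", "random", "ideal"):
            s = stats[key]
            assert s["whisker_low"] <= s["q1"] <= s["median"] <= s["q3"] \
                <= s["whisker_high"]
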