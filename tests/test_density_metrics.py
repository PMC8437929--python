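"""Density rendering, warping and congruence metrics vs. brute-force oracles."""

import numpy as np
import pytest

from drteval import (DensityMap, MetricParams, Tractogram, WarpField,
                     cog_distance_profile, dice_profile, render_density,
                     slice_cog, validity_cog, warp_density)
from drteval._grid import nearest_voxel, in_bounds, resample_polyline


# ---------------------------------------------------------------------------
# independent reference implementations (plain loops)
# ---------------------------------------------------------------------------

def brute_cog(data, affine, k):
    total, sx, sy = 0.0, 0.0, 0.0
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            m = data[i, j, k]
            if m:
                x = affine[0, 0] * i + affine[0, 3]
                y = affine[1, 1] * j + affine[1, 3]
                total += m
                sx += m * x
                sy += m * y
    return None if total == 0 else (sx / total, sy / total)


def brute_cog_profile(d1, d2, params):
    out = []
    for z in params.z_levels():
        k = int(round((z - d1.affine[2, 3]) / d1.affine[2, 2]))
        c1 = brute_cog(d1.data, d1.affine, k)
        c2 = brute_cog(d2.data, d2.affine, k)
        if c1 is None or c2 is None:
            out.append(np.nan)
        else:
            out.append(((c1[0] - c2[0]) ** 2 + (c1[1] - c2[1]) ** 2) ** 0.5)
    return np.array(out)


def brute_dice_profile(d1, d2, params):
    out = []
    for z in params.z_levels():
        k = int(round((z - d1.affine[2, 3]) / d1.affine[2, 2]))
        inter = a_only = b_only = 0
        for i in range(d1.data.shape[0]):
            for j in range(d1.data.shape[1]):
                a = d1.data[i, j, k] >= params.dice_threshold
                b = d2.data[i, j, k] >= params.dice_threshold
                inter += a and b
                a_only += a
                b_only += b
        out.append(2 * inter / (a_only + b_only)
                   if (a_only + b_only) else np.nan)
    return np.array(out)


def brute_visited_voxels(streamline, affine, shape):
    pts = resample_polyline(streamline, 0.5 * affine[0, 0])
    seen = set()
    for p in pts:
        v = tuple(nearest_voxel(affine, p[None])[0])
        if all(0 <= v[a] < shape[a] for a in range(3)):
            seen.add(v)
    return seen


def _grid_affine(n, voxel=1.0):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = -voxel * (n // 2)
    return aff


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

class TestRenderDensity:
    def test_straight_streamline_marks_its_row_once(self):
        aff = np.eye(4)
        sl = np.array([[0.0, 5, 5], [9.0, 5, 5]])
        dm = render_density(Tractogram(streamlines=[sl]), (10, 10, 10), aff)
        assert np.all(dm.data[:, 5, 5] == 1)
        dm.data[:, 5, 5] = 0
        assert not dm.data.any()

    def test_duplicate_streamlines_double_the_count(self):
        aff = np.eye(4)
        sl = np.array([[0.0, 5, 5], [9.0, 5, 5]])
        dm = render_density(Tractogram(streamlines=[sl, sl.copy()]),
                            (10, 10, 10), aff)
        assert np.all(dm.data[:, 5, 5] == 2)

    def test_u_turn_counts_revisited_voxel_once(self):
        aff = np.eye(4)
        u = np.array([[0.0, 2, 5], [6, 2, 5], [6, 8, 5], [0, 8, 5],
                      [0, 2.6, 5]])  # re-enters the first row's voxels
        dm = render_density(Tractogram(streamlines=[u]), (10, 10, 10), aff)
        oracle = brute_visited_voxels(u, aff, (10, 10, 10))
        assert dm.data.max() == 1
        assert {tuple(v) for v in np.argwhere(dm.data > 0)} == oracle

    def test_value_never_exceeds_streamline_count(self):
        rng = np.random.default_rng(1)
        sls = [np.cumsum(rng.uniform(-1, 1, (15, 3)), axis=0) + 8
               for _ in range(7)]
        dm = render_density(Tractogram(streamlines=sls), (16, 16, 16),
                            np.eye(4))
        assert dm.data.max() <= 7


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

class TestWarpDensity:
    def test_zero_warp_is_identity_on_matched_grids(self):
        n = 12
        aff = _grid_affine(n)
        rng = np.random.default_rng(0)
        dm = DensityMap(rng.integers(0, 5, (n, n, n)).astype(float), aff)
        warp = WarpField(np.zeros((n, n, n, 3)), aff)
        out = warp_density(dm, warp)
        assert np.allclose(out.data, dm.data)
        assert out.space_tag == "template"

    def test_translation_moves_point_mass_exactly(self):
        n = 16
        aff = _grid_affine(n)
        dm = DensityMap(np.zeros((n, n, n)), aff)
        dm.data[8, 8, 8] = 7.0
        disp = np.zeros((n, n, n, 3))
        disp[..., 0] = 2.0  # sample native 2 mm toward +x
        out = warp_density(dm, WarpField(disp, aff))
        expected = np.zeros((n, n, n))
        expected[6, 8, 8] = 7.0  # mass appears shifted by -2 voxels
        assert np.allclose(out.data, expected)

    def test_smooth_small_warp_conserves_blob_mass(self):
        from drteval import make_warp
        n = 24
        aff = _grid_affine(n)
        data = np.zeros((n, n, n))
        data[8:16, 8:16, 8:16] = 3.0
        warp = make_warp((n, n, n), aff, amplitude_mm=0.5, max_frequency=1,
                         seed=2)
        out = warp_density(DensityMap(data, aff), warp)
        assert abs(out.data.sum() - data.sum()) / data.sum() < 0.10

    def test_grid_mismatch_rejected(self):
        dm = DensityMap(np.zeros((8, 8, 8)), np.eye(4))
        warp = WarpField(np.zeros((6, 6, 6, 3)), np.eye(4))
        with pytest.raises(ValueError, match="grid"):
            warp_density(dm, warp, template_shape=(8, 8, 8))


# ---------------------------------------------------------------------------
# slice statistics
# ---------------------------------------------------------------------------

class TestSliceCOG:
    def test_point_mass_returns_voxel_centre(self):
        aff = _grid_affine(10)
        dm = DensityMap(np.zeros((10, 10, 10)), aff)
        dm.data[7, 3, 5] = 4.0
        cog = slice_cog(dm, z_level=0.0)
        assert cog == pytest.approx((aff[0, 0] * 7 + aff[0, 3],
                                     aff[1, 1] * 3 + aff[1, 3]))

    def test_two_equal_masses_average(self):
        dm = DensityMap(np.zeros((12, 12, 12)), np.eye(4))
        dm.data[0, 4, 6] = 2.0
        dm.data[10, 4, 6] = 2.0
        assert slice_cog(dm, 6.0) == pytest.approx((5.0, 4.0))

    def test_hand_filled_slice_matches_explicit_sum(self):
        dm = DensityMap(np.zeros((4, 4, 4)), np.eye(4))
        dm.data[0, 1, 2] = 1
        dm.data[1, 0, 2] = 3
        dm.data[2, 3, 2] = 2
        cog = slice_cog(dm, 2.0)
        total = 1 + 3 + 2
        assert cog == pytest.approx(((0 * 1 + 1 * 3 + 2 * 2) / total,
                                     (1 * 1 + 0 * 3 + 3 * 2) / total))

    def test_empty_slice_is_undefined(self):
        dm = DensityMap(np.zeros((4, 4, 4)), np.eye(4))
        assert slice_cog(dm, 1.0) is None

    def test_out_of_volume_level_is_error(self):
        dm = DensityMap(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="outside"):
            slice_cog(dm, 40.0)


def _small_params(n=16):
    half = n // 2
    return MetricParams(z_min=-half + 1, z_max=half - 2, dice_threshold=2.0,
                        eval_levels={"mid": 0.0})


class TestProfiles:
    def test_identical_maps_give_zero_distance_everywhere(self):
        n = 16
        aff = _grid_affine(n)
        rng = np.random.default_rng(3)
        d = DensityMap(rng.integers(0, 6, (n, n, n)).astype(float), aff)
        res = cog_distance_profile(d, d, _small_params(n))
        defined = np.isfinite(res.cog_distance_mm)
        assert defined.any()
        assert np.allclose(res.cog_distance_mm[defined], 0.0)
        assert res.aggregate()["cog_median_mm"] == 0.0

    def test_three_four_five_offset(self):
        n = 20
        aff = _grid_affine(n)
        a = np.zeros((n, n, n))
        b = np.zeros((n, n, n))
        a[6, 6, :] = 5.0
        b[9, 10, :] = 5.0  # (+3, +4) mm in-plane on every slice
        res = cog_distance_profile(DensityMap(a, aff), DensityMap(b, aff),
                                   _small_params(n))
        assert np.allclose(res.cog_distance_mm, 5.0)

    def test_random_pairs_match_brute_force(self):
        rng = np.random.default_rng(7)
        params = _small_params(12)
        for _ in range(20):
            aff = _grid_affine(12)
            d1 = DensityMap(rng.integers(0, 5, (12, 12, 12)).astype(float), aff)
            d2 = DensityMap(rng.integers(0, 5, (12, 12, 12)).astype(float), aff)
            res_c = cog_distance_profile(d1, d2, params)
            res_d = dice_profile(d1, d2, params)
            oc = brute_cog_profile(d1, d2, params)
            od = brute_dice_profile(d1, d2, params)
            assert np.allclose(res_c.cog_distance_mm, oc, atol=1e-9,
                               equal_nan=True)
            assert np.array_equal(np.nan_to_num(res_d.dice, nan=-1),
                                  np.nan_to_num(od, nan=-1))

    def test_dice_identical_one_disjoint_zero_partial_half(self):
        n = 12
        aff = _grid_affine(n)
        params = _small_params(n)
        a = np.zeros((n, n, n))
        a[3:5, 3:5, 6] = 2.0  # 4 suprathreshold voxels
        b = np.zeros((n, n, n))
        b[4:6, 3:5, 6] = 2.0  # 4 voxels, overlap 2
        z = 6 + aff[2, 3]
        da, db = DensityMap(a, aff), DensityMap(b, aff)
        assert dice_profile(da, da, params).at_level(z)["dice"] == 1.0
        assert dice_profile(da, db, params).at_level(z)["dice"] == 0.5
        c = np.zeros((n, n, n))
        c[8:10, 8:10, 6] = 2.0
        assert dice_profile(da, DensityMap(c, aff), params) \
            .at_level(z)["dice"] == 0.0

    def test_grid_mismatch_rejected(self):
        d1 = DensityMap(np.zeros((8, 8, 8)), np.eye(4))
        d2 = DensityMap(np.zeros((8, 8, 8)), np.diag([2.0, 1, 1, 1]))
        with pytest.raises(ValueError, match="grid"):
            cog_distance_profile(d1, d2, _small_params(8))


class TestValidity:
    def test_point_mass_inside_reference(self):
        n = 16
        aff = _grid_affine(n)
        dm = DensityMap(np.zeros((n, n, n)), aff)
        dm.data[8, 8, 8] = 5.0
        ref = np.zeros((n, n, n), dtype=bool)
        ref[7:10, 7:10, 8] = True
        params = _small_params(n)
        res = validity_cog(dm, params, {"mid": ref})
        lvl = res.levels["mid"]
        assert lvl["inside"] and lvl["distance_mm"] == 0.0

    def test_lateral_offset_distance(self):
        n = 16
        aff = _grid_affine(n)
        dm = DensityMap(np.zeros((n, n, n)), aff)
        dm.data[11, 8, 8] = 1.0
        ref = np.zeros((n, n, n), dtype=bool)
        ref[8, 8, 8] = True  # 3 mm medial on a 1 mm grid
        res = validity_cog(dm, _small_params(n), {"mid": ref})
        lvl = res.levels["mid"]
        assert not lvl["inside"]
        assert lvl["distance_mm"] == pytest.approx(3.0)

    def test_empty_slice_flagged_not_error(self):
        n = 16
        dm = DensityMap(np.zeros((n, n, n)), _grid_affine(n))
        ref = np.ones((n, n, n), dtype=bool)
        res = validity_cog(dm, _small_params(n), {"mid": ref})
        assert res.levels["mid"]["defined"] is False
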