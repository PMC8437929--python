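"""Waypoint selection: dilation geometry, visit semantics, oracle equivalence."""

import numpy as np
import pytest

from drteval import (MaskSet, SelectionSpec, Tractogram, apply_exclusions,
                     dilate_mask, resolve_sides, select_drt,
                     streamline_visits)
from drteval._grid import nearest_voxel, in_bounds


def offset_count_oracle(radius_mm, voxel_mm):
    """Integer offsets (dx,dy,dz) whose centre distance is <= radius."""
    r = int(np.ceil(radius_mm / voxel_mm))
    count = 0
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                if (dx ** 2 + dy ** 2 + dz ** 2) * voxel_mm ** 2 \
                        <= radius_mm ** 2 + 1e-9:
                    count += 1
    return count


def brute_force_select(tractogram, masks, spec):
    """Per-point membership scan over the streamline's own (dense) points."""
    sides = resolve_sides(spec)
    req = {
        "DN": masks[f"DN_{sides['DN']}"],
        "RN": dilate_mask(masks[f"RN_{sides['RN']}"], spec.rn_dilation_mm,
                          masks.affine),
        "PG": masks[f"PG_{sides['PG']}"],
    }
    kept = []
    for sl in tractogram:
        vox = nearest_voxel(masks.affine, sl)
        vox = vox[in_bounds(vox, masks.shape)]
        if len(vox) == 0:
            continue
        if all(m[vox[:, 0], vox[:, 1], vox[:, 2]].any() for m in req.values()):
            kept.append(sl)
    return kept


class TestDilation:
    affine1 = np.eye(4)
    affine2 = np.diag([2.0, 2.0, 2.0, 1.0])

    def _single_voxel(self, n=9):
        m = np.zeros((n, n, n), dtype=bool)
        m[n // 2, n // 2, n // 2] = True
        return m

    def test_radius_zero_is_identity(self):
        m = self._single_voxel()
        assert np.array_equal(dilate_mask(m, 0.0, self.affine1), m)

    @pytest.mark.parametrize("voxel,expected", [(1.0, 33), (2.0, 7)])
    def test_two_mm_ball_counts_match_offset_enumeration(self, voxel, expected):
        aff = np.diag([voxel, voxel, voxel, 1.0])
        out = dilate_mask(self._single_voxel(), 2.0, aff)
        assert out.sum() == expected == offset_count_oracle(2.0, voxel)

    def test_monotone_in_radius_and_contains_input(self):
        m = self._single_voxel(11)
        prev = m
        for r in (0.5, 1.0, 2.0, 3.5):
            cur = dilate_mask(m, r, self.affine1)
            assert not (m & ~cur).any()
            assert not (prev & ~cur).any()
            prev = cur

    def test_anisotropic_voxels_use_world_distance(self):
        # 1.5 x 1.5 x 3 mm voxels: a 2 mm radius reaches in-plane
        # neighbours but not the 3 mm-away slice neighbours
        aff = np.diag([1.5, 1.5, 3.0, 1.0])
        out = dilate_mask(self._single_voxel(), 2.0, aff)
        assert out.sum() == offset_count_oracle_aniso((1.5, 1.5, 3.0), 2.0)


def offset_count_oracle_aniso(voxel, radius):
    r = [int(np.ceil(radius / v)) for v in voxel]
    count = 0
    for dx in range(-r[0], r[0] + 1):
        for dy in range(-r[1], r[1] + 1):
            for dz in range(-r[2], r[2] + 1):
                d2 = (dx * voxel[0]) ** 2 + (dy * voxel[1]) ** 2 \
                    + (dz * voxel[2]) ** 2
                count += d2 <= radius ** 2 + 1e-9
    return count


class TestVisits:
    affine = np.eye(4)

    def test_through_central_voxel(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        sl = np.array([[0.0, 2, 2], [4, 2, 2]])
        assert streamline_visits(sl, m, self.affine)

    def test_outside_bounding_box(self):
        m = np.ones((5, 5, 5), dtype=bool)
        sl = np.array([[10.0, 10, 10], [20, 20, 20]])
        assert not streamline_visits(sl, m, self.affine)

    def test_coarse_segment_is_resampled_through_thin_mask(self):
        # two stored points straddle a one-voxel mask; resampling must
        # detect the crossing that a raw point test would miss
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = True
        sl = np.array([[0.0, 4, 4], [8, 4, 4]])
        raw_vox = nearest_voxel(self.affine, sl)
        assert not m[raw_vox[:, 0], raw_vox[:, 1], raw_vox[:, 2]].any()
        assert streamline_visits(sl, m, self.affine)


def _toy_masks(n=16):
    """DN/RN/PG per side as small blocks on an n^3 1 mm grid."""
    def block(c, h=1):
        m = np.zeros((n, n, n), dtype=np.uint8)
        m[c[0] - h:c[0] + h + 1, c[1] - h:c[1] + h + 1,
          c[2] - h:c[2] + h + 1] = 1
        return m
    masks = {
        "DN_L": block((3, 3, 2)), "DN_R": block((12, 3, 2)),
        "RN_L": block((4, 8, 7)), "RN_R": block((11, 8, 7)),
        "PG_L": block((3, 12, 13)), "PG_R": block((12, 12, 13)),
    }
    return MaskSet(masks=masks, affine=np.eye(4))


def _polyline(points):
    return np.asarray(points, dtype=float)


class TestSelectDRT:
    def test_hand_built_visit_table(self):
        masks = _toy_masks()
        hits_all = _polyline([[3, 3, 2], [4, 8, 7], [3, 12, 13]])
        # climbs far from RN (stays at y=3 until z=13, > 2 mm clearance)
        misses_rn = _polyline([[3, 3, 2], [3, 3, 13], [3, 12, 13]])
        misses_pg = _polyline([[3, 3, 2], [4, 8, 7], [8, 8, 8]])
        tg = Tractogram(streamlines=[hits_all, misses_rn, misses_pg])
        sel = select_drt(tg, masks, SelectionSpec(variant="uncrossed",
                                                  dn_side="L"))
        assert len(sel) == 1
        assert np.array_equal(sel.streamlines[0], hits_all)

    def test_empty_input_gives_empty_output(self):
        sel = select_drt(Tractogram(streamlines=[]), _toy_masks(),
                         SelectionSpec())
        assert len(sel) == 0

    def test_subset_and_idempotent(self):
        masks = _toy_masks()
        rng = np.random.default_rng(0)
        sls = [np.cumsum(rng.uniform(-1.5, 1.5, (20, 3)), axis=0) + [8, 8, 8]
               for _ in range(30)]
        tg = Tractogram(streamlines=sls)
        spec = SelectionSpec(variant="uncrossed", dn_side="L")
        once = select_drt(tg, masks, spec)
        twice = select_drt(once, masks, spec)
        assert len(twice) == len(once) <= len(tg)
        ids = {id(s) for s in tg.streamlines}
        assert all(id(s) in ids for s in once.streamlines)

    @pytest.mark.parametrize("variant,dn_side", [("uncrossed", "L"),
                                                 ("crossed", "L"),
                                                 ("crossed", "R")])
    def test_matches_brute_force_membership_scan(self, variant, dn_side):
        """On dense toy tractograms, selection equals the per-point scan."""
        masks = _toy_masks()
        rng = np.random.default_rng(42)
        sls = []
        for _ in range(50):
            start = rng.uniform(1, 15, 3)
            steps = rng.uniform(-0.4, 0.4, (60, 3))  # dense: < half voxel
            sls.append(np.cumsum(np.vstack([start, steps]), axis=0))
        tg = Tractogram(streamlines=sls)
        spec = SelectionSpec(variant=variant, dn_side=dn_side)
        ours = select_drt(tg, masks, spec)
        oracle = brute_force_select(tg, masks, spec)
        assert len(ours) == len(oracle)
        for a, b in zip(ours.streamlines, oracle):
            assert np.array_equal(a, b)

    def test_missing_mask_is_explicit_error(self):
        masks = _toy_masks()
        del masks.masks["PG_R"]
        with pytest.raises(KeyError, match="PG_R"):
            select_drt(Tractogram(streamlines=[]), masks,
                       SelectionSpec(variant="crossed", dn_side="L"))


class TestLaterality:
    def test_default_convention_crossed_is_contralateral(self):
        sides = resolve_sides(SelectionSpec(variant="crossed", dn_side="L"))
        assert sides == {"DN": "L", "RN": "R", "PG": "R"}
        sides = resolve_sides(SelectionSpec(variant="uncrossed", dn_side="L"))
        assert sides == {"DN": "L", "RN": "L", "PG": "L"}

    def test_alternate_convention_flips_both_variants(self):
        sides = resolve_sides(SelectionSpec(variant="uncrossed", dn_side="L",
                                            laterality="drtu_crosses"))
        assert sides == {"DN": "L", "RN": "R", "PG": "R"}
        sides = resolve_sides(SelectionSpec(variant="crossed", dn_side="R",
                                            laterality="drtu_crosses"))
        assert sides == {"DN": "R", "RN": "R", "PG": "R"}


class TestExclusions:
    affine = np.eye(4)

    def _tg(self):
        a = _polyline([[1, 4, 4], [4, 4, 4], [7, 4, 4]])
        b = _polyline([[1, 1, 1], [7, 1, 1]])
        return Tractogram(streamlines=[a, b])

    def test_midpoint_exclusion_removes_streamline(self):
        excl = np.zeros((9, 9, 9), dtype=bool)
        excl[4, 4, 4] = True
        out = apply_exclusions(self._tg(), [excl], self.affine)
        assert len(out) == 1
        assert np.array_equal(out.streamlines[0],
                              self._tg().streamlines[1])

    def test_empty_exclusion_list_is_identity(self):
        tg = self._tg()
        out = apply_exclusions(tg, [], self.affine)
        assert len(out) == len(tg)

    def test_whole_volume_exclusion_empties_tractogram(self):
        excl = np.ones((9, 9, 9), dtype=bool)
        assert len(apply_exclusions(self._tg(), [excl], self.affine)) == 0
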