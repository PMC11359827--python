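"""Region initialization: radius/threshold formulas, components,
enhancement, and quasi-sphere algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from airwayseg import (
    Config,
    CTVolume,
    HU_FLOOR,
    RegionContext,
    build_quasi_sphere,
    compute_region_radius,
    compute_threshold_params,
    dilate_ball,
    enhance_walls,
    extract_seed_surfaces,
    init_region,
    sphere_element,
)
from airwayseg.volume_io import CropBox, bbox_of_mask


class TestSphereElement:
    def test_radius_one_is_face_cross(self):
        el = sphere_element(1)
        assert el.sum() == 7
        assert el[1, 1, 1] and el[0, 1, 1] and el[1, 0, 1] and el[1, 1, 0]
        assert not el[0, 0, 0]

    @pytest.mark.parametrize("R", [1, 2, 3, 5])
    def test_matches_enumeration_oracle(self, R):
        """Element equals the brute-force enumeration of |offset| <= R."""
        count = 0
        for x in range(-R, R + 1):
            for y in range(-R, R + 1):
                for z in range(-R, R + 1):
                    if x * x + y * y + z * z <= R * R:
                        count += 1
        el = sphere_element(R)
        assert el.shape == (2 * R + 1,) * 3
        assert el.sum() == count
        assert el[R, R, R]

    def test_radius_two_has_33_voxels(self):
        assert sphere_element(2).sum() == 33

    def test_symmetry_under_axis_permutation_and_flip(self):
        el = sphere_element(3)
        for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            np.testing.assert_array_equal(el, el.transpose(perm))
        np.testing.assert_array_equal(el, el[::-1], err_msg="flip x")
        np.testing.assert_array_equal(el, el[:, ::-1])

    def test_rejects_radius_below_one(self):
        with pytest.raises(ValueError):
            sphere_element(0)


class TestDilateBall:
    def test_equals_structuring_element_dilation(self):
        """EDT-based ball dilation is exactly binary_dilation with Sphere(R)."""
        rng = np.random.default_rng(0)
        for R in (1, 3, 8):
            mask = np.zeros((25, 25, 25), dtype=bool)
            pts = rng.integers(5, 20, size=(4, 3))
            mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            ref = ndimage.binary_dilation(mask, structure=sphere_element(R))
            np.testing.assert_array_equal(dilate_ball(mask, R), ref)


class TestRegionRadius:
    @pytest.mark.parametrize("area,expected", [(1, 8), (100, 8), (101, 11), (250, 14)])
    def test_formula_values(self, area, expected):
        assert compute_region_radius(area) == expected

    @given(st.integers(min_value=1, max_value=5000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nondecreasing_and_floored(self, area):
        R = compute_region_radius(area)
        assert R >= 8
        assert R >= compute_region_radius(max(area - 1, 1))


class TestThresholdParams:
    def test_enumerated_multiset(self):
        seed, thr = compute_threshold_params(np.array([-950, -920, -900]))
        assert (seed, thr) == (-950, 51)

    def test_constant_surface_gives_unit_threshold(self):
        seed, thr = compute_threshold_params(np.full(30, -1000))
        assert (seed, thr) == (-1000, 1)

    @given(st.lists(st.integers(min_value=-2048, max_value=500),
                    min_size=1, max_size=100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_scan_oracle(self, values):
        lo = hi = values[0]
        for v in values[1:]:
            lo, hi = min(lo, v), max(hi, v)
        assert compute_threshold_params(np.array(values)) == (lo, hi - lo + 1)


class TestExtractSeedSurfaces:
    def test_empty_mask_gives_empty_list(self):
        vol = CTVolume(np.full((5, 5, 5), -1000))
        assert extract_seed_surfaces(np.zeros((5, 5, 5), bool), vol) == []

    def test_corner_touching_voxels_are_one_component(self):
        vol = CTVolume(np.full((4, 4, 4), -1000))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        surfaces = extract_seed_surfaces(mask, vol)
        assert len(surfaces) == 1
        assert surfaces[0].area == 2

    def test_partition_matches_flood_fill_oracle(self):
        """Component partition equals a BFS flood fill with 26-connectivity."""
        rng = np.random.default_rng(11)
        mask = rng.random((12, 12, 12)) < 0.08
        vol = CTVolume(rng.integers(-1100, -900, size=mask.shape))
        surfaces = extract_seed_surfaces(mask, vol)
        # BFS oracle
        seen = np.zeros_like(mask)
        comps = []
        offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
        for start in map(tuple, np.argwhere(mask)):
            if seen[start]:
                continue
            queue, comp = [start], set()
            seen[start] = True
            while queue:
                v = queue.pop()
                comp.add(v)
                for o in offs:
                    w = tuple(a + b for a, b in zip(v, o))
                    if all(0 <= c < 12 for c in w) and mask[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
            comps.append(comp)
        got = [set(map(tuple, s.voxels)) for s in surfaces]
        assert sorted(map(sorted, got)) == sorted(map(sorted, comps))
        # disjoint and union equals mask
        union = set().union(*got) if got else set()
        assert len(union) == int(mask.sum())
        # surface_hu read from the volume at the component voxels
        for s in surfaces:
            np.testing.assert_array_equal(
                s.surface_hu, vol.data[s.voxels[:, 0], s.voxels[:, 1], s.voxels[:, 2]])

    def test_shape_mismatch_raises(self):
        vol = CTVolume(np.full((5, 5, 5), -1000))
        with pytest.raises(ValueError):
            extract_seed_surfaces(np.zeros((4, 4, 4), bool), vol)


class TestEnhanceWalls:
    def test_constant_volume_unchanged(self):
        vol = CTVolume(np.full((6, 6, 6), -900))
        out = enhance_walls(vol, 300)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_bright_plane_raised_exactly(self):
        """A 1-voxel bright plane in dark background gains `strength` HU;
        every other voxel is untouched (hand-enumerable 7x7x7 fixture)."""
        data = np.full((7, 7, 7), -1000, dtype=np.int64)
        data[3, :, :] = -300
        out = enhance_walls(CTVolume(data), 300)
        np.testing.assert_array_equal(out.data[3], np.full((7, 7), 0))
        rest = np.ones((7, 7, 7), bool)
        rest[3] = False
        np.testing.assert_array_equal(out.data[rest], data[rest])

    def test_zero_strength_is_identity_twice(self):
        rng = np.random.default_rng(2)
        vol = CTVolume(rng.integers(-1100, -300, size=(6, 6, 6)))
        once = enhance_walls(vol, 0)
        twice = enhance_walls(once, 0)
        np.testing.assert_array_equal(twice.data, vol.data)

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError):
            enhance_walls(CTVolume(np.full((2, 5, 5), -1000)), 300)


def _context_from_seed_mask(mask, R, T=None):
    shape = mask.shape
    T = T if T is not None else CTVolume(np.full(shape, -1000))
    return RegionContext(
        K=1, R=R, Seed=-1000, Threshold=100, Threshold0=100,
        box=CropBox((0, 0, 0), shape, shape), T=T, P_area0=mask,
    )


class TestQuasiSphere:
    def test_single_voxel_seed_gives_digital_ball(self):
        mask = np.zeros((21, 21, 21), bool)
        mask[10, 10, 10] = True
        ctx = _context_from_seed_mask(mask, R=8)
        qs = build_quasi_sphere(ctx)
        assert qs.region.sum() == sphere_element(8).sum()
        inner = dilate_ball(mask, 7)
        np.testing.assert_array_equal(qs.shell, qs.region & ~inner)
        assert not (qs.shell & inner).any()
        np.testing.assert_array_equal(qs.shell | inner, qs.region)

    def test_restricted_is_floor_off_region(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((30, 30, 30), bool)
        mask[15, 14:17, 14:17] = True
        T = CTVolume(rng.integers(-1200, 0, size=(30, 30, 30)))
        ctx = _context_from_seed_mask(mask, R=8, T=T)
        qs = build_quasi_sphere(ctx)
        assert (qs.restricted[~qs.region] == HU_FLOOR).all()
        np.testing.assert_array_equal(qs.restricted[qs.region], T.data[qs.region])

    def test_plate_seed_region_exceeds_ball(self):
        """A 3x3 plate dilated by Sphere(8) is a quasi-sphere, strictly
        larger than the pure ball."""
        mask = np.zeros((25, 25, 25), bool)
        mask[12, 11:14, 11:14] = True
        ctx = _context_from_seed_mask(mask, R=8)
        qs = build_quasi_sphere(ctx)
        ref = ndimage.binary_dilation(mask, structure=sphere_element(8))
        np.testing.assert_array_equal(qs.region, ref)
        assert qs.region.sum() > sphere_element(8).sum()

    def test_random_seed_masks_satisfy_shell_algebra(self):
        """Shell = dilate(R) \\ dilate(R-1), disjointness and restricted
        fill checked voxelwise for random seeds in 32^3."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            mask = np.zeros((32, 32, 32), bool)
            pts = rng.integers(10, 22, size=(int(rng.integers(1, 6)), 3))
            mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            T = CTVolume(rng.integers(-1100, -800, size=(32, 32, 32)))
            R = int(rng.integers(8, 12))
            ctx = _context_from_seed_mask(mask, R=R, T=T)
            ctx.R = R
            qs = build_quasi_sphere(ctx)
            outer = dilate_ball(mask, R)
            inner = dilate_ball(mask, R - 1)
            np.testing.assert_array_equal(qs.shell, outer & ~inner)
            assert not (qs.shell & inner).any()
            assert (qs.restricted[~outer] == HU_FLOOR).all()


class TestInitRegion:
    def test_composition_on_tube_surface(self, clean_phantom):
        """A disc-like surface of area < 100 gives R=8 and a crop equal to
        the surface bbox expanded by 8 (clamped)."""
        vol = clean_phantom.volume
        mask = np.zeros(vol.shape, bool)
        mask[44:53, 44:53, 10] = clean_phantom.lumen[44:53, 44:53, 10]
        surfaces = extract_seed_surfaces(mask, vol)
        assert len(surfaces) == 1
        s = surfaces[0]
        assert s.area < 100
        ctx = init_region(s, vol, Config())
        assert ctx.R == 8
        assert ctx.box.lo == tuple(max(0, l - 8) for l in s.bbox.lo)
        assert ctx.box.hi == tuple(min(n, h + 8)
                                   for h, n in zip(s.bbox.hi, vol.shape))
        assert ctx.Threshold0 == ctx.Threshold
        # the floor applies: plateau surfaces span far less than 100 HU
        assert ctx.Threshold == Config().region.initial_threshold_override

    def test_corner_surface_crop_clamped(self):
        vol = CTVolume(np.full((20, 20, 20), -1000))
        mask = np.zeros((20, 20, 20), bool)
        mask[0, 0, 0] = True
        s = extract_seed_surfaces(mask, vol)[0]
        ctx = init_region(s, vol, Config())
        assert ctx.box.lo == (0, 0, 0)

    def test_enhancement_changes_only_wall_voxels(self, clean_phantom):
        vol = clean_phantom.volume
        mask = np.zeros(vol.shape, bool)
        mask[:, :, 10] = clean_phantom.lumen[:, :, 10]
        s = extract_seed_surfaces(mask, vol)[0]
        cfg_off = Config()
        cfg_off.region.enhancement = False
        cfg_on = Config()
        ctx_off = init_region(s, vol, cfg_off)
        ctx_on = init_region(s, vol, cfg_on)
        assert (ctx_off.Seed, ctx_off.Threshold) == (ctx_on.Seed, ctx_on.Threshold)
        diff = ctx_on.T.data != ctx_off.T.data
        # enhanced voxels exist, never inside the lumen
        lumen_crop = clean_phantom.lumen[ctx_on.box.slices]
        assert diff.any()
        assert not (diff & lumen_crop).any()
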