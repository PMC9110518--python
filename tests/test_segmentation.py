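import numpy as np
import pytest

from bonequant import (
    GeometryError,
    ImageVolume,
    InputError,
    SeedRegion,
    SegmentationError,
    ThresholdParams,
    define_control_voi,
    segment_lesion_voi,
)
from bonequant.segmentation import ROLE_CONTROL, ROLE_LESION_TARGET, grow_voi
from bonequant.volumes import UNITS_SUV_PERCENT


def _suv_volume(data, spacing=(3.9, 3.9, 3.9)):
    shape = data.shape
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    return ImageVolume(
        data=np.asarray(data, float), spacing=spacing, origin=origin,
        units=UNITS_SUV_PERCENT,
    )


def _sphere_volume(radius_mm=12.0, value=8.0, shape=(32, 32, 32)):
    vol = _suv_volume(np.zeros(shape))
    centers = vol.voxel_centers()
    inside = np.sum(centers**2, axis=-1) <= radius_mm**2
    return vol.with_data(np.where(inside, value, 0.0)), inside


class TestLesionSegmentation:
    def test_uniform_sphere_recovered_exactly(self):
        vol, inside = _sphere_volume()
        seed = SeedRegion("box", (0, 0, 0), half_extents_mm=(20, 20, 20))
        voi = segment_lesion_voi(vol, seed)
        np.testing.assert_array_equal(voi.mask.data, inside)
        assert voi.role == "lesion"
        assert voi.threshold_used is not None
        # every VOI voxel is supra-threshold (closed test)
        assert (vol.data[voi.mask.data] >= voi.threshold_used.threshold).all()

    def test_connectivity_excludes_disjoint_blob(self):
        vol, _ = _sphere_volume(radius_mm=10.0)
        data = vol.data.copy()
        # second hot blob in a far corner, hotter than the first
        data[1:4, 1:4, 1:4] = 20.0
        vol2 = vol.with_data(data)
        seed = SeedRegion("box", (0, 0, 0), half_extents_mm=(15, 15, 15))
        voi = segment_lesion_voi(vol2, seed)
        assert not voi.mask.data[1:4, 1:4, 1:4].any()
        assert voi.mask.data[16, 16, 16]

    def test_pure_background_seed_errors(self):
        vol = _suv_volume(np.zeros((16, 16, 16)))
        seed = SeedRegion("box", (0, 0, 0), half_extents_mm=(10, 10, 10))
        with pytest.raises(SegmentationError):
            segment_lesion_voi(vol, seed)

    def test_seed_outside_grid_errors(self):
        vol, _ = _sphere_volume()
        seed = SeedRegion("box", (500, 500, 500), half_extents_mm=(5, 5, 5))
        with pytest.raises(GeometryError):
            segment_lesion_voi(vol, seed)

    def test_control_role_rejected(self):
        vol, _ = _sphere_volume()
        seed = SeedRegion("sphere", (0, 0, 0), radius_mm=10, role=ROLE_CONTROL)
        with pytest.raises(InputError):
            segment_lesion_voi(vol, seed)

    def test_voi_is_single_26_connected_component(self):
        from scipy import ndimage

        vol, _ = _sphere_volume()
        seed = SeedRegion("box", (0, 0, 0), half_extents_mm=(20, 20, 20))
        voi = segment_lesion_voi(vol, seed)
        _, n = ndimage.label(voi.mask.data, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_no_hole_filling_excludes_cold_core(self):
        vol, inside = _sphere_volume(radius_mm=14.0, value=8.0)
        centers = vol.voxel_centers()
        core = np.sum(centers**2, axis=-1) <= 6.0**2
        data = vol.data.copy()
        data[core] = 0.0
        shell = inside & ~core
        voi = segment_lesion_voi(
            vol.with_data(data),
            SeedRegion("box", (0, 0, 0), half_extents_mm=(20, 20, 20)),
        )
        np.testing.assert_array_equal(voi.mask.data, shell)

    def test_raising_sd_multiplier_never_grows_voi(self):
        # blurred sphere gives a graded edge, so the threshold bites
        from scipy.ndimage import gaussian_filter

        vol, _ = _sphere_volume(radius_mm=12.0, value=8.0)
        blurred = vol.with_data(gaussian_filter(vol.data + 1.0, 0.87, mode="nearest"))
        seed = SeedRegion("box", (0, 0, 0), half_extents_mm=(18, 18, 18))
        sizes = []
        for mult in (0.0, 0.25, 0.5, 1.0, 1.5):
            voi = segment_lesion_voi(
                blurred, seed, ThresholdParams(sd_multiplier=mult)
            )
            sizes.append(voi.voxel_count)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_idempotent_under_frozen_threshold(self):
        from scipy.ndimage import gaussian_filter

        vol, _ = _sphere_volume(radius_mm=12.0, value=8.0)
        blurred = vol.with_data(gaussian_filter(vol.data + 1.0, 0.87, mode="nearest"))
        seed = SeedRegion("box", (0, 0, 0), half_extents_mm=(18, 18, 18))
        voi = segment_lesion_voi(blurred, seed)
        again = grow_voi(blurred, seed, voi.threshold_used)
        np.testing.assert_array_equal(again.mask.data, voi.mask.data)


class TestControlVOI:
    def test_sphere_control_matches_center_enumeration(self):
        vol = _suv_volume(np.ones((24, 24, 24)))
        radius = 2 * 3.9  # two voxel spacings
        region = SeedRegion("sphere", (0, 0, 0), radius_mm=radius, role=ROLE_CONTROL)
        voi = define_control_voi(vol, region)
        centers = vol.voxel_centers()
        expected = np.sum(np.sum(centers**2, axis=-1) <= radius**2)
        assert voi.voxel_count == expected

    def test_sub_voxel_box_selects_exactly_one_voxel(self):
        vol = _suv_volume(np.ones((9, 9, 9)))
        # grid has odd extent, so a voxel center sits at the world origin
        region = SeedRegion(
            "box", (0, 0, 0), half_extents_mm=(1.0, 1.0, 1.0), role=ROLE_CONTROL
        )
        voi = define_control_voi(vol, region)
        assert voi.voxel_count == 1

    def test_control_never_carries_threshold(self):
        vol = _suv_volume(np.ones((8, 8, 8)))
        region = SeedRegion("sphere", (0, 0, 0), radius_mm=5.0, role=ROLE_CONTROL)
        voi = define_control_voi(vol, region)
        assert voi.threshold_used is None
        assert voi.role == "control"

    def test_region_outside_grid_errors(self):
        vol = _suv_volume(np.ones((8, 8, 8)))
        region = SeedRegion("sphere", (900, 0, 0), radius_mm=5.0, role=ROLE_CONTROL)
        with pytest.raises(GeometryError):
            define_control_voi(vol, region)

    def test_lesion_role_rejected(self):
        vol = _suv_volume(np.ones((8, 8, 8)))
        region = SeedRegion(
            "sphere", (0, 0, 0), radius_mm=5.0, role=ROLE_LESION_TARGET
        )
        with pytest.raises(InputError):
            define_control_voi(vol, region)


class TestSeedRegionGeometry:
    def test_invalid_shapes_rejected(self):
        with pytest.raises(GeometryError):
            SeedRegion("cylinder", (0, 0, 0), radius_mm=5)
        with pytest.raises(GeometryError):
            SeedRegion("sphere", (0, 0, 0), radius_mm=-1)
        with pytest.raises(GeometryError):
            SeedRegion("box", (0, 0, 0), half_extents_mm=(1, 0, 1))

    def test_from_dict_round_trip(self):
        d = {
            "shape": "sphere",
            "center_mm": [1.0, 2.0, 3.0],
            "radius_mm": 7.5,
            "role": "control",
        }
        r = SeedRegion.from_dict(d)
        assert r.center_mm == (1.0, 2.0, 3.0)
        assert r.radius_mm == 7.5
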