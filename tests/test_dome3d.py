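import numpy as np
import pytest

from domescope import dome3d, phantom, segment
from domescope.dome3d import (
    HeightMap,
    count_per_angle_view,
    detect_domes,
    detect_domes_with_footprints,
    height_map,
    resample_grid,
)
from domescope.segment import BinaryMask


def mask(data, idx=0):
    return BinaryMask(np.asarray(data, dtype=bool), idx)


def pipeline_height_map(stack, grid=128):
    masks = segment.segment_stack(stack)
    return resample_grid(height_map(masks, stack.z_step), grid)


class TestHeightMap:
    def test_single_full_section(self):
        hm = height_map([mask(np.ones((8, 8)), 0)], z_step=2.0)
        assert np.all(hm.heights == 2.0)

    def test_uncovered_pixels_are_zero(self):
        data = np.zeros((8, 8))
        data[:4] = 1
        hm = height_map([mask(data, 0)], z_step=2.0)
        assert np.all(hm.heights[:4] == 2.0)
        assert np.all(hm.heights[4:] == 0.0)

    def test_highest_section_wins(self):
        m0 = mask(np.ones((4, 4)), 0)
        top = np.zeros((4, 4))
        top[0, 0] = 1
        hm = height_map([m0, mask(top, 3)], z_step=2.0)
        assert hm.heights[0, 0] == 8.0
        assert hm.heights[1, 1] == 2.0

    def test_phantom_apex_within_one_z_step(self, two_dome_spec, two_dome_phantom):
        stack, _ = two_dome_phantom
        masks = segment.segment_stack(stack)
        hm = height_map(masks, two_dome_spec.z_step)
        expected_apex = 14.0 + 10.0  # monolayer top + cap height
        assert abs(hm.heights.max() - expected_apex) <= two_dome_spec.z_step

    def test_intensity_rescaling_invariance(self, two_dome_phantom):
        # the map depends only on the masks, not raw intensities
        stack, _ = two_dome_phantom
        m1 = segment.segment_stack(stack)
        from domescope.zstack_io import ZStack

        scaled = ZStack(
            stack.data * 3.7, stack.z_step, stack.pixel_size, stack.channel_names
        )
        m2 = segment.segment_stack(scaled)
        h1 = height_map(m1, stack.z_step)
        h2 = height_map(m2, stack.z_step)
        assert np.array_equal(h1.heights, h2.heights)


class TestResampleGrid:
    def test_constant_map_stays_constant(self):
        hm = HeightMap(np.full((64, 64), 6.0), z_step=2.0)
        out = resample_grid(hm, 16)
        assert out.heights.shape == (16, 16)
        assert np.allclose(out.heights, 6.0)

    def test_exact_block_means(self):
        blocks = np.arange(128 * 128, dtype=float).reshape(128, 128)
        full = np.kron(blocks, np.ones((2, 2)))  # 256x256 of 2x2 constant blocks
        out = resample_grid(HeightMap(full, 2.0), 128, fill_gaps=False)
        assert np.allclose(out.heights, blocks)

    def test_mean_conserved_even_for_non_divisible_shapes(self):
        rng = np.random.default_rng(9)
        hm = HeightMap(1.0 + rng.random((100, 100)), z_step=2.0)
        for grid in (50, 32, 17):
            out = resample_grid(hm, grid)
            assert out.heights.mean() == pytest.approx(hm.heights.mean(), rel=1e-9)

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError):
            resample_grid(HeightMap(np.ones((32, 32)), 2.0), 64)


class TestFillSurfaceGaps:
    def test_gaps_take_nearest_height(self):
        h = np.full((10, 10), 14.0)
        h[4:6, 4:6] = 0.0
        filled = dome3d.fill_surface_gaps(h)
        assert np.all(filled == 14.0)

    def test_all_zero_map_unchanged(self):
        h = np.zeros((5, 5))
        assert np.array_equal(dome3d.fill_surface_gaps(h), h)


class TestDetectDomes:
    def test_flat_surface_yields_no_domes(self, flat_spec):
        stack, _ = phantom.generate_phantom(flat_spec)
        hm = pipeline_height_map(stack, grid=64)
        assert detect_domes(hm, 4.0, 10) == []

    def test_two_phantom_domes_recovered(self, two_dome_spec, two_dome_phantom):
        stack, truth = two_dome_phantom
        hm = pipeline_height_map(stack)
        recs = detect_domes(hm, 4.0, 25)
        assert len(recs) == truth.dome_count
        for r in recs:
            assert abs(r.max_height_um - 10.0) <= two_dome_spec.z_step
            assert r.eccentricity <= 0.2  # circular caps

    def test_merged_caps_report_one_dome(self):
        # two overlapping elevated regions fuse into a single dome record
        spec = phantom.PhantomSpec(
            width=256,
            height=256,
            n_sections=16,
            noise_sd=0.0,
            base_coverage=1.0,
            domes=[
                phantom.Dome(cx=100, cy=128, radius=40, cap_height_um=10),
                phantom.Dome(cx=150, cy=128, radius=40, cap_height_um=10),
            ],
            seed=0,
        )
        stack, _ = phantom.generate_phantom(spec)
        hm = pipeline_height_map(stack)
        recs = detect_domes(hm, 4.0, 25)
        assert len(recs) == 1
        assert recs[0].area_px > 25

    def test_nonpositive_thresholds_rejected(self):
        hm = HeightMap(np.ones((32, 32)), 2.0)
        with pytest.raises(ValueError):
            detect_domes(hm, 0.0, 10)


def synthetic_cap_map(shape=(128, 128), base=14.0, caps=()):
    """Height map of spherical caps on a flat plateau (no phantom pipeline)."""
    h = np.full(shape, base)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cx, cy, r, c in caps:
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        inside = d2 <= r**2
        h[inside] = base + c * np.sqrt(1 - d2[inside] / r**2)
    return HeightMap(h, z_step=2.0)


class TestPerAngleViews:
    def test_isolated_cap_visible_from_all_views(self):
        hm = synthetic_cap_map(caps=[(64, 64, 20, 10.0)])
        recs, fp = detect_domes_with_footprints(hm, 4.0, 10, opening_radius_px=30)
        assert len(recs) == 1
        avg, scored = count_per_angle_view(hm, recs, 4.0, fp)
        assert scored[0].views_detected == 4
        assert avg == 1.0

    def test_small_cap_hidden_behind_tall_ridge(self):
        # a tall ridge east of the small cap occludes the view looking
        # along -x, but not the north/south views
        hm = synthetic_cap_map(caps=[(40, 64, 12, 6.0)])
        hm.heights[54:74, 90:110] = 40.0  # tall block "in front" along +x
        recs, fp = detect_domes_with_footprints(hm, 4.0, 10, opening_radius_px=30)
        small = [r for r in recs if r.max_height_um < 20]
        assert len(small) == 1
        avg, scored = count_per_angle_view(hm, recs, 4.0, fp)
        small_scored = [r for r in scored if r.max_height_um < 20][0]
        assert small_scored.views_detected < 4
        assert avg < len(recs)

    def test_rotating_the_surface_preserves_the_average(self):
        hm = synthetic_cap_map(caps=[(40, 64, 12, 6.0), (100, 64, 16, 12.0)])
        recs, fp = detect_domes_with_footprints(hm, 4.0, 10, opening_radius_px=30)
        avg, _ = count_per_angle_view(hm, recs, 4.0, fp)
        hm_rot = HeightMap(np.rot90(hm.heights).copy(), z_step=2.0)
        recs_r, fp_r = detect_domes_with_footprints(hm_rot, 4.0, 10, opening_radius_px=30)
        avg_r, _ = count_per_angle_view(hm_rot, recs_r, 4.0, fp_r)
        assert avg_r == pytest.approx(avg)

    def test_average_never_exceeds_total_count(self, two_dome_phantom):
        stack, _ = two_dome_phantom
        hm = pipeline_height_map(stack)
        recs, fp = detect_domes_with_footprints(hm, 4.0, 25)
        avg, _ = count_per_angle_view(hm, recs, 4.0, fp)
        assert avg <= len(recs)
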