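import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from domescope import phantom, segment
from domescope.segment import (
    ArtifactRule,
    BinaryMask,
    SegmentationConfig,
    adaptive_binarize,
    clean_mask,
    enhance_weak_signal,
    flag_artifact_sections,
    normalize_intensity,
    to_grayscale,
)
from domescope.zstack_io import ZStack

from conftest import aggregate_iou


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"block_size": 50},  # even
            {"block_size": 1},
            {"clip_percentiles": (50, 50)},
            {"clip_percentiles": (-1, 99)},
            {"connectivity": 6},
            {"enhance_gamma": 0.0},
            {"normalize_over": "plane"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationConfig(**kwargs)


class TestNormalizeIntensity:
    def test_minmax_mapping(self):
        img = np.array([[10.0, 130.0], [250.0, 70.0]])
        out = normalize_intensity(img, (0, 100))
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 1] == pytest.approx((130 - 10) / 240)

    def test_constant_image_maps_to_zero(self):
        assert np.all(normalize_intensity(np.full((8, 8), 7.0)) == 0.0)

    def test_percentile_clip_matches_direct_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.random((100, 100)) * 100
        hot = rng.choice(img.size, size=100, replace=False)
        img.ravel()[hot] = 1e4  # 1% hot pixels
        out = normalize_intensity(img, (1, 99))
        lo, hi = np.percentile(img, [1, 99])
        oracle = np.clip((img - lo) / (hi - lo), 0, 1)
        assert np.allclose(out, oracle)
        assert np.all(out.ravel()[hot] == 1.0)  # hot pixels saturate

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        once = normalize_intensity(img, (0, 100))
        twice = normalize_intensity(once, (0, 100))
        assert np.allclose(once, twice)


class TestToGrayscale:
    def test_projection_and_symmetry(self):
        rng = np.random.default_rng(2)
        section = rng.random((16, 16, 2))
        only_first = to_grayscale(section, channel_weights=(1.0, 0.0))
        assert np.allclose(only_first, normalize_intensity(section[..., 0]))
        same = np.stack([section[..., 0], section[..., 0]], axis=-1)
        half = to_grayscale(same, channel_weights=(0.5, 0.5))
        assert np.allclose(half, normalize_intensity(section[..., 0]))

    def test_weighted_sum_matches_pixelwise_oracle(self):
        rng = np.random.default_rng(3)
        section = rng.random((16, 16, 2))
        out = to_grayscale(section, channel_weights=(0.7, 0.3))
        oracle = 0.7 * normalize_intensity(section[..., 0]) + 0.3 * normalize_intensity(
            section[..., 1]
        )
        assert np.allclose(out, np.clip(oracle, 0, 1))

    def test_weight_mismatch_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((8, 8, 2)), channel_weights=(1.0,))


class TestEnhanceWeakSignal:
    def test_identity_and_arithmetic(self):
        img = np.array([[0.25, 0.5]])
        assert np.array_equal(enhance_weak_signal(img, 1.0), img)
        assert enhance_weak_signal(img, 0.5)[0, 0] == pytest.approx(0.5)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            enhance_weak_signal(np.zeros((2, 2)), 0.0)

    @settings(deadline=None, max_examples=25)
    @given(
        img=hnp.arrays(
            float,
            (6, 6),
            elements=st.floats(0, 1, allow_nan=False),
        ),
        gamma=st.floats(0.1, 4.0),
    )
    def test_monotone_for_any_positive_gamma(self, img, gamma):
        out = enhance_weak_signal(img, gamma)
        a, b = img.ravel(), out.ravel()
        order = np.argsort(a)
        assert np.all(np.diff(b[order]) >= -1e-12)


class TestAdaptiveBinarize:
    def test_uniform_image_gives_empty_mask(self):
        mask = adaptive_binarize(np.full((64, 64), 0.5), 11, 0.01)
        assert not mask.data.any()

    def test_bright_disk_on_dark_ground_recovered(self):
        yy, xx = np.ogrid[:128, :128]
        disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2
        img = np.where(disk, 0.9, 0.1)
        mask = adaptive_binarize(img, 51, 0.05)
        inter = np.logical_and(mask.data, disk).sum()
        union = np.logical_or(mask.data, disk).sum()
        assert inter / union >= 0.95

    def test_disk_on_illumination_gradient_recovered(self):
        # a global threshold cannot separate a 0.1-0.5 background ramp from
        # the disk; the local-mean rule can
        yy, xx = np.ogrid[:128, :128]
        img = 0.1 + 0.4 * (xx / 127.0) * np.ones((128, 1))
        disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2
        img = np.where(disk, 0.9, img)
        mask = adaptive_binarize(img, 51, 0.05)
        inter = np.logical_and(mask.data, disk).sum()
        union = np.logical_or(mask.data, disk).sum()
        assert inter / union >= 0.9

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(4)
        img = rng.random((64, 64)) * 0.5
        m1 = adaptive_binarize(img, 21, 0.02)
        m2 = adaptive_binarize(img + 0.3, 21, 0.02)
        assert np.array_equal(m1.data, m2.data)

    def test_affine_rescale_with_rescaled_offset(self):
        rng = np.random.default_rng(5)
        img = rng.random((64, 64)) * 0.4
        m1 = adaptive_binarize(img, 21, 0.02)
        m2 = adaptive_binarize(0.5 * img + 0.2, 21, 0.01)
        assert np.array_equal(m1.data, m2.data)

    def test_oversized_block_rejected(self):
        with pytest.raises(ValueError):
            adaptive_binarize(np.zeros((16, 16)), 17, 0.01)


def flood_fill_count(data: np.ndarray, connectivity: int) -> int:
    """Brute-force component count by BFS flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(data, dtype=bool)
    count = 0
    h, w = data.shape
    for sy in range(h):
        for sx in range(w):
            if data[sy, sx] and not seen[sy, sx]:
                count += 1
                stack = [(sy, sx)]
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in steps:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and data[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


class TestCleanMask:
    def test_speck_below_min_size_removed(self):
        data = np.zeros((32, 32), dtype=bool)
        data[5:6, 5:8] = True  # 3-px speck
        out = clean_mask(BinaryMask(data, 0), min_object_px=10)
        assert not out.data.any()

    def test_annulus_filled_to_solid_disk(self):
        yy, xx = np.ogrid[:64, :64]
        r2 = (yy - 32) ** 2 + (xx - 32) ** 2
        annulus = (r2 <= 20**2) & (r2 >= 12**2)
        out = clean_mask(BinaryMask(annulus, 0), min_object_px=0, fill_holes=True)
        disk = r2 <= 20**2
        assert np.array_equal(out.data, disk)

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(6)
        data = rng.random((48, 48)) < 0.35
        for conn in (4, 8):
            out = clean_mask(BinaryMask(data, 0), min_object_px=5,
                             fill_holes=False, connectivity=conn)
            from domescope import morpho

            got = morpho.label_regions(out, conn).n_labels
            assert got == flood_fill_count(out.data, conn)


class TestSegmentationRecovery:
    def test_phantom_iou_above_090(self, two_dome_spec, two_dome_phantom):
        stack, truth = two_dome_phantom
        masks = segment.segment_stack(stack)
        assert aggregate_iou(masks, truth.masks) >= 0.9

    def test_empty_sections_stay_empty(self, two_dome_phantom):
        stack, truth = two_dome_phantom
        masks = segment.segment_stack(stack)
        for m, t in zip(masks, truth.masks):
            if not t.any():
                assert m.data.mean() < 0.01


class TestArtifactFlagging:
    def _with_line(self, spec, section):
        stack, _ = phantom.generate_phantom(spec)
        data = stack.data.copy()
        data[section, 60:62, :, 0] = 1.5  # 2-px full-width bright line
        return ZStack(data=data, z_step=spec.z_step, pixel_size=spec.pixel_size)

    def test_line_artifact_section_flagged(self, flat_spec):
        stack = self._with_line(flat_spec, 5)
        qc = flag_artifact_sections(stack)
        flagged = {q.section_index for q in qc if q.excluded}
        assert 5 in flagged

    def test_clean_phantom_not_flagged(self, two_dome_phantom):
        stack, _ = two_dome_phantom
        qc = flag_artifact_sections(stack)
        assert not any(q.excluded for q in qc)

    def test_manual_exclusion_honored(self, flat_spec):
        stack, _ = phantom.generate_phantom(flat_spec)
        qc = flag_artifact_sections(
            stack, ArtifactRule(manual_exclude=[2, 7], detect_lines=False)
        )
        flagged = {q.section_index for q in qc if q.excluded}
        assert flagged == {2, 7}
        assert all(q.reason for q in qc if q.excluded)
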