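"""Height-map surface reconstruction and dome detection/quantification.

The epithelial top surface is reconstructed from the per-section
segmentation masks: at each lateral position the height is the top of the
highest foreground section, ``z_step * (1 + max foreground section index)``
µm (0 where no section is foreground).  Domes — blister-like elevations of
the monolayer — are then detected as connected regions that rise at least a
minimum prominence above a local baseline obtained by grayscale
morphological opening (a rolling disk wide enough to slide under the
monolayer but not into the domes).

Because dome visibility in oblique surface renderings depends on viewing
angle (a small dome can hide behind a taller neighbor), each dome is also
scored against four azimuthal viewing directions (0°, 90°, 180°, 270°):
it counts as visible from a direction when, somewhere on its footprint, it
rises at least the minimum prominence above the tallest structure between
it and the viewer.  The headline statistic is the mean visible-dome count
over the four views, which equals the total count when nothing occludes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .segment import BinaryMask, _skimage_connectivity


@dataclass
class HeightMap:
    """Top-surface heights in µm on a (possibly resampled) square-pixel grid.

    ``z_scale`` is a display-only scale factor for 3D surface plots; it
    never enters any measurement.
    """

    heights: np.ndarray
    z_step: float
    grid_size: int | None = None
    z_scale: float = 0.1

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError("height map must be 2D")
        if self.heights.min() < 0:
            raise ValueError("heights must be non-negative")


@dataclass
class DomeRecord:
    """One detected dome: footprint geometry and apex prominence."""

    dome_id: int
    area_px: int
    max_height_um: float
    eccentricity: float
    centroid: tuple[float, float]  # (x, y) in map pixels
    views_detected: int = 4

    def __post_init__(self) -> None:
        if self.max_height_um <= 0:
            raise ValueError("a dome must have positive height")


def height_map(masks: Sequence[BinaryMask], z_step: float) -> HeightMap:
    """Reconstruct the top surface from per-section masks.

    height(y, x) = z_step * (1 + highest foreground section index at
    (y, x)); 0 where no section is foreground.  Depends only on the masks,
    so it is invariant to any intensity rescaling of the source stack.
    """
    if not masks:
        raise ValueError("empty mask list")
    shape = masks[0].data.shape
    top = np.full(shape, -1, dtype=np.int64)
    for m in masks:
        if m.data.shape != shape:
            raise ValueError("masks must share a common shape")
        top[m.data] = np.maximum(top[m.data], m.section_index)
    return HeightMap(heights=z_step * (top + 1).astype(np.float64), z_step=z_step)


def resample_grid(hm: HeightMap, grid_size: int = 128, fill_gaps: bool = True) -> HeightMap:
    """Area-weighted block-mean downsampling to a grid_size x grid_size map.

    When the map dimensions divide evenly the result is the exact block
    mean; otherwise each source pixel's area is split fractionally across
    the target cells.  Either way the global mean height is conserved
    exactly, so resampling never biases surface statistics.

    With ``fill_gaps`` (default) zero-height gaps are inpainted with the
    nearest measured height before averaging, so that missing-surface
    pixels do not drag block means toward the membrane; pass False to
    average the raw map.
    """
    if grid_size < 8:
        raise ValueError(f"grid_size must be >= 8, got {grid_size}")
    h, w = hm.heights.shape
    if grid_size > min(h, w):
        raise ValueError(f"grid_size {grid_size} exceeds map extent {hm.heights.shape}")
    heights = fill_surface_gaps(hm.heights) if fill_gaps else hm.heights
    wy = _overlap_weights(h, grid_size)
    wx = _overlap_weights(w, grid_size)
    out = wy @ heights @ wx.T
    return HeightMap(out, z_step=hm.z_step, grid_size=grid_size, z_scale=hm.z_scale)


def _overlap_weights(n_src: int, n_dst: int) -> np.ndarray:
    """(n_dst, n_src) matrix averaging source cells into equal target bins."""
    w = np.zeros((n_dst, n_src))
    step = n_src / n_dst
    for j in range(n_dst):
        lo, hi = j * step, (j + 1) * step
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n_src)):
            overlap = min(hi, i + 1) - max(lo, i)
            if overlap > 0:
                w[j, i] = overlap / step
    return w


def fill_surface_gaps(heights: np.ndarray) -> np.ndarray:
    """Inpaint zero-height gaps with the nearest measured surface height.

    Zero means "no tissue detected in any section" — missing surface, not
    surface at the membrane.  Left at zero, a gap would drag the rolling-
    disk baseline to the membrane and make the surrounding monolayer look
    like one giant dome; nearest-neighbor inpainting keeps the baseline on
    the tissue.  An all-zero map is returned unchanged.
    """
    gaps = heights <= 0
    if not gaps.any() or gaps.all():
        return heights
    # propagate the *minimum* neighboring measured height inward, so a gap
    # bordered by both monolayer and dome takes the monolayer level and the
    # dome footprint does not smear into it
    filled = np.where(gaps, np.inf, heights)
    remaining = gaps.copy()
    while remaining.any():
        neigh_min = ndimage.grey_erosion(filled, size=3, mode="reflect")
        newly = remaining & np.isfinite(neigh_min)
        filled[newly] = neigh_min[newly]
        remaining &= ~newly
    return filled


def opening_baseline(hm: HeightMap, opening_radius_px: int) -> np.ndarray:
    """Local monolayer level: grayscale opening with a rolling disk.

    The disk radius should exceed the largest expected dome radius (twice
    it, by default, in callers) so that domes are removed from the baseline
    while broad monolayer topography is preserved.  Surface gaps are
    inpainted first (see :func:`fill_surface_gaps`).
    """
    footprint = morphology.disk(opening_radius_px)
    return ndimage.grey_opening(fill_surface_gaps(hm.heights), footprint=footprint)


def detect_domes_with_footprints(
    hm: HeightMap,
    min_prominence_um: float = 4.0,
    min_area_px: int = 25,
    opening_radius_px: int | None = None,
    connectivity: int = 8,
) -> tuple[list[DomeRecord], np.ndarray]:
    """Detect domes; also return the footprint label map (dome_id per pixel).

    Prominence is height minus the rolling-disk opening baseline; a
    candidate region must rise at least ``min_prominence_um`` and cover at
    least ``min_area_px`` map pixels.  Two caps whose elevated regions
    merge are reported as a single dome with the combined footprint
    (matching the fusion of neighboring domes into larger formations).
    """
    if min_prominence_um <= 0 or min_area_px <= 0:
        raise ValueError("detection thresholds must be positive")
    if opening_radius_px is None:
        opening_radius_px = max(8, min(hm.heights.shape) // 4)
    baseline = opening_baseline(hm, opening_radius_px)
    prominence = fill_surface_gaps(hm.heights) - baseline
    candidate = prominence >= min_prominence_um
    labels = measure.label(candidate, connectivity=_skimage_connectivity(connectivity))
    records: list[DomeRecord] = []
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int64)
    for rp in measure.regionprops(labels, intensity_image=prominence):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid
        records.append(
            DomeRecord(
                dome_id=len(records) + 1,
                area_px=int(rp.area),
                max_height_um=float(rp.image_intensity[rp.image].max()),
                eccentricity=float(min(rp.eccentricity, 1.0)),
                centroid=(float(cx), float(cy)),
            )
        )
        remap[rp.label] = records[-1].dome_id
    return records, remap[labels]


def detect_domes(
    hm: HeightMap,
    min_prominence_um: float = 4.0,
    min_area_px: int = 25,
    opening_radius_px: int | None = None,
    connectivity: int = 8,
) -> list[DomeRecord]:
    """Dome records only; see :func:`detect_domes_with_footprints`."""
    records, _ = detect_domes_with_footprints(
        hm, min_prominence_um, min_area_px, opening_radius_px, connectivity
    )
    return records


def _directional_occlusion(heights: np.ndarray, view: int) -> np.ndarray:
    """Running max of heights strictly in front of each pixel for one view.

    Views are azimuths of the line of sight: 0 looks along -x (viewer at
    x=+inf), 1 along -y, 2 along +x, 3 along +y.
    """
    h = heights
    if view == 0:
        sweep = h[:, ::-1]
    elif view == 1:
        sweep = h.T[:, ::-1]
    elif view == 2:
        sweep = h
    elif view == 3:
        sweep = h.T
    else:
        raise ValueError(f"view must be 0-3, got {view}")
    run = np.maximum.accumulate(sweep, axis=1)
    # shift by one: occlusion strictly in front, not the pixel itself
    occ = np.concatenate([np.zeros((run.shape[0], 1)), run[:, :-1]], axis=1)
    if view == 0:
        occ = occ[:, ::-1]
    elif view == 1:
        occ = occ[:, ::-1].T
    elif view == 3:
        occ = occ.T
    return occ


def count_per_angle_view(
    hm: HeightMap,
    domes: Sequence[DomeRecord],
    min_prominence_um: float = 4.0,
    footprints: np.ndarray | None = None,
    n_views: int = 4,
) -> tuple[float, list[DomeRecord]]:
    """Score dome visibility from azimuthal viewing directions.

    For each view, a dome is visible when some footprint pixel rises at
    least ``min_prominence_um`` above everything between it and the viewer
    (the dome's own pixels are excised from the occlusion sweep — a dome
    cannot hide behind itself).  Returns the mean visible count over views
    and the dome records with ``views_detected`` filled in.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if footprints is None:
        raise ValueError("footprint label map required for view scoring")
    if footprints.shape != hm.heights.shape:
        raise ValueError("footprint map must match the height map shape")
    if not domes:
        return 0.0, []
    views = [int(round(v * 4 / n_views)) % 4 for v in range(n_views)]
    visible = np.zeros((len(domes), n_views), dtype=bool)
    for d_idx, dome in enumerate(domes):
        own = footprints == dome.dome_id
        others = np.where(own, 0.0, hm.heights)
        for v_pos, view in enumerate(views):
            occ = _directional_occlusion(others, view)
            vis = (hm.heights - occ)[own].max() >= min_prominence_um
            visible[d_idx, v_pos] = vis
    scored = [
        DomeRecord(
            dome_id=d.dome_id,
            area_px=d.area_px,
            max_height_um=d.max_height_um,
            eccentricity=d.eccentricity,
            centroid=d.centroid,
            views_detected=int(visible[i].sum()),
        )
        for i, d in enumerate(domes)
    ]
    avg = float(visible.sum(axis=0).mean())
    return avg, scored
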