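"""Per-section preprocessing and binarization of confocal z-stacks.

The chain mirrors a standard fluorescence-microscopy segmentation recipe:
per-section intensity normalization to [0, 1] (percentile clip), weighted
channel merge to grayscale, optional gamma enhancement of weak signal,
adaptive (local-mean) thresholding, and binary-mask hygiene (small-object
removal, hole filling).  Local-mean thresholding is used because the target
images are large tiled mosaics whose illumination varies across the field;
a global threshold would trade coverage in dim tiles against noise in
bright ones.

Section-level QC lives here too: sections crossed by glass-slide grid
artifacts (long straight bright lines) are detected by a Hough-transform
line-occupancy test and excluded from all downstream profiles, alongside
any manual exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage
from skimage import measure, morphology, transform

from .zstack_io import SectionQC, ZStack


class SegmentationConfig(BaseModel):
    """Tuning parameters of the binarization chain.

    Channel weights default to (1, 0): coverage is defined on the WGA/mucus
    channel, which marks cellular presence throughout the cell body, with
    the nuclei channel reserved for QC overlays.
    """

    clip_percentiles: tuple[float, float] = (0.0, 100.0)
    channel_weights: tuple[float, ...] = (1.0, 0.0)
    block_size: int = Field(default=51, ge=3)
    offset: float = 0.02
    min_intensity: float | None = Field(
        default=0.15,
        description="absolute foreground floor in stack-normalized units; a pixel "
        "above it is foreground even where the local-mean criterion fails "
        "(large uniform cell sheets have no local contrast); None disables",
    )
    smooth_sigma: float = Field(default=1.5, ge=0)
    min_object_px: int = Field(default=25, ge=0)
    fill_holes: bool = False
    connectivity: int = 8
    enhance_gamma: float = Field(default=1.0, gt=0)
    normalize_over: str = Field(
        default="stack",
        description="compute clip bounds per 'stack' (sections share one scale, "
        "so empty sections stay dark) or per 'section'",
    )

    @model_validator(mode="after")
    def _check(self) -> "SegmentationConfig":
        lo, hi = self.clip_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"clip percentiles must satisfy 0 <= lo < hi <= 100, got {lo, hi}")
        if self.block_size % 2 == 0:
            raise ValueError(f"block_size must be odd, got {self.block_size}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.normalize_over not in ("stack", "section"):
            raise ValueError("normalize_over must be 'stack' or 'section'")
        return self


@dataclass
class BinaryMask:
    """Boolean foreground mask of one optical section."""

    data: np.ndarray
    section_index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")


class ArtifactRule(BaseModel):
    """How to flag artifact sections.

    A section is excluded when at least ``line_occupancy`` of its bright
    foreground is concentrated on one straight Hough line (slide-grid
    artifacts are thin bright image-spanning lines), when the fraction of
    near-saturated pixels exceeds ``saturation_fraction`` (if set), or when
    its index is listed in ``manual_exclude``.
    """

    manual_exclude: list[int] = Field(default_factory=list)
    line_occupancy: float = Field(default=0.3, gt=0, le=1)
    saturation_fraction: float | None = None
    detect_lines: bool = True


def _skimage_connectivity(connectivity: int) -> int:
    # pixel-neighbourhood 4/8 -> scikit-image rank 1/2
    return 1 if connectivity == 4 else 2


def normalize_intensity(
    image: np.ndarray,
    clip_percentiles: tuple[float, float] = (0.0, 100.0),
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Percentile-clip and affinely rescale one section to [0, 1].

    The values at the low/high percentiles map to 0/1; values outside
    saturate.  A constant image maps to all zeros (no contrast to stretch).
    ``bounds`` bypasses the percentile computation with explicit (lo, hi)
    intensities — used to share one scale across all sections of a stack.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image intensities must be finite")
    if image.min() < 0:
        raise ValueError("image intensities must be non-negative")
    if bounds is None:
        lo_p, hi_p = clip_percentiles
        if not (0 <= lo_p < hi_p <= 100):
            raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")
        lo, hi = np.percentile(image, [lo_p, hi_p])
    else:
        lo, hi = bounds
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def to_grayscale(
    stack: ZStack | np.ndarray,
    section_index: int | None = None,
    channel_weights: Sequence[float] = (1.0, 0.0),
    clip_percentiles: tuple[float, float] = (0.0, 100.0),
    channel_bounds: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Weighted merge of normalized channels of one section, clipped to [0, 1].

    Accepts either a :class:`ZStack` plus section index or a raw
    ``(y, x, channel)`` array.  ``channel_bounds`` optionally fixes the
    per-channel normalization range (e.g. computed over the whole stack).
    """
    if isinstance(stack, ZStack):
        if section_index is None:
            raise ValueError("section_index required with a ZStack input")
        section = stack.data[section_index]
    else:
        section = np.asarray(stack, dtype=np.float64)
        if section.ndim == 2:
            section = section[..., None]
    weights = np.asarray(channel_weights, dtype=np.float64)
    if weights.shape[0] != section.shape[-1]:
        raise ValueError(
            f"{weights.shape[0]} weights for {section.shape[-1]} channels"
        )
    out = np.zeros(section.shape[:2])
    for c, w in enumerate(weights):
        if w != 0:
            bounds = channel_bounds[c] if channel_bounds is not None else None
            out += w * normalize_intensity(section[..., c], clip_percentiles, bounds)
    return np.clip(out, 0.0, 1.0)


def enhance_weak_signal(image: np.ndarray, enhance_gamma: float = 1.0) -> np.ndarray:
    """Gamma transform x**gamma on a [0, 1] image; gamma < 1 brightens dim signal.

    This is the reproducible stand-in for interactive contrast enhancement:
    a single logged exponent instead of hand editing, preserving the pixel
    ordering for any gamma > 0.
    """
    if enhance_gamma <= 0:
        raise ValueError(f"gamma must be positive, got {enhance_gamma}")
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be normalized to [0, 1] before enhancement")
    if enhance_gamma == 1.0:
        return image.copy()
    return np.power(image, enhance_gamma)


def adaptive_binarize(
    image: np.ndarray,
    block_size: int = 51,
    offset: float = 0.02,
    section_index: int = 0,
) -> BinaryMask:
    """Local-mean adaptive threshold of a [0, 1] section image.

    A pixel is foreground iff its value exceeds the mean over the
    ``block_size`` x ``block_size`` window centred on it plus ``offset``.
    Borders use reflected padding.  Subtracting the local mean makes the
    rule exactly invariant to adding a constant to the whole image.
    """
    image = np.asarray(image, dtype=np.float64)
    if block_size % 2 == 0 or block_size < 3:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")
    if block_size > min(image.shape):
        raise ValueError(
            f"block_size {block_size} exceeds image extent {image.shape}"
        )
    local_mean = ndimage.uniform_filter(image, size=block_size, mode="reflect")
    return BinaryMask(data=image > local_mean + offset, section_index=section_index)


def clean_mask(
    mask: BinaryMask,
    min_object_px: int = 25,
    fill_holes: bool = True,
    connectivity: int = 8,
) -> BinaryMask:
    """Remove sub-threshold specks and optionally fill interior holes."""
    data = mask.data
    if fill_holes:
        data = ndimage.binary_fill_holes(data)
    if min_object_px > 0:
        # remove components of < min_object_px pixels (skimage removes <= max_size)
        data = morphology.remove_small_objects(
            data,
            max_size=min_object_px - 1,
            connectivity=_skimage_connectivity(connectivity),
        )
    return BinaryMask(data=data, section_index=mask.section_index)


def segment_section(
    stack: ZStack,
    section_index: int,
    config: SegmentationConfig,
    channel_bounds: Sequence[tuple[float, float]] | None = None,
) -> BinaryMask:
    """Full chain for one section: normalize -> gray -> gamma -> smooth -> adaptive -> clean."""
    gray = to_grayscale(
        stack,
        section_index,
        config.channel_weights,
        config.clip_percentiles,
        channel_bounds,
    )
    gray = enhance_weak_signal(gray, config.enhance_gamma)
    if config.smooth_sigma > 0:
        gray = ndimage.gaussian_filter(gray, sigma=config.smooth_sigma)
    mask = adaptive_binarize(gray, config.block_size, config.offset, section_index)
    data = mask.data
    if config.min_intensity is not None:
        data = data | (gray > config.min_intensity)
    mask = BinaryMask(data=data, section_index=section_index)
    return clean_mask(mask, config.min_object_px, config.fill_holes, config.connectivity)


def stack_channel_bounds(
    stack: ZStack, clip_percentiles: tuple[float, float]
) -> list[tuple[float, float]]:
    """Per-channel clip bounds computed over the whole stack."""
    lo_p, hi_p = clip_percentiles
    out = []
    for c in range(stack.n_channels):
        lo, hi = np.percentile(stack.data[..., c], [lo_p, hi_p])
        out.append((float(lo), float(hi)))
    return out


def segment_stack(stack: ZStack, config: SegmentationConfig | None = None) -> list[BinaryMask]:
    """Segment every section of a stack with one configuration.

    With ``normalize_over="stack"`` (the default) the percentile clip
    bounds are computed once over the full volume, so that sections above
    the tissue — which contain only noise — stay dark instead of being
    stretched to full contrast.
    """
    config = config or SegmentationConfig()
    bounds = (
        stack_channel_bounds(stack, config.clip_percentiles)
        if config.normalize_over == "stack"
        else None
    )
    return [
        segment_section(stack, i, config, bounds) for i in range(stack.n_sections)
    ]


def _line_occupancy(gray: np.ndarray) -> float:
    """Straight-line concentration of the bright foreground.

    Hough-accumulator peak (longest collinear bright run) divided by the
    total bright-foreground area.  A thin image-spanning line concentrates
    ~half its pixels on one line and scores near 0.5; filled blobs score
    ~2*sqrt(area/pi)/area, well below 0.1 for anything sizeable.  Peaks
    shorter than a quarter of the image are ignored (noise specks).
    """
    fg = gray > 0.5
    area = int(fg.sum())
    if area == 0:
        return 0.0
    hspace, _, _ = transform.hough_line(fg)
    peak = float(hspace.max())
    if peak < 0.25 * min(fg.shape):
        return 0.0
    return peak / area


def flag_artifact_sections(
    stack: ZStack, rule: ArtifactRule | None = None
) -> list[SectionQC]:
    """Flag sections carrying slide-grid line artifacts or listed manually.

    Returns one :class:`SectionQC` per section; downstream profile code
    drops the excluded ones (they appear as missing values, never as zero
    coverage).
    """
    rule = rule or ArtifactRule()
    manual = set(rule.manual_exclude)
    qc: list[SectionQC] = []
    for i in range(stack.n_sections):
        if i in manual:
            qc.append(SectionQC(i, True, "manual exclusion"))
            continue
        gray = to_grayscale(stack, i, (1.0,) + (0.0,) * (stack.n_channels - 1))
        if rule.detect_lines:
            occ = _line_occupancy(gray)
            if occ >= rule.line_occupancy:
                qc.append(
                    SectionQC(i, True, f"line artifact (occupancy {occ:.2f})")
                )
                continue
        if rule.saturation_fraction is not None:
            sat = float((gray >= 0.98).mean())
            if sat >= rule.saturation_fraction:
                qc.append(SectionQC(i, True, f"saturated ({sat:.2f})"))
                continue
        qc.append(SectionQC(i, False))
    return qc
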