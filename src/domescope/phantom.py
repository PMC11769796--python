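"""Synthetic two-channel z-stacks of a domed epithelial monolayer.

The phantom emulates the geometry this toolkit is built to measure: a flat
epithelial monolayer on a Transwell membrane (occupying a configurable
fraction of the field up to a fixed height), carrying spherical-cap domes on
top, imaged as a two-channel confocal z-stack.  The mucus/WGA channel shows
a weak signal throughout the cell body plus a bright shell at the top
surface (the lectin stain is strongest where the secreted mucus layer caps
the culture); the nuclei channel is scattered isotropic Gaussian blobs
inside covered regions.  Additive Gaussian noise, clipped at zero, stresses
segmentation.

Every phantom comes with exact ground truth — per-section boolean masks,
analytic coverage, and per-dome footprint area / apex height / eccentricity
— so each downstream stage can be tested against known geometry.

Geometry conventions
--------------------
Section ``i`` samples height ``i * z_step`` µm above the membrane.  The
monolayer occupies sections with height < ``monolayer_height_um``; a dome of
cap height ``c`` and base radius ``r`` adds, at height ``h`` above the
monolayer top, a disk of radius ``r * sqrt(1 - (h / c)^2)`` (spherical cap),
sampled at ``h = 0, z_step, 2*z_step, ...`` so the base disk is full-radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .zstack_io import ZStack


class Dome(BaseModel):
    """Spherical-cap dome: center and base radius in pixels, cap height in µm."""

    cx: float
    cy: float
    radius: float = Field(gt=0)
    cap_height_um: float = Field(gt=0)


class PhantomSpec(BaseModel):
    """Parameters of one synthetic z-stack.

    Defaults mirror the desk-scale imaging geometry the toolkit targets:
    a 512x512 px field, 28 optical sections at 2 µm spacing (heights
    0-54 µm), a monolayer reaching 14 µm with 80% surface coverage, and a
    nominal 2 µm lateral pixel size.
    """

    width: int = Field(default=512, gt=0)
    height: int = Field(default=512, gt=0)
    n_sections: int = Field(default=28, gt=0)
    z_step: float = Field(default=2.0, gt=0)
    pixel_size: float = Field(default=2.0, gt=0)
    base_coverage: float = Field(default=0.8, ge=0.0, le=1.0)
    monolayer_height_um: float = Field(default=14.0, gt=0)
    domes: list[Dome] = Field(default_factory=list)
    nuclei_density: float = Field(default=10.0, ge=0.0, description="nuclei per 100x100 px")
    nucleus_sigma_px: float = Field(default=3.0, gt=0)
    cell_intensity: float = Field(default=0.3, gt=0, le=1.0)
    shell_intensity: float = Field(default=0.9, gt=0, le=1.0)
    noise_sd: float = Field(default=0.02, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "PhantomSpec":
        span = self.n_sections * self.z_step
        for d in self.domes:
            if self.monolayer_height_um + d.cap_height_um > span:
                raise ValueError(
                    f"dome cap at {d.cap_height_um} µm exceeds the stack span {span} µm"
                )
            if (
                d.cx - d.radius < 0
                or d.cy - d.radius < 0
                or d.cx + d.radius > self.width - 1
                or d.cy + d.radius > self.height - 1
            ):
                raise ValueError(
                    f"dome at ({d.cx}, {d.cy}) r={d.radius} overlaps the image border"
                )
        return self

    @property
    def n_monolayer_sections(self) -> int:
        """Sections whose height lies strictly below the monolayer top."""
        n = int(math.ceil(self.monolayer_height_um / self.z_step))
        return min(max(n, 1), self.n_sections)


@dataclass
class GroundTruth:
    """Exact per-section masks and dome geometry for one phantom."""

    coverage_by_section: np.ndarray  # fraction, per section
    dome_count: int
    per_dome: list[dict]  # area_px, max_height_um, eccentricity
    masks: np.ndarray  # boolean (section, y, x)

    def __post_init__(self) -> None:
        if self.dome_count != len(self.per_dome):
            raise ValueError("dome_count inconsistent with per_dome records")


def _dome_section_radius(dome: Dome, h_above_top: float) -> float:
    """Cross-section radius of a spherical cap at height h above its base."""
    if h_above_top < 0 or h_above_top >= dome.cap_height_um:
        return 0.0
    return dome.radius * math.sqrt(1.0 - (h_above_top / dome.cap_height_um) ** 2)


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _base_monolayer_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random cell mask with an exact pixel fraction equal to base_coverage.

    Smoothed white noise thresholded at the matching quantile yields blobby,
    tissue-like holes while keeping the covered-pixel count exact.  Dome
    footprints are forced covered first (a dome sits on cells), and the
    threshold is taken over the remaining pixels.
    """
    shape = (spec.height, spec.width)
    n_total = spec.height * spec.width
    n_target = int(round(spec.base_coverage * n_total))

    forced = np.zeros(shape, dtype=bool)
    for d in spec.domes:
        forced |= _disk_mask(shape, d.cx, d.cy, d.radius)
    n_forced = int(forced.sum())
    n_target = max(n_target, n_forced)
    if n_target >= n_total:
        return np.ones(shape, dtype=bool)

    from scipy.ndimage import gaussian_filter

    fieldv = gaussian_filter(rng.standard_normal(shape), sigma=12.0)
    fieldv[forced] = np.inf  # always kept
    # keep the n_target highest-valued pixels -> exact coverage fraction
    flat = fieldv.ravel()
    kth = np.argpartition(flat, n_total - n_target)[n_total - n_target :]
    mask = np.zeros(n_total, dtype=bool)
    mask[kth] = True
    return mask.reshape(shape)


def ground_truth_masks(spec: PhantomSpec, base_mask: np.ndarray) -> np.ndarray:
    """Per-section boolean masks implied by the phantom geometry."""
    masks = np.zeros((spec.n_sections, spec.height, spec.width), dtype=bool)
    n_mono = spec.n_monolayer_sections
    masks[:n_mono] = base_mask
    for i in range(n_mono, spec.n_sections):
        h = (i - n_mono) * spec.z_step
        for d in spec.domes:
            r = _dome_section_radius(d, h)
            if r > 0:
                masks[i] |= _disk_mask((spec.height, spec.width), d.cx, d.cy, r)
    return masks


def ground_truth_coverage(spec: PhantomSpec) -> np.ndarray:
    """Analytic per-section coverage fractions (no rasterization).

    Below the monolayer top every section carries ``base_coverage``; above
    it each dome contributes the area of its spherical-cap cross-section
    disk.  Domes are assumed disjoint (enforced only in the sense that
    overlapping footprints would double-count).
    """
    n_total = spec.height * spec.width
    cov = np.zeros(spec.n_sections)
    n_mono = spec.n_monolayer_sections
    cov[:n_mono] = spec.base_coverage
    for i in range(n_mono, spec.n_sections):
        h = (i - n_mono) * spec.z_step
        area = sum(math.pi * _dome_section_radius(d, h) ** 2 for d in spec.domes)
        cov[i] = area / n_total
    return cov


def _dome_eccentricity(_: Dome) -> float:
    # circular footprints by construction
    return 0.0


def generate_phantom(spec: PhantomSpec) -> tuple[ZStack, GroundTruth]:
    """Render the phantom stack and its exact ground truth.

    The same spec (including its seed) always produces bit-identical
    output.  Returns the two-channel stack (channels "mucus", "nuclei") and
    the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    base_mask = _base_monolayer_mask(spec, rng)
    masks = ground_truth_masks(spec, base_mask)

    # top surface: highest covered section per column, as a section index
    top_idx = np.where(
        masks.any(axis=0), masks.shape[0] - 1 - np.argmax(masks[::-1], axis=0), -1
    )

    mucus = np.zeros((spec.n_sections, *shape))
    for i in range(spec.n_sections):
        sec = np.zeros(shape)
        sec[masks[i]] = spec.cell_intensity
        # bright mucus shell where this section is the local top surface
        shell = top_idx == i
        sec[shell] = spec.shell_intensity
        mucus[i] = sec

    nuclei = np.zeros_like(mucus)
    n_nuclei = int(round(spec.nuclei_density * spec.height * spec.width / 1e4))
    if n_nuclei > 0:
        cov_idx = np.flatnonzero(base_mask.ravel())
        if cov_idx.size:
            picks = rng.choice(cov_idx, size=n_nuclei, replace=True)
            ny, nx = np.unravel_index(picks, shape)
            n_mono = spec.n_monolayer_sections
            nz = rng.integers(0, n_mono, size=n_nuclei)
            sig = spec.nucleus_sigma_px
            half = int(math.ceil(3 * sig))
            ax = np.arange(-half, half + 1)
            blob = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sig**2))
            for z, y, x in zip(nz, ny, nx):
                y0, y1 = max(0, y - half), min(shape[0], y + half + 1)
                x0, x1 = max(0, x - half), min(shape[1], x + half + 1)
                by0, bx0 = y0 - (y - half), x0 - (x - half)
                nuclei[z, y0:y1, x0:x1] += 0.8 * blob[
                    by0 : by0 + (y1 - y0), bx0 : bx0 + (x1 - x0)
                ]
            np.clip(nuclei, 0.0, 1.0, out=nuclei)

    data = np.stack([mucus, nuclei], axis=-1)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)

    stack = ZStack(
        data=data,
        z_step=spec.z_step,
        pixel_size=spec.pixel_size,
        channel_names=("mucus", "nuclei"),
    )

    n_mono = spec.n_monolayer_sections
    per_dome = [
        {
            "area_px": float(_disk_mask(shape, d.cx, d.cy, d.radius).sum()),
            "max_height_um": d.cap_height_um,
            "eccentricity": _dome_eccentricity(d),
        }
        for d in spec.domes
    ]
    truth = GroundTruth(
        coverage_by_section=masks.reshape(spec.n_sections, -1).mean(axis=1),
        dome_count=len(spec.domes),
        per_dome=per_dome,
        masks=masks,
    )
    return stack, truth


def random_separated_domes(
    spec_shape: tuple[int, int],
    n_domes: int,
    rng: np.random.Generator,
    *,
    radius_range: tuple[float, float] = (30.0, 50.0),
    cap_range: tuple[float, float] = (8.0, 12.0),
    margin: float = 8.0,
    max_tries: int = 1000,
) -> list[Dome]:
    """Sample well-separated non-overlapping domes inside the field.

    Rejection sampling: a candidate is kept if its footprint, padded by
    ``margin`` px, stays inside the image and clear of every accepted dome.
    """
    h, w = spec_shape
    domes: list[Dome] = []
    tries = 0
    while len(domes) < n_domes and tries < max_tries:
        tries += 1
        r = rng.uniform(*radius_range)
        cx = rng.uniform(r + margin, w - 1 - r - margin)
        cy = rng.uniform(r + margin, h - 1 - r - margin)
        if all(
            math.hypot(cx - d.cx, cy - d.cy) > r + d.radius + 2 * margin for d in domes
        ):
            domes.append(
                Dome(cx=cx, cy=cy, radius=r, cap_height_um=rng.uniform(*cap_range))
            )
    if len(domes) < n_domes:
        raise RuntimeError(
            f"could not place {n_domes} separated domes in {w}x{h} after {max_tries} tries"
        )
    return domes
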