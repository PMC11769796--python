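"""Per-section morphometrics: coverage profiles and connected-component shape scoring.

Three quantities summarize epithelial organization per optical section:

* **coverage** — fraction of pixels classified as cell-covered;
* **object count** — number of contiguous cell-covered components;
* **eccentricity** — elongation of each component's best-fit ellipse,
  ``e = sqrt(1 - (b/a)^2)`` for semi-axes ``a >= b`` (equivalently the
  inter-focal distance over the major-axis length), 0 for a circle and
  approaching 1 for a line.

Excluded (QC-flagged) sections propagate as missing values, never as zeros,
so that cross-replicate averages can distinguish "no cells" from "no data":
a section's mean over replicates is *full* when every replicate has data
there and *partial* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .segment import BinaryMask, _skimage_connectivity
from .zstack_io import SectionQC, excluded_sections


@dataclass
class LabeledRegions:
    """Connected-component labeling of one section's foreground."""

    labels: np.ndarray  # int array, background 0
    n_labels: int
    section_index: int
    connectivity: int = 8


@dataclass
class RegionFeatures:
    """Shape descriptors of one contiguous cell-covered object."""

    label: int
    area_px: int
    eccentricity: float
    centroid: tuple[float, float]  # (x, y) pixels
    section_index: int
    border: bool = False

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("a region must contain at least one pixel")
        if not (0.0 <= self.eccentricity <= 1.0):
            raise ValueError(f"eccentricity out of [0, 1]: {self.eccentricity}")


@dataclass
class CoverageProfile:
    """Per-section cell coverage of one replicate stack.

    ``coverage`` holds NaN at QC-excluded sections; ``heights`` are the
    section heights above the membrane in µm (strictly increasing).
    """

    replicate_id: str
    condition: str
    timepoint: str
    coverage: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.coverage.shape != self.heights.shape:
            raise ValueError("coverage and heights must align")
        if np.any(np.diff(self.heights) <= 0):
            raise ValueError("heights must be strictly increasing")
        finite = self.coverage[np.isfinite(self.coverage)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("coverage values must lie in [0, 1]")

    def auc(self) -> float:
        """Area under the coverage-vs-height profile (trapezoid, µm units).

        Missing sections are dropped; the trapezoid runs over the remaining
        height grid.  This is the scalar per-replicate summary used by the
        overall condition comparison.
        """
        ok = np.isfinite(self.coverage)
        if ok.sum() < 2:
            raise ValueError("need at least two non-missing sections for an AUC")
        return float(np.trapezoid(self.coverage[ok], self.heights[ok]))


def coverage_profile(
    masks: Sequence[BinaryMask],
    qc: Sequence[SectionQC] = (),
    z_step: float = 2.0,
    replicate_id: str = "r0",
    condition: str = "",
    timepoint: str = "",
) -> CoverageProfile:
    """Fraction of cell-covered pixels per non-excluded optical section."""
    if not masks:
        raise ValueError("empty mask list")
    shape = masks[0].data.shape
    if any(m.data.shape != shape for m in masks):
        raise ValueError("masks must share a common shape")
    dropped = excluded_sections(qc)
    cov = np.array(
        [
            np.nan if m.section_index in dropped else m.data.mean()
            for m in masks
        ]
    )
    heights = np.array([m.section_index for m in masks], dtype=float) * z_step
    return CoverageProfile(replicate_id, condition, timepoint, cov, heights)


def label_regions(mask: BinaryMask, connectivity: int = 8) -> LabeledRegions:
    """Label maximal connected foreground components (background stays 0)."""
    labels, n = measure.label(
        mask.data, connectivity=_skimage_connectivity(connectivity), return_num=True
    )
    return LabeledRegions(labels, n, mask.section_index, connectivity)


def region_features(regions: LabeledRegions) -> list[RegionFeatures]:
    """Area, eccentricity and centroid of each labeled component.

    Eccentricity comes from the ellipse with the same second central
    moments as the region; components touching the image border are kept
    but flagged so callers can filter them.
    """
    h, w = regions.labels.shape
    out: list[RegionFeatures] = []
    for rp in measure.regionprops(regions.labels):
        minr, minc, maxr, maxc = rp.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        cy, cx = rp.centroid
        out.append(
            RegionFeatures(
                label=int(rp.label),
                area_px=int(rp.area),
                eccentricity=float(min(rp.eccentricity, 1.0)),
                centroid=(float(cx), float(cy)),
                section_index=regions.section_index,
                border=border,
            )
        )
    return out


def object_count_profile(
    masks: Sequence[BinaryMask],
    connectivity: int = 8,
    qc: Sequence[SectionQC] = (),
) -> np.ndarray:
    """Contiguous-object count per section; NaN at excluded sections."""
    dropped = excluded_sections(qc)
    return np.array(
        [
            np.nan
            if m.section_index in dropped
            else float(label_regions(m, connectivity).n_labels)
            for m in masks
        ]
    )


def eccentricity_profile(
    masks: Sequence[BinaryMask],
    connectivity: int = 8,
    qc: Sequence[SectionQC] = (),
    statistic: str = "mean",
) -> np.ndarray:
    """Per-section aggregate eccentricity over objects (mean by default).

    The per-object values are aggregated with ``mean`` or ``median``; a
    section with no objects (or excluded by QC) yields NaN.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median
    dropped = excluded_sections(qc)
    out = []
    for m in masks:
        if m.section_index in dropped:
            out.append(np.nan)
            continue
        feats = region_features(label_regions(m, connectivity))
        out.append(agg([f.eccentricity for f in feats]) if feats else np.nan)
    return np.array(out)


def aggregate_profiles(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    """Cross-replicate per-section averages, flagged full vs partial.

    A section's mean is *full* when every replicate contributes a
    non-missing value at that height and *partial* otherwise (replicates
    can lose sections to QC or differing stack depths).  Returns a tidy
    frame with columns section, height_um, mean_coverage, n, kind.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    n_rep = len(profiles)
    records = []
    heights = profiles[0].heights
    for p in profiles[1:]:
        if p.heights.shape != heights.shape or not np.allclose(p.heights, heights):
            raise ValueError("profiles must share a common section/height grid")
    values = np.vstack([p.coverage for p in profiles])
    for j, h in enumerate(heights):
        col = values[:, j]
        ok = np.isfinite(col)
        if ok.sum() == 0:
            continue
        records.append(
            {
                "section": j,
                "height_um": float(h),
                "mean_coverage": float(col[ok].mean()),
                "n": int(ok.sum()),
                "kind": "full" if ok.sum() == n_rep else "partial",
            }
        )
    return pd.DataFrame.from_records(records)
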