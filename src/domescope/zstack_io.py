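"""Reading and writing of multichannel confocal z-stacks and tabular results.

A z-stack is stored as a 4D float array indexed ``(section, y, x, channel)``
with physical calibration (xy pixel size and axial step, both in µm).
Sections are 0-based and ordered bottom to top: section 0 is the plane of the
Transwell membrane, and section ``i`` sits at height ``i * z_step`` µm above
it.  On disk, stacks are plain multi-page TIFF with calibration carried in a
JSON description tag, so a stack written by :func:`write_stack` round-trips
exactly through :func:`read_stack`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

_DESCRIPTION_KEY = "domescope"


@dataclass
class ZStack:
    """Two-(or more-)channel 3D intensity volume with physical calibration.

    Attributes
    ----------
    data:
        Float array of shape ``(n_sections, height, width, n_channels)``;
        intensities are finite and non-negative.
    z_step:
        Axial spacing between consecutive optical sections, µm.
    pixel_size:
        Lateral pixel size, µm.
    channel_names:
        Ordered channel labels, e.g. ``("mucus", "nuclei")``.
    """

    data: np.ndarray
    z_step: float
    pixel_size: float
    channel_names: tuple[str, ...] = ("mucus", "nuclei")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4D (section, y, x, channel), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one section")
        if self.z_step <= 0:
            raise ValueError(f"z_step must be positive, got {self.z_step}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[-1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[-1]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    def section_heights(self) -> np.ndarray:
        """Height of each section above the membrane, µm (section i at i*z_step)."""
        return np.arange(self.n_sections, dtype=float) * self.z_step

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Single-channel sub-volume ``(section, y, x)`` by label or index."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"no channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.data[..., idx]


@dataclass
class SectionQC:
    """Per-section quality-control verdict.

    Excluded sections (e.g. sections crossed by glass-slide grid artifacts)
    are dropped from all downstream profiles and carry the reason with them.
    """

    section_index: int
    excluded: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.reason:
            raise ValueError("an excluded section must carry a non-empty reason")


def validate_qc(qc: Sequence[SectionQC], n_sections: int) -> None:
    indices = [q.section_index for q in qc]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate section indices in QC records")
    bad = [i for i in indices if i < 0 or i >= n_sections]
    if bad:
        raise ValueError(f"QC indices out of range for {n_sections} sections: {bad}")


def excluded_sections(qc: Sequence[SectionQC]) -> set[int]:
    return {q.section_index for q in qc if q.excluded}


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write a :class:`ZStack` as a multi-page TIFF with embedded calibration.

    Planes are stored as float32 in (section, channel, y, x) order; z_step,
    pixel_size and channel names go into a JSON description tag so the file
    is self-describing for :func:`read_stack`.
    """
    path = Path(path)
    meta = {
        _DESCRIPTION_KEY: {
            "z_step_um": stack.z_step,
            "pixel_size_um": stack.pixel_size,
            "channel_names": list(stack.channel_names),
        }
    }
    # (section, y, x, channel) -> (section, channel, y, x) plane order
    planes = np.moveaxis(stack.data, -1, 1).astype(np.float32)
    tifffile.imwrite(path, planes, description=json.dumps(meta))
    return path


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    *,
    z_step: float | None = None,
    pixel_size: float | None = None,
) -> ZStack:
    """Read a TIFF / OME-TIFF z-stack into a :class:`ZStack`.

    Parameters
    ----------
    path:
        TIFF file with planes ordered section-major (all channels of section
        0, then section 1, ...), bottom (membrane) section first.
    channel_map:
        Mapping from channel label to channel index within the file, e.g.
        ``{"mucus": 0, "nuclei": 1}``.  Determines both the channel count and
        the output channel order.  Defaults to the names stored in the file,
        else a single channel named "mucus".
    z_step, pixel_size:
        Calibration overrides in µm.  Explicit values win over file metadata
        (with a logged warning on disagreement); one of file metadata or the
        argument must supply each.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack file: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    file_meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            file_meta = parsed.get(_DESCRIPTION_KEY, {})
        except (json.JSONDecodeError, AttributeError):
            file_meta = {}

    if channel_map is None:
        names = file_meta.get("channel_names")
        if names:
            channel_map = {n: i for i, n in enumerate(names)}
        else:
            channel_map = {"mucus": 0}
    n_channels = len(channel_map)

    if arr.ndim == 2:
        arr = arr[None, None]  # single plane -> (1 section, 1 channel, y, x)
    elif arr.ndim == 3:
        # pages of a plain multi-page TIFF: (planes, y, x)
        n_planes = arr.shape[0]
        if n_planes % n_channels != 0:
            raise ValueError(
                f"{n_planes} planes not divisible by {n_channels} channels"
            )
        arr = arr.reshape(n_planes // n_channels, n_channels, *arr.shape[1:])
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with array shape {arr.shape}")

    max_idx = max(channel_map.values())
    if max_idx >= arr.shape[1]:
        raise ValueError(
            f"channel_map index {max_idx} out of range for {arr.shape[1]} file channels"
        )

    def _resolve(name: str, override: float | None) -> float:
        from_file = file_meta.get(f"{name}_um")
        if override is not None:
            if from_file is not None and not np.isclose(override, from_file):
                logger.warning(
                    "%s: config %s=%g overrides file metadata %g", path, name, override, from_file
                )
            value = override
        elif from_file is not None:
            value = float(from_file)
        else:
            raise ValueError(f"{name} not in file metadata and not provided")
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
        return value

    names_sorted = sorted(channel_map, key=channel_map.__getitem__)
    sel = [channel_map[n] for n in names_sorted]
    data = np.moveaxis(arr[:, sel].astype(np.float64), 1, -1)
    return ZStack(
        data=data,
        z_step=_resolve("z_step", z_step),
        pixel_size=_resolve("pixel_size", pixel_size),
        channel_names=tuple(names_sorted),
    )


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> Path:
    """Write homogeneous result records (features/coverage/stats) to CSV.

    Refuses empty input: an empty file is indistinguishable from a failed
    run, so the degenerate case is an error by contract.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("refusing to write an empty table")
        keys = set(records[0].keys())
        for r in records[1:]:
            if set(r.keys()) != keys:
                raise ValueError("records do not share a homogeneous schema")
        df = pd.DataFrame.from_records(records)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
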