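"""Shared domain types for the myofiber-typing pipeline.

A stained muscle cross-section is carried through the pipeline as a
:class:`SectionImage` (multichannel raster with a physical pixel size and a
role per channel).  Pixel classification yields a :class:`ProbabilityMap`
(per-pixel myofiber-boundary probability), segmentation a :class:`LabelMap`
(one integer label per myofiber ROI), and measurement an :class:`MFITable`
(one record per ROI x channel, mirroring the tab-delimited measurement
export of the original Fiji workflow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np


class ChannelRole(str, Enum):
    """Biological role of one image channel.

    The staining panel marks the three most abundant myosin heavy chain
    (MyHC) isoforms plus laminin (basement membrane, outlining every fiber).
    ``CLASSIFICATION`` is the pixel-classification output appended as an
    extra channel before measurement.
    """

    MYHC1 = "MYHC1"
    MYHC2A = "MYHC2A"
    MYHC2X_OR_2B = "MYHC2X_OR_2B"
    LAMININ = "LAMININ"
    CLASSIFICATION = "CLASSIFICATION"


#: Conventional 4-channel acquisition order.
DEFAULT_CHANNEL_ROLES = (
    ChannelRole.MYHC1,
    ChannelRole.MYHC2A,
    ChannelRole.MYHC2X_OR_2B,
    ChannelRole.LAMININ,
)

#: Column order of the tab-delimited measurement (``_MFI``) files.
MFI_COLUMNS = (
    "Label",
    "Area",
    "Mean",
    "StdDev",
    "Mode",
    "Min",
    "Max",
    "Median",
    "Circ.",
    "Mean_boundary",
    "StdDev_boundary",
    "Mean_distance",
)

#: Columns that must be present in any MFI file; the rest may be absent
#: (the published worked example prints only a subset) and parse as NaN.
MFI_REQUIRED_COLUMNS = ("Label", "Area", "Mean")


@dataclass
class SectionImage:
    """A multichannel section raster with physical pixel size.

    ``pixels`` is ``H x W x C``; integer 16-bit on disk, float allowed in
    memory (block-averaged downsampling and shading correction produce
    fractional values).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_roles: tuple[ChannelRole, ...]
    sample_id: str = ""
    section_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        h, w, c = self.pixels.shape
        if h < 1 or w < 1:
            raise ValueError("image must have at least one pixel")
        self.channel_roles = tuple(ChannelRole(r) for r in self.channel_roles)
        if len(self.channel_roles) != c:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for {c} channels"
            )
        counts: dict[ChannelRole, int] = {}
        for r in self.channel_roles:
            counts[r] = counts.get(r, 0) + 1
        dupes = [r.value for r, n in counts.items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate channel roles: {dupes}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if np.issubdtype(self.pixels.dtype, np.integer) and self.pixels.min() < 0:
            raise ValueError("pixel values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, role: ChannelRole | str) -> np.ndarray:
        """Return the 2-D raster of the channel with the given role."""
        role = ChannelRole(role)
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role.value}") from None
        return self.pixels[:, :, idx]

    def has_role(self, role: ChannelRole | str) -> bool:
        return ChannelRole(role) in self.channel_roles


@dataclass
class ProbabilityMap:
    """Per-pixel myofiber-boundary probability in [0, 1]."""

    values: np.ndarray
    source: str = "internal_classifier"  # or "external_file"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LabelMap:
    """Integer ROI labels per pixel; 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)


@dataclass
class TissueMask:
    """Binary tissue-foreground mask."""

    mask: np.ndarray
    edits_applied: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class ROIChannelRecord:
    """One measurement row: one ROI in one channel.

    ``label`` is ``"<roi id>:<channel number>"``.  Shape-derived fields
    (``area_um2``, ``circ``, ``mean_distance``) repeat identically across
    the C rows of one ROI.  Optional statistics absent from a parsed file
    are NaN.
    """

    label: str
    area_um2: float
    mean: float
    circ: float = math.nan
    mean_boundary: float = math.nan
    stddev_boundary: float = math.nan
    mean_distance: float = math.nan
    stddev: float = math.nan
    mode: float = math.nan
    min: float = math.nan
    max: float = math.nan
    median: float = math.nan

    @property
    def roi_id(self) -> str:
        return self.label.rsplit(":", 1)[0]

    @property
    def channel(self) -> int:
        return int(self.label.rsplit(":", 1)[1])


@dataclass
class MFITable:
    """Ordered collection of per-(ROI, channel) measurement records."""

    records: list[ROIChannelRecord] = field(default_factory=list)
    n_channels: int = 5
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.records and len(self.records) % self.n_channels:
            raise ValueError(
                f"{len(self.records)} records is not a multiple of "
                f"{self.n_channels} channels"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_rois(self) -> int:
        return len(self.records) // self.n_channels if self.records else 0

    @property
    def roi_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.roi_id, None)
        return list(seen)

    def to_dataframe(self):
        """Long-format DataFrame with one row per (ROI, channel)."""
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                {
                    "Label": r.label,
                    "roi_id": r.roi_id,
                    "channel": r.channel,
                    "Area": r.area_um2,
                    "Mean": r.mean,
                    "StdDev": r.stddev,
                    "Mode": r.mode,
                    "Min": r.min,
                    "Max": r.max,
                    "Median": r.median,
                    "Circ.": r.circ,
                    "Mean_boundary": r.mean_boundary,
                    "StdDev_boundary": r.stddev_boundary,
                    "Mean_distance": r.mean_distance,
                }
            )
        return pd.DataFrame(rows)

    def channel_matrix(self, channels: Sequence[int], stat: str = "mean") -> np.ndarray:
        """n_rois x len(channels) matrix of one statistic, ROI order preserved."""
        by_roi: dict[str, dict[int, ROIChannelRecord]] = {}
        for r in self.records:
            by_roi.setdefault(r.roi_id, {})[r.channel] = r
        out = np.empty((len(by_roi), len(channels)))
        for i, (roi, chans) in enumerate(by_roi.items()):
            for j, c in enumerate(channels):
                out[i, j] = getattr(chans[c], stat)
        return out


def iter_rois(table: MFITable) -> Iterable[tuple[str, list[ROIChannelRecord]]]:
    """Yield (roi_id, records sorted by channel) groups in table order."""
    by_roi: dict[str, list[ROIChannelRecord]] = {}
    for r in table.records:
        by_roi.setdefault(r.roi_id, []).append(r)
    for roi, recs in by_roi.items():
        yield roi, sorted(recs, key=lambda r: r.channel)
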