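"""Readers and writers for the pipeline's file formats.

Rasters travel as multichannel 16-bit TIFF (channel-interleaved planes)
with the physical pixel size in the TIFF resolution tags, duplicated in a
JSON sidecar (``<image>.meta.json``).  The sidecar wins on conflict:
explicit metadata beats what a converter happened to stamp into the tags.
Measurements travel as tab-delimited ``_MFI`` text files.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .core import (
    MFI_COLUMNS,
    MFI_REQUIRED_COLUMNS,
    ChannelRole,
    LabelMap,
    MFITable,
    ProbabilityMap,
    ROIChannelRecord,
    SectionImage,
    TissueMask,
)

_CM_PER_UM = 1e-4

#: Map from MFI column name to ROIChannelRecord attribute.
_COL_TO_ATTR = {
    "Label": "label",
    "Area": "area_um2",
    "Mean": "mean",
    "StdDev": "stddev",
    "Mode": "mode",
    "Min": "min",
    "Max": "max",
    "Median": "median",
    "Circ.": "circ",
    "Mean_boundary": "mean_boundary",
    "StdDev_boundary": "stddev_boundary",
    "Mean_distance": "mean_distance",
}


def _sidecar_path(path: os.PathLike | str) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_multichannel_tiff(
    image: SectionImage, path: os.PathLike | str, overwrite: bool = True
) -> Path:
    """Write a SectionImage as a multi-plane TIFF plus a JSON sidecar.

    Integer data is written as uint16 (bit-for-bit round trip); float data
    as float32.  Pixel size is recorded in the resolution tags (pixels per
    centimeter) and, authoritatively, in the sidecar.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(path)
    px = image.pixels
    if np.issubdtype(px.dtype, np.integer):
        if px.max(initial=0) > 0xFFFF:
            raise ValueError("integer pixel values exceed 16-bit range")
        data = px.astype(np.uint16)
    else:
        data = px.astype(np.float32)
    res = 1.0 / (image.pixel_size_um * _CM_PER_UM)  # px per cm
    tifffile.imwrite(
        path,
        np.moveaxis(data, 2, 0),
        resolution=(res, res),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )
    meta = {
        "pixel_size_um": image.pixel_size_um,
        "channel_roles": [r.value for r in image.channel_roles],
        "sample_id": image.sample_id,
        "section_index": image.section_index,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_multichannel_tiff(
    path: os.PathLike | str,
    channel_roles: Sequence[ChannelRole | str] | None = None,
    pixel_size_um: float | None = None,
) -> SectionImage:
    """Read a multichannel TIFF into a SectionImage.

    Channel roles and pixel size come from, in order of precedence: the
    explicit arguments, the JSON sidecar, the TIFF resolution tags (pixel
    size only).  A pixel size that cannot be determined is an error, never
    a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        page = tf.pages[0]
        tag_px: float | None = None
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None:
            num, den = res.value
            if num:
                per_unit = num / den
                # unit 3 = cm, 2 = inch; anything else unusable
                if unit is not None and getattr(unit.value, "value", unit.value) == 2:
                    tag_px = 25400.0 / per_unit
                else:
                    tag_px = 1.0 / (per_unit * _CM_PER_UM)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    pixels = np.moveaxis(arr, 0, 2)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if channel_roles is None:
        channel_roles = meta.get("channel_roles")
    if channel_roles is None:
        raise ValueError(
            f"no channel roles configured for {path.name} and no sidecar found"
        )
    if len(channel_roles) != pixels.shape[2]:
        raise ValueError(
            f"{path.name}: file has {pixels.shape[2]} channels but "
            f"{len(channel_roles)} roles are configured"
        )
    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um", tag_px)
    if pixel_size_um is None:
        raise ValueError(
            f"{path.name}: pixel size not in arguments, sidecar or TIFF tags"
        )
    return SectionImage(
        pixels=pixels,
        pixel_size_um=float(pixel_size_um),
        channel_roles=tuple(ChannelRole(r) for r in channel_roles),
        sample_id=str(meta.get("sample_id", path.stem)),
        section_index=int(meta.get("section_index", 0)),
    )


def write_probability_map(prob: ProbabilityMap, path: os.PathLike | str) -> Path:
    """Write a boundary-probability map as 32-bit float TIFF in [0, 1]."""
    path = Path(path)
    tifffile.imwrite(path, prob.values.astype(np.float32))
    return path


def read_probability_map(path: os.PathLike | str) -> ProbabilityMap:
    """Read a probability TIFF, accepting either float [0,1] or 8-bit 0-255.

    This is the interop path for externally produced (Ilastik-style)
    probability exports, which are commonly scaled to 0-255.
    """
    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:  # two-class export: take the boundary plane
        arr = arr[0] if arr.shape[0] < arr.shape[-1] else arr[..., 0]
    if arr.max(initial=0) > 1.0:
        arr = arr / 255.0
    return ProbabilityMap(values=np.clip(arr, 0.0, 1.0), source="external_file")


def write_label_map(labels: LabelMap, path: os.PathLike | str) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.int32))
    return path


def read_label_map(path: os.PathLike | str) -> LabelMap:
    return LabelMap(labels=np.asarray(tifffile.imread(path)).astype(np.int64))


def write_mask(mask: TissueMask, path: os.PathLike | str) -> Path:
    """Mask TIFF, 8-bit with foreground 255."""
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    return path


def read_mask(path: os.PathLike | str) -> TissueMask:
    return TissueMask(mask=np.asarray(tifffile.imread(path)) > 0)


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return f"{x:.3f}".rstrip("0").rstrip(".") if x == x else ""


def write_mfi_table(table: MFITable, path: os.PathLike | str) -> Path:
    """Write the tab-delimited measurement file (decimal point '.').

    One header row, then one line per (ROI, channel); numeric fields at
    3-decimal precision, NaN fields empty.  An empty table yields a
    header-only file.
    """
    path = Path(path)
    lines = ["\t".join(MFI_COLUMNS)]
    for r in table.records:
        lines.append(
            "\t".join(
                [r.label]
                + [_fmt(getattr(r, _COL_TO_ATTR[c])) for c in MFI_COLUMNS[1:]]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mfi_table(path: os.PathLike | str, n_channels: int | None = None) -> MFITable:
    """Parse a tab-delimited MFI file.

    Columns beyond the known schema are an error; known columns may be
    absent (older exports print a subset) and parse as NaN.  Malformed
    rows raise with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path.name}: empty file, no header")
    header = lines[0].split("\t")
    unknown = [c for c in header if c not in _COL_TO_ATTR]
    if unknown:
        raise ValueError(f"{path.name}: unknown column(s) {unknown}")
    missing_req = [c for c in MFI_REQUIRED_COLUMNS if c not in header]
    if missing_req:
        raise ValueError(f"{path.name}: missing required column(s) {missing_req}")
    records: list[ROIChannelRecord] = []
    channels_seen: set[int] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path.name} line {lineno}: {len(fields)} fields, "
                f"expected {len(header)}"
            )
        kwargs: dict[str, object] = {}
        for col, val in zip(header, fields):
            attr = _COL_TO_ATTR[col]
            if attr == "label":
                kwargs[attr] = val
            else:
                try:
                    kwargs[attr] = float(val) if val.strip() else math.nan
                except ValueError:
                    raise ValueError(
                        f"{path.name} line {lineno}: bad numeric value "
                        f"{val!r} in column {col}"
                    ) from None
        label = str(kwargs.get("label", ""))
        if ":" not in label:
            raise ValueError(
                f"{path.name} line {lineno}: label {label!r} is not "
                "'<roi>:<channel>'"
            )
        rec = ROIChannelRecord(**kwargs)  # type: ignore[arg-type]
        channels_seen.add(rec.channel)
        records.append(rec)
    if n_channels is None:
        n_channels = max(channels_seen) if channels_seen else 5
    return MFITable(records=records, n_channels=n_channels, provenance=str(path))


def write_filter_table(df, path: os.PathLike | str) -> Path:
    """Write the ``_Filt`` table (MFI columns + per-filter 0/1 + aggregate)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path
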