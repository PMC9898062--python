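"""Tissue masking: automatic mask, scripted polygon edits, masked laminin,
and the tissue-edge distance map.

The automatic mask finds the section outline from the laminin channel
(which outlines every fiber regardless of type).  Manual cleanup of
artifacts — folds, out-of-focus regions, scratches, dirt — is replaced by
an ordered, reproducible list of polygon add/remove edits stored beside
the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects

from .core import ChannelRole, SectionImage, TissueMask


@dataclass
class MaskParams:
    blur_sigma_px: float = 10.0
    min_area_px: int = 2000
    keep_fraction_of_largest: float = 0.10


@dataclass
class PolygonEdit:
    """One scripted mask edit: add or remove a polygon region.

    Vertices are (row, col), 0-based; a pixel belongs to the polygon if
    its center lies inside (even-odd rule).
    """

    op: str  # "add" | "remove"
    polygon: np.ndarray  # (k, 2) float (row, col)

    def __post_init__(self) -> None:
        if self.op not in ("add", "remove"):
            raise ValueError(f"unknown edit op {self.op!r}")
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")


def auto_tissue_mask(
    image: SectionImage, params: MaskParams | None = None
) -> TissueMask:
    """Automatic tissue mask from the laminin channel.

    Gaussian blur (sigma 10 px), Otsu threshold, hole filling, removal of
    objects below ``min_area_px``, and of components smaller than 10% of
    the largest — which drops dirt specks while keeping genuinely split
    tissue pieces.
    """
    params = params or MaskParams()
    lam = image.channel(ChannelRole.LAMININ).astype(np.float64)
    if not lam.any() or lam.max() == lam.min():
        raise ValueError("no tissue found: laminin channel is blank")
    blurred = gaussian(lam, sigma=params.blur_sigma_px, preserve_range=True)
    thr = threshold_otsu(blurred)
    fg = blurred > thr
    if not fg.any():
        raise ValueError("no tissue found: nothing above Otsu threshold")
    fg = ndi.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=params.min_area_px - 1)
    lab, n = ndi.label(fg)
    if n == 0:
        raise ValueError("no tissue found after size filtering")
    sizes = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(sizes >= params.keep_fraction_of_largest * sizes.max()) + 1
    fg = np.isin(lab, keep)
    return TissueMask(mask=fg)


def rasterize_polygon(
    polygon: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean raster of pixels whose centers fall inside the polygon."""
    poly = np.asarray(polygon, dtype=float)
    h, w = shape
    if (
        poly[:, 0].min() < -0.5
        or poly[:, 1].min() < -0.5
        or poly[:, 0].max() > h - 0.5
        or poly[:, 1].max() > w - 0.5
    ):
        raise ValueError("polygon vertices outside image bounds")
    shp = Polygon(poly[:, ::-1])  # shapely wants (x, y) = (col, row)
    r0 = max(0, int(np.floor(poly[:, 0].min())))
    r1 = min(h, int(np.ceil(poly[:, 0].max())) + 1)
    c0 = max(0, int(np.floor(poly[:, 1].min())))
    c1 = min(w, int(np.ceil(poly[:, 1].max())) + 1)
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = shapely.contains_xy(shp, xx.ravel(), yy.ravel()).reshape(yy.shape)
    out[r0:r1, c0:c1] = inside
    return out


def apply_mask_edits(
    mask: TissueMask, edits: Sequence[PolygonEdit]
) -> TissueMask:
    """Apply add/remove polygon edits in order; each edit is idempotent."""
    out = mask.mask.copy()
    for e in edits:
        region = rasterize_polygon(e.polygon, out.shape)
        if e.op == "add":
            out |= region
        else:
            out &= ~region
    return TissueMask(mask=out, edits_applied=mask.edits_applied + len(edits))


def masked_laminin(
    image: SectionImage, mask: TissueMask, sigma_px: float = 4.0
) -> np.ndarray:
    """Feathered masked copy of the laminin channel.

    The binary mask is Gaussian-blurred (default sigma 4 px) into a soft
    weight m; outside-tissue pixels fade to the median laminin intensity
    of the background, avoiding the hard edge a binary mask would imprint
    on the subsequent pixel classification:

        out = m * laminin + (1 - m) * median(laminin | mask == 0)
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    lam = image.channel(ChannelRole.LAMININ).astype(np.float64)
    if mask.shape != lam.shape:
        raise ValueError(f"mask shape {mask.shape} != image {lam.shape}")
    bg = lam[~mask.mask]
    med = float(np.median(bg)) if bg.size else float(np.median(lam))
    m = ndi.gaussian_filter(mask.mask.astype(np.float64), sigma_px, mode="nearest")
    return m * lam + (1.0 - m) * med


def edge_distance_map(mask: TissueMask, pixel_size_um: float) -> np.ndarray:
    """Euclidean distance (um) from each tissue pixel to the tissue edge.

    The image frame counts as background (a 1-px virtual border), so a
    mask that touches the frame still gets finite distances.  Zero outside
    the mask.
    """
    if not mask.mask.any():
        raise ValueError("empty mask has no distances")
    padded = np.pad(mask.mask, 1)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return dist * pixel_size_um
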