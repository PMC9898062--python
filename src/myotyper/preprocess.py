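"""Downsampling and retrospective shading correction.

Whole-slide scans carry smooth, low-frequency illumination inhomogeneity
("shading") that is unrelated to biology and must be divided out before
intensities are compared across a section.  The estimator here recovers a
per-channel multiplicative profile by heavy Gaussian smoothing of the
image itself (shading varies over a scale much larger than a fiber), takes
the per-pixel median across slides to suppress tissue structure, and
divides it out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .core import SectionImage

_PROFILE_FLOOR = 0.05


@dataclass
class ShadingProfile:
    """Multiplicative illumination profile for one channel, mean 1."""

    values: np.ndarray
    channel_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("profile must be 2-D")
        if self.values.min() <= 0:
            raise ValueError("profile must be strictly positive")


def downsample_by_averaging(image: SectionImage, factor: int) -> SectionImage:
    """Block-average the image by an integer factor.

    Each output pixel is the arithmetic mean of its ``factor x factor``
    block; trailing partial blocks are averaged over the pixels they
    contain rather than dropped.  The pixel size scales by ``factor``; a
    warning is emitted if the result leaves the 1-5 um working range that
    the downstream segmentation expects.
    """
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    h, w, c = image.pixels.shape
    if factor > h or factor > w:
        raise ValueError("factor exceeds image size")
    px = image.pixels.astype(np.float64)
    row_idx = np.arange(0, h, factor)
    col_idx = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(px, row_idx, axis=0), col_idx, axis=1)
    rows_per = np.diff(np.append(row_idx, h))
    cols_per = np.diff(np.append(col_idx, w))
    counts = np.outer(rows_per, cols_per)[:, :, None]
    out = sums / counts
    new_px_size = image.pixel_size_um * factor
    if not (1.0 <= new_px_size <= 5.0):
        warnings.warn(
            f"pixel size {new_px_size:.3g} um is outside the 1-5 um range "
            "recommended for fiber segmentation",
            stacklevel=2,
        )
    return replace(image, pixels=out, pixel_size_um=new_px_size)


def _coarse_foreground(ch: np.ndarray, sigma: float) -> np.ndarray | None:
    """Tissue-vs-background split, or None when the channel is not
    strongly bimodal (e.g. a blank or smoothly shaded flat field).

    Without this, heavy smoothing of a bright tissue region on a dark
    background leaks the tissue outline into the shading estimate and the
    correction over-divides the section's center.
    """
    from skimage.filters import threshold_otsu

    blurred = ndi.gaussian_filter(ch, min(sigma / 4, 10.0), mode="nearest")
    if blurred.max() == blurred.min():
        return None
    thr = threshold_otsu(blurred)
    fg = blurred > thr
    if not fg.any() or fg.all():
        return None
    mu_fg = float(blurred[fg].mean())
    mu_bg = float(blurred[~fg].mean())
    if mu_bg <= 0 or mu_fg / max(mu_bg, 1e-12) < 4.0:
        return None  # smooth gradient, not tissue/background contrast
    return fg


def estimate_shading_profile(
    image: SectionImage,
    channel: int,
    smooth_sigma_px: float | None = None,
    foreground: np.ndarray | None = None,
) -> ShadingProfile:
    """Estimate one channel's shading profile from the image itself.

    Heavy Gaussian smoothing (default sigma = min(H, W)/12: large against
    a fiber, small enough to keep attenuation of an image-scale
    illumination field below ~15%) leaves only the low-frequency
    illumination trend.  When
    the channel shows strong tissue/background contrast (or an explicit
    ``foreground`` mask is given), smoothing is a normalized convolution
    over foreground pixels only, so the tissue outline itself does not
    masquerade as shading.  The profile is normalized to mean 1 and
    floored at 0.05 so division stays safe.
    """
    ch = image.pixels[:, :, channel].astype(np.float64)
    if not ch.any():
        raise ValueError(f"channel {channel} is all zero: no signal to estimate")
    if smooth_sigma_px is None:
        smooth_sigma_px = min(ch.shape) / 12
    if smooth_sigma_px <= 0:
        raise ValueError("smooth_sigma_px must be positive")
    if foreground is None:
        foreground = _coarse_foreground(ch, smooth_sigma_px)
    if foreground is None:
        smooth = ndi.gaussian_filter(ch, smooth_sigma_px, mode="nearest")
    else:
        m = foreground.astype(np.float64)
        num = ndi.gaussian_filter(ch * m, smooth_sigma_px, mode="nearest")
        den = ndi.gaussian_filter(m, smooth_sigma_px, mode="nearest")
        smooth = num / np.maximum(den, 1e-9)
    prof = smooth / smooth.mean()
    prof = np.maximum(prof, _PROFILE_FLOOR)
    prof = prof / prof.mean()
    return ShadingProfile(values=prof, channel_index=channel)


def estimate_slide_profile(image: SectionImage) -> ShadingProfile:
    """Estimate the slide's illumination field from the laminin channel.

    Laminin stains every fiber boundary regardless of type, so its
    large-scale intensity is spatially stationary and any low-frequency
    trend is illumination.  The MyHC channels are patchy (fiber types
    cluster), which a self-estimated per-channel profile would mistake
    for shading; the pipeline therefore estimates one field per slide
    from laminin and divides it out of every channel.
    """
    from .core import ChannelRole

    if not image.has_role(ChannelRole.LAMININ):
        raise ValueError("image has no laminin channel to estimate shading from")
    idx = image.channel_roles.index(ChannelRole.LAMININ)
    return estimate_shading_profile(image, idx)


def median_shading_profile(profiles: Sequence[ShadingProfile]) -> ShadingProfile:
    """Per-pixel median across slides' profiles, renormalized to mean 1.

    The median suppresses slide-specific tissue structure that leaked into
    individual profiles, leaving the illumination pattern the slides share.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    shapes = {p.values.shape for p in profiles}
    if len(shapes) > 1:
        raise ValueError(f"profile shapes differ: {shapes}")
    med = np.median(np.stack([p.values for p in profiles]), axis=0)
    med = np.maximum(med, _PROFILE_FLOOR)
    return ShadingProfile(
        values=med / med.mean(), channel_index=profiles[0].channel_index
    )


def apply_shading_correction(
    image: SectionImage, profiles: Sequence[ShadingProfile]
) -> SectionImage:
    """Divide each channel by its profile, clipped to the 16-bit range."""
    c = image.n_channels
    by_ch = {p.channel_index: p for p in profiles}
    missing = [i for i in range(c) if i not in by_ch]
    if missing:
        raise ValueError(f"no shading profile for channel(s) {missing}")
    out = np.empty(image.pixels.shape, dtype=np.float64)
    for i in range(c):
        prof = by_ch[i]
        if prof.values.shape != image.shape:
            raise ValueError(
                f"profile shape {prof.values.shape} != image {image.shape}"
            )
        out[:, :, i] = image.pixels[:, :, i] / prof.values
    out = np.clip(out, 0, 0xFFFF)
    return replace(image, pixels=out)
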