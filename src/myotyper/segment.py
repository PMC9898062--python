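"""Myofiber segmentation from the boundary-probability map.

Seeds are the connected components of confidently-non-boundary tissue;
a watershed on the smoothed probability surface grows them outward so
that adjacent fibers separated by a weak (gappy) laminin line still end
up as distinct ROIs.  Pixels on the boundary ridge itself stay
unassigned: ROI interiors deliberately exclude the laminin line, which is
what makes the interior/boundary statistics of the classification channel
discriminative for segmentation quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .core import LabelMap, ProbabilityMap, TissueMask


@dataclass
class SegmentationParams:
    prob_threshold: float = 0.5
    smooth_sigma_px: float = 1.0
    min_seed_area_px: int = 9
    seed_erosion_px: int = 2
    border_policy: str = "exclude"  # or "keep"

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be strictly inside (0, 1)")
        if self.border_policy not in ("exclude", "keep"):
            raise ValueError(f"unknown border policy {self.border_policy!r}")


def segment_fibers(
    prob: ProbabilityMap,
    mask: TissueMask,
    params: SegmentationParams | None = None,
) -> LabelMap:
    """Watershed the boundary probability into per-fiber labels.

    1. Gaussian-smooth the probability (sigma ``smooth_sigma_px``).
    2. Boundary mask: smoothed probability >= threshold.
    3. Seeds: 4-connected components of tissue-and-not-boundary, eroded
       by ``seed_erosion_px`` so that narrow leaks through the thresholded
       boundary cannot chain two fibers into one seed, then kept if area
       >= ``min_seed_area_px``.
    4. Watershed the smoothed probability from the seeds, restricted to
       tissue (this regrows the eroded margin and closes laminin gaps).
    5. Boundary-ridge pixels are reset to background.
    """
    params = params or SegmentationParams()
    if prob.shape != mask.shape:
        raise ValueError(f"probability {prob.shape} vs mask {mask.shape}")
    if not mask.mask.any():
        raise ValueError("empty tissue mask")
    smooth = ndi.gaussian_filter(prob.values, params.smooth_sigma_px)
    boundary = smooth >= params.prob_threshold
    seed_region = mask.mask & ~boundary
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if params.seed_erosion_px > 0:
        seed_region = ndi.binary_erosion(
            seed_region, four, iterations=params.seed_erosion_px
        )
    seeds, n = ndi.label(seed_region, structure=four)
    if n and params.min_seed_area_px > 1:
        sizes = np.bincount(seeds.ravel())
        small = np.flatnonzero(sizes < params.min_seed_area_px)
        seeds[np.isin(seeds, small)] = 0
    labels = watershed(smooth, markers=seeds, mask=mask.mask, connectivity=1)
    labels[boundary] = 0
    _keep_largest_component(labels, four)
    return _relabel(labels)


def _keep_largest_component(lab: np.ndarray, structure: np.ndarray) -> None:
    """Removing ridge pixels can split a label; keep its largest piece so
    every ROI stays 4-connected."""
    for sl, roi_id in zip(ndi.find_objects(lab), range(1, int(lab.max()) + 1)):
        if sl is None:
            continue
        local = lab[sl] == roi_id
        comp, n = ndi.label(local, structure=structure)
        if n <= 1:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        lab[sl][local & (comp != keep)] = 0


def filter_labels(
    labels: LabelMap | np.ndarray,
    min_area_px: int = 9,
    border_policy: str = "exclude",
) -> LabelMap:
    """Pre-measurement cleanup of a label map.

    Removes components smaller than ``min_area_px``; under the default
    ``exclude`` policy also removes ROIs touching the image frame (their
    shape statistics would be truncated).  Relabels contiguously 1..N.
    """
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    lab = lab.copy()
    if lab.size == 0 or lab.max() == 0:
        return _relabel(lab)
    sizes = np.bincount(lab.ravel())
    drop = set(np.flatnonzero(sizes < min_area_px).tolist())
    if border_policy == "exclude":
        frame = np.concatenate(
            [lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]
        )
        drop |= set(np.unique(frame).tolist())
    drop.discard(0)
    if drop:
        lab[np.isin(lab, list(drop))] = 0
    return _relabel(lab)


def _relabel(lab: np.ndarray) -> LabelMap:
    """Renumber labels contiguously 1..N preserving order."""
    out = np.zeros_like(lab, dtype=np.int64)
    ids = np.unique(lab)
    ids = ids[ids > 0]
    lut = np.zeros(int(lab.max()) + 1 if lab.size else 1, dtype=np.int64)
    lut[ids] = np.arange(1, len(ids) + 1)
    if lab.size:
        out = lut[lab]
    return LabelMap(labels=out)


def match_to_truth(
    predicted: LabelMap, truth: LabelMap, iou_threshold: float = 0.7
) -> dict:
    """One-to-one Hungarian matching of predicted vs truth ROIs by IoU.

    Returns match pairs, per-match IoU, and recall (matched truth fibers /
    truth fibers).  Used to validate segmentation against phantom truth.
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.sparse import coo_matrix

    p = predicted.labels.ravel()
    t = truth.labels.ravel()
    both = (p > 0) | (t > 0)
    p, t = p[both], t[both]
    np_, nt = int(predicted.labels.max()), int(truth.labels.max())
    inter = coo_matrix(
        (np.ones(len(p)), (p, t)), shape=(np_ + 1, nt + 1)
    ).toarray()
    area_p = inter.sum(axis=1)
    area_t = inter.sum(axis=0)
    union = area_p[:, None] + area_t[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    iou = iou[1:, 1:]  # drop background
    if iou.size == 0:
        return {"pairs": [], "ious": [], "recall": 0.0}
    rows, cols = linear_sum_assignment(-iou)
    pairs, ious = [], []
    for r, c in zip(rows, cols):
        if iou[r, c] >= iou_threshold:
            pairs.append((r + 1, c + 1))
            ious.append(float(iou[r, c]))
    truth_ids = np.unique(truth.labels)
    n_truth = int((truth_ids > 0).sum())
    return {
        "pairs": pairs,
        "ious": ious,
        "recall": len(pairs) / n_truth if n_truth else 0.0,
    }
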