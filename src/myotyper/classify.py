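"""Trainable pixel classification of myofiber boundaries.

A random-forest pixel classifier in the style of interactive segmentation
tools: per-pixel features are multi-scale Gaussian derivatives (smoothing,
Laplacian, gradient magnitude, difference of Gaussians, structure-tensor
and Hessian eigenvalues) and the classifier is trained from sparse pixel
annotations of two classes, 'myofiber boundary' vs 'not myofiber
boundary'.  Prediction yields the per-pixel boundary probability that
drives the watershed segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import (
    hessian_matrix,
    hessian_matrix_eigvals,
    structure_tensor,
    structure_tensor_eigenvalues,
)
from sklearn.ensemble import RandomForestClassifier

from .core import ProbabilityMap
from .phantom import AnnotationSet

#: Default scales (px): spans laminin boundary widths at ~2.6 um/px.
DEFAULT_SIGMAS = (0.7, 1.0, 1.6, 3.5, 5.0)

FEATURES_PER_SIGMA = 8


@dataclass
class FeatureConfig:
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS

    @property
    def n_features(self) -> int:
        return FEATURES_PER_SIGMA * len(self.sigmas)


def compute_features(
    raster: np.ndarray, sigmas: tuple[float, ...] = DEFAULT_SIGMAS
) -> np.ndarray:
    """H x W x (8 * len(sigmas)) feature stack.

    Per sigma: Gaussian smoothing, Laplacian of Gaussian, Gaussian
    gradient magnitude, difference of Gaussians (sigma vs 0.66 sigma),
    two structure-tensor eigenvalues, two Hessian eigenvalues.
    """
    if len(sigmas) == 0:
        raise ValueError("need at least one sigma")
    if any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be positive")
    img = np.asarray(raster, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("raster must be single-channel 2-D")
    planes: list[np.ndarray] = []
    for s in sigmas:
        smooth = ndi.gaussian_filter(img, s)
        planes.append(smooth)
        planes.append(ndi.gaussian_laplace(img, s))
        planes.append(ndi.gaussian_gradient_magnitude(img, s))
        planes.append(smooth - ndi.gaussian_filter(img, 0.66 * s))
        st = structure_tensor(img, sigma=s, mode="nearest")
        planes.extend(structure_tensor_eigenvalues(st))
        hm = hessian_matrix(img, sigma=s, mode="nearest", use_gaussian_derivatives=False)
        planes.extend(hessian_matrix_eigvals(hm))
    return np.stack(planes, axis=-1)


@dataclass
class BoundaryClassifier:
    """Fitted boundary/not-boundary pixel classifier."""

    feature_config: FeatureConfig
    model: RandomForestClassifier
    train_seed: int
    training_accuracy: float = float("nan")

    @property
    def boundary_class_index(self) -> int:
        return int(np.flatnonzero(self.model.classes_ == "boundary")[0])


def train_classifier(
    raster: np.ndarray | list[np.ndarray],
    annotations: AnnotationSet | list[AnnotationSet],
    feature_config: FeatureConfig | None = None,
    seed: int = 0,
    n_trees: int = 100,
    max_depth: int = 12,
) -> BoundaryClassifier:
    """Fit a decision forest on features at the annotated pixels.

    Accepts a single raster + annotation set or parallel lists of them
    (training across several sections improves generalization).
    Deterministic for a fixed seed.
    """
    feature_config = feature_config or FeatureConfig()
    rasters = raster if isinstance(raster, list) else [raster]
    anns = annotations if isinstance(annotations, list) else [annotations]
    if len(rasters) != len(anns):
        raise ValueError("need one annotation set per raster")
    xs, ys = [], []
    for rast, ann in zip(rasters, anns):
        feats = compute_features(rast, feature_config.sigmas)
        rr, cc = ann.coordinates[:, 0], ann.coordinates[:, 1]
        xs.append(feats[rr, cc])
        ys.append(ann.classes)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"annotations contain a single class {classes.tolist()}")
    if counts.min() < 10:
        raise ValueError("need at least 10 annotations per class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    acc = float(forest.score(x, y))
    return BoundaryClassifier(
        feature_config=feature_config,
        model=forest,
        train_seed=seed,
        training_accuracy=acc,
    )


def predict_probability(
    classifier: BoundaryClassifier, raster: np.ndarray
) -> ProbabilityMap:
    """Per-pixel boundary-class probability in [0, 1]."""
    feats = compute_features(raster, classifier.feature_config.sigmas)
    h, w, f = feats.shape
    if f != classifier.feature_config.n_features:
        raise ValueError(
            f"{f} features computed, classifier expects "
            f"{classifier.feature_config.n_features}"
        )
    proba = classifier.model.predict_proba(feats.reshape(-1, f))
    vals = proba[:, classifier.boundary_class_index].reshape(h, w)
    return ProbabilityMap(values=vals, source="internal_classifier")
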