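"""Data-driven myofiber-type classification.

Fiber types are not imposed as fixed intensity gates.  Instead the three
MyHC mean fluorescence intensities of every surviving fiber are scaled
per sample (uncentered root-mean-square, removing staining-batch gain),
log-transformed, and pooled across samples; Gaussian-kernel mean-shift
clustering then finds the density modes, which are the fiber types
actually present (pure types, hybrids, sometimes a low-intensity
cluster).  Clusters holding under ~2% of fibers are pruned as noise, and
the per-sample composition is the share of assigned fibers in each
retained cluster.

Bandwidth convention: the suggested h range 0.01-0.05 is relative to a
unit data range, so the high-level :func:`cluster_fibers` divides each
log-MFI column by its pooled range before clustering (the convention of
the mean-shift implementation the original analysis used).  The low-level
:func:`mean_shift` itself applies no scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ISOFORMS = ("MyHC1", "MyHC2A", "MyHC2X")
_TYPE_OF_ISOFORM = {"MyHC1": "type1", "MyHC2A": "type2A", "MyHC2X": "type2X"}


@dataclass
class TypingConfig:
    """Mean-shift typing parameters.

    ``bandwidth_h`` is relative to unit data range; 0.01-0.05 is the
    useful span (smaller h, more and smaller clusters).  Clusters below
    ``min_cluster_prop`` of the fibers are pruned.  ``zero_floor`` guards
    the log transform; ``mode_merge_radius`` defaults to h/2 and
    ``converge_tol`` to 1e-6 of the data diameter.
    """

    bandwidth_h: float = 0.03
    min_cluster_prop: float = 0.02
    zero_floor: float = 1e-6
    converge_tol: float | None = None
    max_iter: int = 500
    mode_merge_radius: float | None = None
    hybrid_margin: float = 0.2
    low_intensity_quantile: float = 0.10
    expected_cluster_range: tuple[int, int] = (3, 8)

    def __post_init__(self) -> None:
        if self.bandwidth_h <= 0:
            raise ValueError("bandwidth_h must be positive")
        if not (0 <= self.min_cluster_prop < 1):
            raise ValueError("min_cluster_prop must be in [0, 1)")


@dataclass
class ClusterModel:
    """Mean-shift result on the pooled transformed MFI matrix.

    ``points`` are the log-transformed per-sample-scaled MFI triples;
    ``labels`` are 1-based cluster ids with 0 = pruned/unassigned;
    ``proportions`` are the retained clusters' shares of assigned fibers.
    """

    points: np.ndarray  # (n, 3)
    modes: np.ndarray  # (k, 3), in points space
    labels: np.ndarray  # (n,), 0 = pruned
    proportions: np.ndarray  # (k,)
    sample_ids: np.ndarray  # (n,)
    type_names: list[str] = field(default_factory=list)
    bandwidth_h: float = float("nan")

    @property
    def n_clusters(self) -> int:
        return len(self.proportions)

    @property
    def pruned_fraction(self) -> float:
        """Share of fibers left unassigned by small-cluster pruning."""
        return float((self.labels == 0).mean()) if len(self.labels) else 0.0

    @property
    def cluster_columns(self) -> list[str]:
        """Unique per-cluster column labels, e.g. 'c1_type2A'."""
        if len(self.type_names) == self.n_clusters:
            return [
                f"c{j}_{name}"
                for j, name in enumerate(self.type_names, start=1)
            ]
        return [f"c{j}" for j in range(1, self.n_clusters + 1)]


def scale_per_sample(
    mfi: np.ndarray, sample_of: Sequence[object]
) -> np.ndarray:
    """Divide each isoform column by its per-sample uncentered RMS.

    Removes multiplicative staining/imaging gain differences between
    samples without centering, so zero stays zero and ratios between
    fibers within a sample are preserved.
    """
    x = np.asarray(mfi, dtype=float)
    if x.ndim != 2:
        raise ValueError("mfi must be n x channels")
    if x.min(initial=0) < 0:
        raise ValueError("MFI values must be nonnegative")
    samples = np.asarray(sample_of)
    if len(samples) != len(x):
        raise ValueError("sample_of must parallel mfi rows")
    out = np.empty_like(x)
    for s in pd.unique(samples):
        rows = samples == s
        block = x[rows]
        rms = np.sqrt(np.mean(block**2, axis=0))
        bad = np.flatnonzero(rms == 0)
        if bad.size:
            raise ValueError(
                f"sample {s!r}: channel(s) {bad.tolist()} are all zero, "
                "cannot scale"
            )
        out[rows] = block / rms
    return out


def log_transform(scaled: np.ndarray, zero_floor: float = 1e-6) -> np.ndarray:
    """Natural log with a small floor for zeros."""
    x = np.asarray(scaled, dtype=float)
    if x.min(initial=0) < 0:
        raise ValueError("scaled values must be nonnegative")
    return np.log(np.maximum(x, zero_floor))


def mean_shift(
    points: np.ndarray, cfg: TypingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel mean-shift.

    Every point ascends the kernel density estimate
    x <- sum_i w_i x_i / sum_i w_i with w_i = exp(-||x - x_i||^2 / 2h^2)
    until the step is below ``converge_tol`` or ``max_iter`` is hit;
    converged positions within ``mode_merge_radius`` merge into one mode.

    Returns (modes (k, d), labels (n,) 1-based).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.size == 0:
        raise ValueError("no points")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    n, d = pts.shape
    h = cfg.bandwidth_h
    diam = float(np.linalg.norm(pts.max(0) - pts.min(0)))
    tol = cfg.converge_tol if cfg.converge_tol is not None else 1e-6 * max(diam, 1e-12)
    merge_r = cfg.mode_merge_radius if cfg.mode_merge_radius is not None else h / 2

    x = pts.copy()
    active = np.ones(n, dtype=bool)
    inv = -0.5 / h**2
    for _ in range(cfg.max_iter):
        if not active.any():
            break
        xa = x[active]
        d2 = (
            np.sum(xa**2, axis=1)[:, None]
            + np.sum(pts**2, axis=1)[None, :]
            - 2.0 * xa @ pts.T
        )
        w = np.exp(inv * np.maximum(d2, 0.0))
        new = (w @ pts) / w.sum(axis=1)[:, None]
        step = np.linalg.norm(new - xa, axis=1)
        x[active] = new
        still = step >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    modes: list[np.ndarray] = []
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        assigned = 0
        for m, mode in enumerate(modes):
            if np.linalg.norm(x[i] - mode) <= merge_r:
                assigned = m + 1
                break
        if not assigned:
            modes.append(x[i])
            assigned = len(modes)
        labels[i] = assigned
    return np.asarray(modes), labels


def prune_clusters(
    labels: np.ndarray, min_prop: float = 0.02
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero out clusters holding under ``min_prop`` of the fibers.

    Returns (new labels with pruned fibers = 0, retained original cluster
    ids, renormalized proportions of the retained clusters).
    """
    labels = np.asarray(labels, dtype=int)
    assigned = labels[labels > 0]
    if assigned.size == 0:
        raise ValueError("no assigned fibers")
    ids, counts = np.unique(assigned, return_counts=True)
    props = counts / assigned.size
    keep = ids[props >= min_prop]
    if keep.size == 0:
        raise ValueError(
            f"all {len(ids)} clusters fall below min proportion {min_prop}"
        )
    new = np.zeros_like(labels)
    for newid, old in enumerate(keep, start=1):
        new[labels == old] = newid
    kept_counts = counts[np.isin(ids, keep)]
    return new, keep, kept_counts / kept_counts.sum()


def assign_types(model: ClusterModel, cfg: TypingConfig | None = None) -> list[str]:
    """Name each retained cluster by its dominant MyHC isoform.

    A cluster is a hybrid when its top two isoform means are within
    ``hybrid_margin`` (log units), and 'low-MyHC' when all three means
    fall below the ``low_intensity_quantile`` of the pooled transformed
    values.
    """
    cfg = cfg or TypingConfig()
    if model.n_clusters < 1:
        raise ValueError("no retained clusters")
    low_thr = float(np.quantile(model.points, cfg.low_intensity_quantile))
    names: list[str] = []
    for k in range(1, model.n_clusters + 1):
        member = model.points[model.labels == k]
        means = member.mean(axis=0)
        if np.all(means < low_thr):
            names.append("low-MyHC")
            continue
        order = np.argsort(means)[::-1]
        top, second = order[0], order[1]
        if means[top] - means[second] < cfg.hybrid_margin:
            pair = sorted([ISOFORMS[top], ISOFORMS[second]], key=ISOFORMS.index)
            names.append(
                "hybrid-"
                + "/".join(_TYPE_OF_ISOFORM[i].replace("type", "") for i in pair)
            )
        else:
            names.append(_TYPE_OF_ISOFORM[ISOFORMS[top]])
    model.type_names = names
    return names


def composition(model: ClusterModel) -> pd.DataFrame:
    """Per-sample cluster proportions; rows sum to 1 over assigned fibers.

    Pruned fibers (label 0) are excluded from the denominators.  A sample
    with no assigned fibers gets a NaN row with a warning.
    """
    k = model.n_clusters
    cols = model.cluster_columns
    samples = pd.unique(model.sample_ids)
    out = pd.DataFrame(index=pd.Index(samples, name="sample"), columns=cols, dtype=float)
    for s in samples:
        sel = (model.sample_ids == s) & (model.labels > 0)
        total = int(sel.sum())
        if total == 0:
            warnings.warn(f"sample {s!r} has no assigned fibers", stacklevel=2)
            continue
        for j in range(1, k + 1):
            out.loc[s, cols[j - 1]] = float(
                ((model.labels == j) & sel).sum() / total
            )
    return out


def cluster_fibers(
    mfi: np.ndarray,
    sample_of: Sequence[object],
    cfg: TypingConfig | None = None,
) -> ClusterModel:
    """Full typing chain on raw MyHC MFI triples.

    Per-sample RMS scaling, log transform, per-column division by the
    pooled range (so ``bandwidth_h`` is on the unit-range scale),
    mean-shift, pruning, and type naming.
    """
    cfg = cfg or TypingConfig()
    scaled = scale_per_sample(mfi, sample_of)
    logged = log_transform(scaled, cfg.zero_floor)
    rng_ = logged.max(axis=0) - logged.min(axis=0)
    rng_ = np.where(rng_ > 0, rng_, 1.0)
    unit = logged / rng_
    modes_u, raw_labels = mean_shift(unit, cfg)
    labels, kept, props = prune_clusters(raw_labels, cfg.min_cluster_prop)
    modes = modes_u[kept - 1] * rng_
    model = ClusterModel(
        points=logged,
        modes=modes,
        labels=labels,
        proportions=props,
        sample_ids=np.asarray(sample_of),
        bandwidth_h=cfg.bandwidth_h,
    )
    lo, hi = cfg.expected_cluster_range
    if not (lo <= model.n_clusters <= hi):
        warnings.warn(
            f"{model.n_clusters} retained clusters is outside the "
            f"biologically expected {lo}-{hi} range; consider another h",
            stacklevel=2,
        )
    assign_types(model, cfg)
    return model


def bandwidth_sweep(
    mfi: np.ndarray,
    sample_of: Sequence[object],
    h_values: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05),
    cfg: TypingConfig | None = None,
) -> dict[float, ClusterModel]:
    """Fit the typing chain over a grid of bandwidths."""
    cfg = cfg or TypingConfig()
    out: dict[float, ClusterModel] = {}
    for h in h_values:
        c = TypingConfig(
            bandwidth_h=h,
            min_cluster_prop=cfg.min_cluster_prop,
            zero_floor=cfg.zero_floor,
            converge_tol=cfg.converge_tol,
            max_iter=cfg.max_iter,
            mode_merge_radius=cfg.mode_merge_radius,
            hybrid_margin=cfg.hybrid_margin,
            low_intensity_quantile=cfg.low_intensity_quantile,
            expected_cluster_range=cfg.expected_cluster_range,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[h] = cluster_fibers(mfi, sample_of, c)
        except ValueError:
            # a too-small h can shatter the data so completely that every
            # cluster falls below the pruning threshold; skip that h
            continue
    if not out:
        raise ValueError("no bandwidth in the grid produced a usable fit")
    return out


def choose_bandwidth(
    models: Mapping[float, ClusterModel], max_pruned: float = 0.02
) -> float:
    """Deterministic bandwidth pick from a sweep.

    The smallest h whose retained cluster count lies in the biologically
    expected 3-8 band AND whose pruning discarded at most ``max_pruned``
    of the fibers (a tiny h shatters the data into many small clusters,
    which pruning then masks as a plausible count).  If none qualifies,
    the h minimizing (pruned fraction, distance to the 3-8 band).
    """
    hs = sorted(models)
    for h in hs:
        m = models[h]
        if 3 <= m.n_clusters <= 8 and m.pruned_fraction <= max_pruned:
            return h

    def badness(h: float) -> tuple[float, int, float]:
        m = models[h]
        k = m.n_clusters
        return (m.pruned_fraction, max(3 - k, k - 8, 0), h)

    return min(hs, key=badness)
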