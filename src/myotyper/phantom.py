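"""Synthetic stained-muscle-section phantoms with per-fiber ground truth.

A phantom emulates a transverse muscle cryosection: a quasi-hexagonal
mosaic of myofiber cross-sections (Lloyd-relaxed Voronoi tessellation of an
elliptical tissue region), a laminin channel that is bright on the
inter-fiber boundaries and dim inside, and three MyHC channels whose
per-fiber intensities follow type-specific log-normal distributions.
Hybrid fibers co-express two isoforms (convex mixture of the pure-type
means).  Optional degradations — low-frequency shading, Gaussian noise,
dirt blobs, fold bands, and elongated (longitudinally cut) fibers — give
the downstream mask/filter stages something realistic to reject.

The ground truth (per-fiber type, intensity, CSA, elongation flag, and a
label map of fiber interiors) is what every downstream stage is validated
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.measure import approximate_polygon, find_contours
from skimage.morphology import disk
from skimage.segmentation import find_boundaries

from .core import DEFAULT_CHANNEL_ROLES, ChannelRole, LabelMap, SectionImage, TissueMask

FIBER_TYPES = ("type1", "type2A", "type2X", "hybrid")

#: Per-type mean intensity in the (MyHC1, MyHC2A, MyHC2X/2B) channels,
#: 16-bit scale; a hybrid co-expresses MyHC2A and MyHC2X at half strength.
DEFAULT_TYPE_MEANS: dict[str, tuple[float, float, float]] = {
    "type1": (1900.0, 250.0, 200.0),
    "type2A": (250.0, 3200.0, 300.0),
    "type2X": (220.0, 350.0, 2100.0),
    "hybrid": (235.0, 1775.0, 1200.0),
}


@dataclass
class ArtifactSpec:
    """Counts/sizes of injected non-myofiber structures."""

    n_dirt: int = 0
    dirt_radius_px: int = 6
    n_folds: int = 0
    fold_width_px: int = 10
    n_elongated: int = 0
    elongated_aspect: float = 4.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic section.

    Defaults describe a healthy human leg-muscle section imaged at
    2.6 um/pixel: a mosaic of ~200 fibers with a composition of roughly
    40% type 1, 35% type 2A, 20% type 2X and 5% hybrids, a ~2-px-wide
    bright laminin boundary, and moderate detector noise.
    """

    width: int = 512
    height: int = 512
    pixel_size_um: float = 2.6
    n_fibers: int = 200
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "type1": 0.40,
            "type2A": 0.35,
            "type2X": 0.20,
            "hybrid": 0.05,
        }
    )
    type_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MEANS)
    )
    intensity_sigma_log: float = 0.25  # fiber-to-fiber log-normal spread
    boundary_width_px: int = 2
    boundary_intensity: int = 3000
    laminin_interior: float = 200.0
    background: float = 20.0
    noise_sd: float = 40.0
    shading_amplitude: float = 0.0
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.type_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"type proportions sum to {tot}, not 1")
        if any(v < 0 for v in self.type_proportions.values()):
            raise ValueError("type proportions must be nonnegative")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.boundary_width_px < 1:
            raise ValueError("boundary_width_px must be >= 1")
        if not (0 <= self.shading_amplitude < 1):
            raise ValueError("shading_amplitude must be in [0, 1)")


@dataclass
class PhantomTruth:
    """Ground truth for one phantom.

    ``fibers`` has one row per fiber: fiber_id, centroid_row/col,
    true_type, true per-channel mean (myhc1/myhc2a/myhc2x), csa_um2,
    elongated_flag.  ``polygons`` maps fiber_id to an (k, 2) array of
    (row, col) outline vertices (marching-squares contour of the interior,
    an approximate outline: CSA is defined from the interior pixel count).
    """

    fibers: pd.DataFrame
    polygons: dict[int, np.ndarray]
    fold_polygons: list[np.ndarray] = field(default_factory=list)
    boundary_band: np.ndarray | None = None  # bool H x W


def shading_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Separable-cosine illumination field: 1 + A cos(2*pi*y/H) cos(2*pi*x/W).

    The analytic form makes the max/min ratio (1+A)/(1-A) available as an
    oracle for shading-estimation tests.
    """
    h, w = shape
    yy = np.cos(2 * np.pi * np.arange(h) / h)
    xx = np.cos(2 * np.pi * np.arange(w) / w)
    return 1.0 + amplitude * np.outer(yy, xx)


def _sample_seeds_in_ellipse(
    rng: np.random.Generator, n: int, h: int, w: int
) -> np.ndarray:
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ay, ax = 0.45 * h, 0.45 * w
    pts = []
    while len(pts) < n:
        cand = rng.uniform(0, [h, w], size=(2 * n, 2))
        ok = ((cand[:, 0] - cy) / ay) ** 2 + ((cand[:, 1] - cx) / ax) ** 2 <= 0.95
        pts.extend(cand[ok].tolist())
    return np.asarray(pts[:n])


def _ellipse_mask(h: int, w: int) -> np.ndarray:
    cy, cx = (h - 1) / 2, (w - 1) / 2
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.45 * w)) ** 2 <= 1.0


def _lloyd_relax(
    seeds: np.ndarray, coords: np.ndarray, n_iter: int = 2
) -> np.ndarray:
    """Move each seed to the centroid of its Voronoi cell (restricted to
    the tissue pixel set), n_iter times."""
    for _ in range(n_iter):
        _, owner = cKDTree(seeds).query(coords)
        sums = np.zeros_like(seeds)
        counts = np.bincount(owner, minlength=len(seeds)).astype(float)
        np.add.at(sums, owner, coords)
        nonempty = counts > 0
        seeds = seeds.copy()
        seeds[nonempty] = sums[nonempty] / counts[nonempty, None]
    return seeds


def _assign_cells(
    seeds: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, int],
    aniso: dict[int, tuple[float, float]] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Label each tissue pixel with its nearest seed (1-based).

    ``aniso`` maps seed index -> (aspect, angle); those seeds use an
    anisotropic metric so their cells come out elongated, emulating
    longitudinally cut fibers.
    """
    lab = np.zeros(shape, dtype=np.int32)
    if not aniso:
        _, owner = cKDTree(seeds).query(coords)
        lab[coords[:, 0].astype(int), coords[:, 1].astype(int)] = owner + 1
        return lab
    n = len(seeds)
    mats = np.tile(np.eye(2, dtype=np.float32), (n, 1, 1))
    for i, (aspect, ang) in aniso.items():
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, s], [-s, c]], dtype=np.float32)
        # metric ratio aspect^2: neighbours squeeze the cell, so the
        # realized shape lands near the requested aspect
        scale = np.diag([1.0 / aspect, aspect]).astype(np.float32)
        mats[i] = scale @ rot
    seeds32 = seeds.astype(np.float32)
    chunk = max(1, 2_000_000 // n)
    owner = np.empty(len(coords), dtype=np.int64)
    for start in range(0, len(coords), chunk):
        block = coords[start : start + chunk].astype(np.float32)
        d = block[:, None, :] - seeds32[None, :, :]  # (b, n, 2)
        t = np.einsum("bnj,nij->bni", d, np.transpose(mats, (0, 2, 1)))
        dist2 = np.einsum("bni,bni->bn", t, t)
        owner[start : start + chunk] = np.argmin(dist2, axis=1)
    lab[coords[:, 0].astype(int), coords[:, 1].astype(int)] = owner + 1
    return lab


def _boundary_band(lab: np.ndarray, width_px: int) -> np.ndarray:
    band = find_boundaries(lab, mode="thick")  # ~2 px wide
    extra = width_px - 2
    if extra > 0:
        band = ndi.binary_dilation(band, disk(int(math.ceil(extra / 2))))
    return band


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[SectionImage, LabelMap, TissueMask, PhantomTruth]:
    """Generate one phantom section with ground truth.

    Returns the 4-channel image (MyHC1, MyHC2A, MyHC2X/2B, laminin), the
    truth label map of fiber interiors (boundary band = background), the
    truth tissue mask, and the per-fiber truth table.  Deterministic for a
    fixed spec (including seed).
    """
    h, w, n = spec.height, spec.width, spec.n_fibers
    tissue = _ellipse_mask(h, w)
    if tissue.sum() / n < 9:
        raise ValueError(
            f"{n} fibers in {int(tissue.sum())} tissue pixels: mean fiber "
            "area below 9 px^2"
        )
    rng = np.random.default_rng(spec.seed)
    seeds = _sample_seeds_in_ellipse(rng, n, h, w)
    coords = np.argwhere(tissue).astype(float)
    seeds = _lloyd_relax(seeds, coords, n_iter=2)

    types = rng.choice(
        list(spec.type_proportions), size=n, p=list(spec.type_proportions.values())
    )
    elong_idx: list[int] = []
    aniso: dict[int, tuple[float, float]] = {}
    if spec.artifacts.n_elongated > 0:
        elong_idx = list(
            rng.choice(n, size=min(spec.artifacts.n_elongated, n), replace=False)
        )
        for i in elong_idx:
            aniso[int(i)] = (
                spec.artifacts.elongated_aspect,
                float(rng.uniform(0, np.pi)),
            )
    lab_full = _assign_cells(seeds, coords, (h, w), aniso, rng)

    band = _boundary_band(lab_full, spec.boundary_width_px) & tissue
    truth_lab = np.where(band | ~tissue, 0, lab_full).astype(np.int32)
    # a fiber whose interior vanished entirely keeps one pixel at its seed
    present = np.zeros(n + 1, bool)
    present[np.unique(truth_lab)] = True
    for i in range(1, n + 1):
        if not present[i]:
            cell = np.argwhere(lab_full == i)
            if len(cell):
                r, c = cell[len(cell) // 2]
                truth_lab[r, c] = i

    # per-fiber true mean intensities (log-normal around the type mean)
    means = np.empty((n + 1, 3))
    means[0] = spec.background
    for i in range(n):
        base = np.asarray(spec.type_means[types[i]], dtype=float)
        means[i + 1] = base * np.exp(
            rng.normal(0.0, spec.intensity_sigma_log, size=3)
        )

    channels = [means[lab_full][:, :, j] for j in range(3)]
    laminin = np.full((h, w), spec.laminin_interior, dtype=float)
    laminin[band] = spec.boundary_intensity
    for img in channels:
        img[~tissue] = spec.background
    laminin[~tissue] = spec.background

    fold_polys: list[np.ndarray] = []
    for _ in range(spec.artifacts.n_folds):
        # bright band across the tissue, in every channel
        cy = rng.uniform(0.3 * h, 0.7 * h)
        ang = rng.uniform(0, np.pi)
        length = 0.5 * min(h, w)
        dy, dx = math.sin(ang), math.cos(ang)
        p0 = np.array([cy - length * dy, w / 2 - length * dx])
        p1 = np.array([cy + length * dy, w / 2 + length * dx])
        half = spec.artifacts.fold_width_px / 2
        nvec = np.array([-dx, dy]) * half
        poly = np.array([p0 - nvec, p0 + nvec, p1 + nvec, p1 - nvec])
        fold_polys.append(poly)
        yy, xx = np.mgrid[0:h, 0:w]
        rel = np.stack([yy - cy, xx - w / 2], axis=-1)
        along = rel[..., 0] * dy + rel[..., 1] * dx
        across = rel[..., 0] * -dx + rel[..., 1] * dy
        in_fold = (np.abs(across) <= half) & (np.abs(along) <= length) & tissue
        for img in channels:
            img[in_fold] = spec.boundary_intensity
        laminin[in_fold] = spec.boundary_intensity

    for _ in range(spec.artifacts.n_dirt):
        # small bright blob outside the tissue
        for _try in range(100):
            r = rng.integers(0, h)
            c = rng.integers(0, w)
            if not tissue[r, c]:
                break
        yy, xx = np.mgrid[0:h, 0:w]
        blob = (yy - r) ** 2 + (xx - c) ** 2 <= spec.artifacts.dirt_radius_px**2
        blob &= ~tissue
        laminin[blob] = spec.boundary_intensity
        for img in channels:
            img[blob] = spec.boundary_intensity / 2

    stack = np.stack(channels + [laminin], axis=-1)
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
    if spec.shading_amplitude > 0:
        stack = stack * shading_field((h, w), spec.shading_amplitude)[:, :, None]
    pixels = np.clip(np.round(stack), 0, 0xFFFF).astype(np.uint16)

    image = SectionImage(
        pixels=pixels,
        pixel_size_um=spec.pixel_size_um,
        channel_roles=DEFAULT_CHANNEL_ROLES,
        sample_id=f"phantom-{spec.seed}",
    )

    px2 = spec.pixel_size_um**2
    slices = ndi.find_objects(truth_lab, max_label=n)
    rows = []
    polygons: dict[int, np.ndarray] = {}
    for i in range(1, n + 1):
        sl = slices[i - 1]
        if sl is None:
            continue
        local = truth_lab[sl] == i
        npx = int(local.sum())
        rr, cc = np.nonzero(local)
        cy = rr.mean() + sl[0].start
        cx = cc.mean() + sl[1].start
        padded = np.pad(local, 1).astype(float)
        contours = find_contours(padded, 0.5)
        if contours:
            cont = max(contours, key=len)
            poly = approximate_polygon(cont, tolerance=0.5)
            poly = poly - 1 + np.array([sl[0].start, sl[1].start])
            polygons[i] = poly
        rows.append(
            {
                "fiber_id": i,
                "centroid_row": cy,
                "centroid_col": cx,
                "true_type": str(types[i - 1]),
                "myhc1": means[i, 0],
                "myhc2a": means[i, 1],
                "myhc2x": means[i, 2],
                "csa_um2": npx * px2,
                "elongated_flag": bool(i - 1 in set(map(int, elong_idx))),
            }
        )
    truth = PhantomTruth(
        fibers=pd.DataFrame(rows),
        polygons=polygons,
        fold_polygons=fold_polys,
        boundary_band=band,
    )
    return image, LabelMap(truth_lab.astype(np.int64)), TissueMask(tissue), truth


@dataclass
class AnnotationSet:
    """Sparse pixel annotations for classifier training."""

    coordinates: np.ndarray  # (m, 2) int (row, col)
    classes: np.ndarray  # (m,) str in {"boundary", "not_boundary"}

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        self.classes = np.asarray(self.classes)
        if len(self.coordinates) != len(self.classes):
            raise ValueError("coordinates and classes must be parallel")


def sample_annotations(
    truth_labelmap: LabelMap,
    n_per_class: int,
    seed: int,
    mask: TissueMask | None = None,
) -> AnnotationSet:
    """Draw sparse training annotations from phantom ground truth.

    Boundary-class pixels come from the inter-fiber boundary band (tissue
    pixels with truth label 0); non-boundary pixels from fiber interiors.
    """
    lab = truth_labelmap.labels
    interior = lab > 0
    if mask is not None:
        tissue = mask.mask
    else:
        tissue = ndi.binary_dilation(interior, disk(3))
    band = tissue & ~interior
    rng = np.random.default_rng(seed)
    out_coords, out_classes = [], []
    for cls, pool in (("boundary", band), ("not_boundary", interior)):
        pix = np.argwhere(pool)
        if len(pix) < n_per_class:
            raise ValueError(
                f"only {len(pix)} {cls} pixels available, need {n_per_class}"
            )
        pick = rng.choice(len(pix), size=n_per_class, replace=False)
        out_coords.append(pix[pick])
        out_classes.append(np.full(n_per_class, cls))
    return AnnotationSet(
        coordinates=np.concatenate(out_coords),
        classes=np.concatenate(out_classes),
    )


def degrade(
    image: SectionImage, spec: PhantomSpec
) -> tuple[SectionImage, np.ndarray]:
    """Apply multiplicative cosine shading and additive Gaussian noise.

    Returns the degraded image and the analytic shading field, so that
    shading-estimation tests have an exact oracle.
    """
    if spec.shading_amplitude >= 1:
        raise ValueError("shading amplitude >= 1 would null the signal")
    fld = shading_field(image.shape, spec.shading_amplitude)
    rng = np.random.default_rng(spec.seed + 1)
    out = image.pixels.astype(float) * fld[:, :, None]
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    out = np.clip(np.round(out), 0, 0xFFFF).astype(np.uint16)
    return replace(image, pixels=out), fld


def write_phantom_dataset(
    out_dir,
    spec: PhantomSpec,
    n_samples: int = 1,
    sections_per_sample: int = 1,
    n_annotations: int = 300,
) -> list:
    """Write a ready-to-run phantom dataset into a directory.

    Per (sample, section): the image TIFF (+ metadata sidecar), sparse
    training annotations as JSON, and the ground truth (label map TIFF,
    tissue-mask TIFF, tab-delimited truth table).  Sections of one sample
    use consecutive seeds, so replicates differ but share the model.
    Returns the list of image paths.
    """
    import json as _json
    from dataclasses import replace as _replace
    from pathlib import Path as _Path

    from .io import write_label_map, write_mask, write_multichannel_tiff

    out = _Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    k = 0
    for s in range(n_samples):
        for sec in range(sections_per_sample):
            sp = _replace(spec, seed=spec.seed + k)
            k += 1
            image, truth_lab, tissue, truth = generate_phantom(sp)
            image.sample_id = f"S{s + 1}"
            image.section_index = sec + 1
            name = f"S{s + 1}_sec{sec + 1}_merged"
            p = write_multichannel_tiff(image, out / f"{name}.tif")
            paths.append(p)
            ann = sample_annotations(
                truth_lab, n_annotations, seed=sp.seed + 10_000, mask=tissue
            )
            recs = [
                {"row": int(r), "col": int(c), "class": str(cl)}
                for (r, c), cl in zip(ann.coordinates, ann.classes)
            ]
            (out / f"{name}.annotations.json").write_text(_json.dumps(recs))
            write_label_map(truth_lab, out / f"{name}_truth_labels.tif")
            write_mask(tissue, out / f"{name}_truth_mask.tif")
            truth.fibers.to_csv(
                out / f"{name}_truth.tsv", sep="\t", index=False
            )
    return paths


def sample_fiber_mfis(
    n_fibers: int,
    seed: int,
    type_proportions: dict[str, float] | None = None,
    type_means: dict[str, tuple[float, float, float]] | None = None,
    sigma_log: float = 0.25,
    n_samples: int = 1,
    sample_gain_sd: float = 0.3,
) -> pd.DataFrame:
    """Draw per-fiber MyHC MFI triples directly from the intensity model.

    Bypasses image rendering: used to exercise the typing stage at large n.
    Each sample (section) gets its own multiplicative per-channel gain
    (log-normal, sd ``sample_gain_sd``), emulating staining-batch
    variation that the per-sample scaling step must undo.

    Returns a DataFrame with columns sample, true_type, myhc1, myhc2a,
    myhc2x.
    """
    props = type_proportions or {
        "type1": 0.40,
        "type2A": 0.35,
        "type2X": 0.20,
        "hybrid": 0.05,
    }
    tot = sum(props.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"type proportions sum to {tot}, not 1")
    means = type_means or DEFAULT_TYPE_MEANS
    rng = np.random.default_rng(seed)
    per = [n_fibers // n_samples] * n_samples
    per[-1] += n_fibers - sum(per)
    frames = []
    for s in range(n_samples):
        gain = np.exp(rng.normal(0.0, sample_gain_sd, size=3))
        types = rng.choice(list(props), size=per[s], p=list(props.values()))
        base = np.array([means[t] for t in types], dtype=float)
        vals = base * np.exp(rng.normal(0.0, sigma_log, size=base.shape)) * gain
        frames.append(
            pd.DataFrame(
                {
                    "sample": f"S{s + 1}",
                    "true_type": types,
                    "myhc1": vals[:, 0],
                    "myhc2a": vals[:, 1],
                    "myhc2x": vals[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
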