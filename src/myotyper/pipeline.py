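"""End-to-end orchestration of the myofiber-typing pipeline.

``run_pipeline`` drives one dataset directory through every stage —
downsample, shading correction, tissue mask (+ scripted edits), masked
laminin, pixel classification, watershed segmentation, measurement,
percentile filtering, replicate selection, and mean-shift typing — writing
each stage's suffix-named artifact (``_Mask``, ``_Lamin_Masked``,
``Masked_Probabilities``, ``_Segmentation``, ``_MFI``, ``_Filt``,
``_check4``) plus a JSON run log, and returning the in-memory results.

Input conventions (all plain files beside each image):
- ``<name>.tif``            multichannel section (+ ``.meta.json`` sidecar)
- ``<name>.annotations.json``  sparse training pixels, optional
- ``<name>.maskedits.json``    ordered polygon edits, optional
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import FeatureConfig, predict_probability, train_classifier
from .core import ChannelRole, LabelMap, MFITable, SectionImage
from .fibertype import (
    ClusterModel,
    TypingConfig,
    bandwidth_sweep,
    choose_bandwidth,
    cluster_fibers,
    composition,
)
from .io import (
    read_multichannel_tiff,
    write_label_map,
    write_mask,
    write_mfi_table,
    write_multichannel_tiff,
    write_probability_map,
)
from .mask import (
    MaskParams,
    PolygonEdit,
    apply_mask_edits,
    auto_tissue_mask,
    edge_distance_map,
    masked_laminin,
)
from .measure import MeasureConfig, append_classification_channel, measure_section
from .phantom import AnnotationSet
from .preprocess import (
    ShadingProfile,
    apply_shading_correction,
    downsample_by_averaging,
    estimate_slide_profile,
    median_shading_profile,
)
from .qc import FilterConfig, apply_filters, select_replicate
from .segment import SegmentationParams, filter_labels, segment_fibers


@dataclass
class PipelineConfig:
    """All stage parameters plus bookkeeping for one run.

    Defaults are the published workflow's: 4x downsampling to ~2.6 um/px,
    masked-laminin feathering sigma 4 px, 3-px boundary strip, certainty
    percentiles 5/95, CSA 10/99, circularity 1, at least 100 surviving
    fibers per sample, clusters under 2% pruned.
    """

    input_dir: str = "."
    output_dir: str = "run"
    downsample_factor: int = 4
    shading_correction: bool = True
    mask: MaskParams = field(default_factory=MaskParams)
    masked_laminin_sigma_px: float = 4.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    min_roi_area_px: int = 9
    measure: MeasureConfig = field(default_factory=MeasureConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    typing: TypingConfig = field(default_factory=TypingConfig)
    bandwidth_grid: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
    seed: int = 0

    def config_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        blob = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    run_dir: Path
    tables: dict[str, MFITable]
    flags: pd.DataFrame
    selected_sections: dict[str, object]
    model: ClusterModel | None
    composition: pd.DataFrame | None
    chosen_h: float | None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_annotations(path: Path) -> AnnotationSet | None:
    if not path.exists():
        return None
    data = json.loads(path.read_text())
    coords = np.array([[d["row"], d["col"]] for d in data], dtype=int)
    classes = np.array([d["class"] for d in data])
    return AnnotationSet(coordinates=coords, classes=classes)


def _load_mask_edits(path: Path) -> list[PolygonEdit]:
    if not path.exists():
        return []
    data = json.loads(path.read_text())
    return [
        PolygonEdit(op=d["op"], polygon=np.asarray(d["polygon"], dtype=float))
        for d in data
    ]


def run_pipeline(
    config: PipelineConfig,
    images: dict[str, SectionImage] | None = None,
) -> PipelineResult:
    """Execute the full pipeline on a directory (or in-memory images).

    Any stage failure aborts with the stage name; artifacts written by
    earlier stages are retained for inspection.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    in_dir = Path(config.input_dir)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - rethrown with stage name
                raise StageError(name, e) from e

        return deco

    if images is None:
        paths = sorted(
            p
            for p in in_dir.glob("*.tif*")
            if p.suffix.lower() in (".tif", ".tiff")
            and not any(
                s in p.stem
                for s in (
                    "_Mask",
                    "_Lamin_Masked",
                    "Probabilities",
                    "_Segmentation",
                    "_truth",
                )
            )
        )
        if not paths:
            raise StageError("load", FileNotFoundError(f"no TIFFs in {in_dir}"))
        images = {}
        for p in paths:
            images[p.stem] = stage("load")(lambda p=p: read_multichannel_tiff(p))

    if config.downsample_factor > 1:
        images = {
            k: stage("downsample")(
                lambda im=im: downsample_by_averaging(im, config.downsample_factor)
            )
            for k, im in images.items()
        }

    if config.shading_correction and len(images) >= 1:

        def _shade():
            # one illumination field per run: per-slide laminin estimates,
            # median across slides, divided out of every channel
            nchan = next(iter(images.values())).n_channels
            med = median_shading_profile(
                [estimate_slide_profile(im) for im in images.values()]
            )
            profiles = [
                ShadingProfile(values=med.values, channel_index=c)
                for c in range(nchan)
            ]
            return {
                k: apply_shading_correction(im, profiles)
                for k, im in images.items()
            }

        images = stage("shade")(_shade)

    masks = {}
    for k, im in images.items():
        def _mask(k=k, im=im):
            if not im.has_role(ChannelRole.LAMININ):
                raise ValueError(f"{k}: no laminin channel, cannot build mask")
            m = auto_tissue_mask(im, config.mask)
            edits = _load_mask_edits(in_dir / f"{k}.maskedits.json")
            if edits:
                m = apply_mask_edits(m, edits)
            write_mask(m, out / f"{k}_Mask.tif")
            return m

        masks[k] = stage("mask")(_mask)

    lamins = {}
    for k, im in images.items():
        def _lamin(k=k, im=im):
            lam = masked_laminin(im, masks[k], config.masked_laminin_sigma_px)
            write_multichannel_tiff(
                SectionImage(
                    pixels=lam[:, :, None].astype(np.float32),
                    pixel_size_um=im.pixel_size_um,
                    channel_roles=(ChannelRole.LAMININ,),
                    sample_id=im.sample_id,
                ),
                out / f"{k}_Lamin_Masked.tif",
            )
            return lam

        lamins[k] = stage("masked_laminin")(_lamin)

    def _classify():
        train_rasters, train_anns = [], []
        for k in images:
            ann = _load_annotations(in_dir / f"{k}.annotations.json")
            if ann is not None:
                train_rasters.append(lamins[k])
                train_anns.append(ann)
        if not train_rasters:
            raise ValueError(
                "no .annotations.json beside any input image: cannot train "
                "the boundary classifier"
            )
        clf = train_classifier(
            train_rasters, train_anns, config.features, seed=config.seed
        )
        probs = {}
        for k in images:
            pm = predict_probability(clf, lamins[k])
            write_probability_map(pm, out / f"{k}_Masked_Probabilities.tif")
            probs[k] = pm
        return probs

    probs = stage("classify")(_classify)

    labelmaps: dict[str, LabelMap] = {}
    for k in images:
        def _segment(k=k):
            lm = segment_fibers(probs[k], masks[k], config.segmentation)
            lm = filter_labels(
                lm, config.min_roi_area_px, config.segmentation.border_policy
            )
            write_label_map(lm, out / f"{k}_Segmentation.tif")
            return lm

        labelmaps[k] = stage("segment")(_segment)

    tables: dict[str, MFITable] = {}
    for k, im in images.items():
        def _measure(k=k, im=im):
            dist = edge_distance_map(masks[k], im.pixel_size_um)
            im5 = append_classification_channel(im, probs[k])
            tab = measure_section(
                im5,
                labelmaps[k],
                dist,
                config.measure,
                roi_prefix=f"{im.sample_id}-{im.section_index:04d}-",
            )
            write_mfi_table(tab, out / f"{k}_MFI.txt")
            return tab

        tables[k] = stage("measure")(_measure)

    def _filter():
        pooled_records = []
        roi_image: dict[str, str] = {}
        roi_sample: dict[str, str] = {}
        for k, tab in tables.items():
            for r in tab.records:
                pooled_records.append(r)
            for roi in tab.roi_ids:
                roi_image[roi] = k
                roi_sample[roi] = images[k].sample_id
        pooled = MFITable(
            records=pooled_records,
            n_channels=next(iter(tables.values())).n_channels,
        )
        group_of = (
            roi_sample if config.filters.csa_group_by == "sample" else None
        )
        flags = apply_filters(pooled, config.filters, group_of)
        flags["image"] = [roi_image[r] for r in flags.index]
        flags["sample"] = [roi_sample[r] for r in flags.index]
        for k, tab in tables.items():
            df = tab.to_dataframe()
            sub = flags.loc[[r for r in tab.roi_ids]]
            merged = df.merge(
                sub.drop(columns=["image", "sample"]),
                left_on="roi_id",
                right_index=True,
            )
            merged.drop(columns=["roi_id", "channel"]).to_csv(
                out / f"{k}_Filt.txt", sep="\t", index=False, float_format="%.3f"
            )
            code_of = dict(
                zip(
                    (int(r.rsplit("-", 1)[-1]) for r in sub.index),
                    sub["aggregate_code"],
                )
            )
            overlay = render_overlay(labelmaps[k], code_of)
            _write_png(overlay, out / f"{k}_check4.png")
        return flags

    flags = stage("filter")(_filter)

    def _select():
        by_sample: dict[str, dict[str, int]] = {}
        for k, im in images.items():
            surv = int(
                (flags.loc[flags["image"] == k, "aggregate_code"] == 1.0).sum()
            )
            by_sample.setdefault(im.sample_id, {})[k] = surv
        chosen = {}
        for s, counts in by_sample.items():
            keyed = {
                images[k].section_index: k for k in counts
            }
            sel = select_replicate(
                {images[k].section_index: counts[k] for k in counts},
                config.filters.min_fibers_per_sample,
            )
            chosen[s] = keyed[sel] if sel is not None else None
        return chosen

    selected = stage("select_replicate")(_select)

    def _typing():
        keep_images = [k for k in selected.values() if k is not None]
        if not keep_images:
            return None, None, None
        rows, samples = [], []
        for k in keep_images:
            tab = tables[k]
            surviving = set(
                flags.index[
                    (flags["image"] == k) & (flags["aggregate_code"] == 1.0)
                ]
            )
            mat = tab.channel_matrix([1, 2, 3])
            for roi, triple in zip(tab.roi_ids, mat):
                if roi in surviving:
                    rows.append(triple)
                    samples.append(images[k].sample_id)
        if not rows:
            return None, None, None
        mat = np.asarray(rows)
        if len(config.bandwidth_grid) > 1:
            models = bandwidth_sweep(
                mat, samples, config.bandwidth_grid, config.typing
            )
            h = choose_bandwidth(models)
            model = models[h]
        else:
            h = config.typing.bandwidth_h
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = cluster_fibers(mat, samples, config.typing)
        comp = composition(model)
        comp.to_csv(out / "composition.txt", sep="\t", float_format="%.4f")
        return model, comp, h

    model, comp, chosen_h = stage("typing")(_typing)

    log = {
        "myotyper_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_images": len(images),
        "chosen_bandwidth": chosen_h,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return PipelineResult(
        run_dir=out,
        tables=tables,
        flags=flags,
        selected_sections=selected,
        model=model,
        composition=comp,
        chosen_h=chosen_h,
    )


def _gray_palette(value: float) -> tuple[int, int, int]:
    g = int(round(255 * value))
    return (g, g, g)


def render_overlay(
    labels: LabelMap,
    value_of: dict[int, float],
    palette=None,
) -> np.ndarray:
    """Paint each ROI with palette(value); background black.

    ``value_of`` maps label id to a value in [0, 1] (e.g. the aggregate
    filter code, or a cluster id mapped to [0, 1]).  Unknown labels in the
    map are an error; ROIs absent from the map stay black.
    """
    palette = palette or _gray_palette
    lab = labels.labels
    present = set(labels.ids.tolist())
    unknown = [k for k in value_of if k not in present]
    if unknown:
        raise ValueError(f"value map refers to unknown label(s) {unknown[:5]}")
    bad = [k for k, v in value_of.items() if not (0 <= v <= 1)]
    if bad:
        raise ValueError(f"values outside [0, 1] for label(s) {bad[:5]}")
    out = np.zeros(lab.shape + (3,), dtype=np.uint8)
    lut = np.zeros((int(lab.max()) + 1, 3), dtype=np.uint8)
    for k, v in value_of.items():
        lut[k] = palette(v)
    out = lut[lab]
    return out


def cluster_palette(n_clusters: int):
    """Distinct-color palette for cluster overlays (red, blue, green, ...)."""
    base = [
        (220, 40, 40),
        (50, 80, 220),
        (40, 180, 70),
        (230, 180, 30),
        (160, 60, 200),
        (40, 200, 200),
        (240, 120, 40),
        (130, 130, 130),
    ]

    def pal(value: float) -> tuple[int, int, int]:
        idx = int(round(value * max(n_clusters - 1, 1)))
        return base[idx % len(base)]

    return pal


def _write_png(arr: np.ndarray, path: Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, arr)
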