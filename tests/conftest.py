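"""Shared fixtures: phantoms and derived artifacts, built once per session.

The phantom sizes here (130-500 fibers, 384-768 px) are chosen so the
whole suite exercises every stage end-to-end in a few minutes on one CPU
while keeping enough fibers for the statistical assertions to be stable.
"""

from __future__ import annotations

import numpy as np
import pytest

from myotyper.classify import predict_probability, train_classifier
from myotyper.mask import auto_tissue_mask, edge_distance_map, masked_laminin
from myotyper.measure import append_classification_channel, measure_section
from myotyper.phantom import (
    ArtifactSpec,
    PhantomSpec,
    generate_phantom,
    sample_annotations,
    sample_fiber_mfis,
)
from myotyper.segment import filter_labels, match_to_truth, segment_fibers

THREE_TYPE_PROPS = {"type1": 0.6, "type2A": 0.3, "type2X": 0.1}


@pytest.fixture(scope="session")
def phantom_bundle():
    """A mid-size phantom with a few elongated (longitudinal) fibers."""
    spec = PhantomSpec(
        width=384,
        height=384,
        n_fibers=130,
        artifacts=ArtifactSpec(n_elongated=6),
        seed=11,
    )
    image, truth_labels, tissue, truth = generate_phantom(spec)
    return {
        "spec": spec,
        "image": image,
        "truth_labels": truth_labels,
        "tissue": tissue,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def seg_bundle(phantom_bundle):
    """Mask -> masked laminin -> classifier -> probability -> labels."""
    b = phantom_bundle
    mask = auto_tissue_mask(b["image"])
    lam = masked_laminin(b["image"], mask)
    ann = sample_annotations(b["truth_labels"], 200, seed=2, mask=b["tissue"])
    clf = train_classifier(lam, ann, seed=0)
    prob = predict_probability(clf, lam)
    labels = filter_labels(segment_fibers(prob, mask), 9, "keep")
    match = match_to_truth(labels, b["truth_labels"], 0.7)
    return {
        "mask": mask,
        "lam": lam,
        "annotations": ann,
        "classifier": clf,
        "prob": prob,
        "labels": labels,
        "match": match,
    }


@pytest.fixture(scope="session")
def measured(phantom_bundle, seg_bundle):
    """Full 5-channel measurement table for the session phantom."""
    im5 = append_classification_channel(
        phantom_bundle["image"], seg_bundle["prob"]
    )
    dist = edge_distance_map(
        seg_bundle["mask"], phantom_bundle["image"].pixel_size_um
    )
    table = measure_section(im5, seg_bundle["labels"], dist)
    return {"table": table, "im5": im5, "distmap": dist}


@pytest.fixture(scope="session")
def mfi_df():
    """2000 fibers with a 0.6/0.3/0.1 three-type mixture over 4 samples."""
    return sample_fiber_mfis(
        2000,
        seed=7,
        type_proportions=THREE_TYPE_PROPS,
        n_samples=4,
    )


@pytest.fixture(scope="session")
def sweep_models(mfi_df):
    from myotyper.fibertype import bandwidth_sweep

    mat = mfi_df[["myhc1", "myhc2a", "myhc2x"]].to_numpy()
    return bandwidth_sweep(mat, mfi_df["sample"].to_numpy())


def rng_image(shape, seed, high=4096):
    rng = np.random.default_rng(seed)
    return rng.integers(0, high, size=shape).astype(np.uint16)
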