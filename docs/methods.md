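# Methods

This note records the models and procedures `myotyper` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what phantom-based validation does and does not
establish. No number here is asserted that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement model

A stained transverse muscle section is a mosaic of fiber cross-sections
outlined by laminin. Fiber identity is carried by the mean fluorescence
intensity (MFI) of three MyHC isoform channels inside each fiber; the
laminin channel carries geometry only. The pipeline's job is therefore
(i) to delineate fiber interiors accurately enough that interior MFIs
are uncontaminated by the boundary, (ii) to reject ROIs that are not
single transversely-cut fibers, and (iii) to classify the surviving
fibers by their MFI triples without imposing fixed intensity gates.

## Preprocessing

**Downsampling.** Block averaging by an integer factor (default 4);
trailing partial blocks are averaged over the pixels they contain rather
than dropped, preserving tissue at image edges. The working pixel size
should land in 1–5 µm (a warning is raised otherwise); 2.6 µm is the
reference scale for the default feature and boundary widths. Averaged
pixels are carried as floats in memory; integer 16-bit applies on disk.

**Shading correction.** Whole-slide scans carry a smooth multiplicative
illumination field. The estimator is retrospective: heavy Gaussian
smoothing of the laminin channel — a *normalized convolution* restricted
to a coarse tissue foreground, so the tissue outline itself is not
mistaken for shading — normalized to mean 1 and floored at 0.05; the
per-pixel median across slides suppresses slide-specific structure; the
resulting field is divided out of every channel.

Two design points deserve emphasis. First, the field is estimated from
the *laminin* channel and shared across channels: laminin's large-scale
intensity is spatially stationary (every fiber has a boundary), whereas
the MyHC channels are patchy (fiber types cluster spatially), and a
self-estimated per-channel profile on a patchy channel absorbs type
patchiness into the "illumination" and corrupts the intensities that
typing later depends on. This sacrifices any genuinely per-channel
shading component; users with per-channel flat-field references can
apply `estimate_shading_profile`/`apply_shading_correction` per channel
instead. Second, the smoothing scale defaults to min(H, W)/12: a
Gaussian of scale σ attenuates a sinusoidal field of period T by
exp(−2π²σ²/T²), so min/8 would suppress an image-period field by ~27%
and cap the achievable correction, while min/12 keeps attenuation under
~15% and remains well above the fiber scale.

On phantoms degraded with a known amplitude-0.3 cosine field, this
estimator removes ≈60% of the illumination component of per-tile mean
variation (measured on the degraded/clean ratio — raw tile means are
dominated by genuine fiber-to-fiber variation, which correction must not
touch). That validates the machinery, not the estimator's adequacy for
any particular scanner: real shading is tile-structured rather than a
single smooth cosine, and acquisition-side references remain preferable
when available.

## Tissue mask and masked laminin

Automatic mask: Gaussian blur (σ = 10 px) of laminin, Otsu threshold,
hole filling, removal of objects < 2000 px², and of components smaller
than 10% of the largest. Artifact cleanup (folds, scratches, dirt,
out-of-focus regions) is a scripted, ordered list of polygon add/remove
edits stored beside the image — an auditable replacement for interactive
mask painting, which is the workflow's main manual bottleneck. Polygons
cover a pixel when its center lies inside.

The laminin channel used for classification is feathered: the binary
mask is blurred (σ = 4 px, tunable when it blurs detail) into a weight
m, and the output is m·laminin + (1−m)·median(laminin outside the mask).
More than ~4σ inside the tissue this is exactly the laminin channel;
more than ~4σ outside it is exactly the background median.

The distance-to-edge map is the Euclidean distance transform of the mask
(image frame counted as background via a 1-px virtual border), in µm; it
feeds the Mean_distance column used to flag edge artifacts.

## Boundary classification

An Ilastik-style trainable pixel classifier, implemented as a random
forest (100 trees, depth ≤ 12, fixed seed) over 8 features per scale:
Gaussian smoothing, Laplacian of Gaussian, gradient magnitude,
difference of Gaussians (σ vs 0.66σ), and the eigenvalue pairs of the
structure tensor and Hessian. Default scales {0.7, 1.0, 1.6, 3.5, 5.0}px
span laminin line widths at 2.6 µm/px. Training needs ≥ 10 annotations
per class; annotating across several sections (the API accepts lists)
guards against overfitting one section's staining. Externally produced
probability maps (e.g. from Ilastik itself) are accepted through
`read_probability_map`, which auto-normalizes 0–255 exports.

## Segmentation

Seeded watershed on the smoothed (σ = 1 px) probability surface:
boundary mask = smoothed probability ≥ 0.5; seed region = tissue ∧
¬boundary, **eroded by 2 px**, 4-connected components ≥ 9 px; watershed
restricted to tissue; ridge pixels reset to background so ROI interiors
exclude the laminin line (this exclusion is what makes the channel-5
interior-vs-strip contrast a usable certainty score). The erosion exists
because a few-pixel-wide leak through the thresholded boundary otherwise
chains two fibers into one seed — the watershed immediately regrows the
eroded margin, so interiors are unaffected. Watershed ties
follow scikit-image's deterministic flooding order; the whole stage is
deterministic. Frame-touching ROIs are removed by default (`exclude`
border policy) since their shape statistics are truncated.

On 130–500-fiber phantoms at default parameters, ≥ 90% of truth fibers
are recovered one-to-one at IoU ≥ 0.7 (Hungarian matching), with mean
matched IoU ≈ 0.98.

## Measurement

Per ROI and channel: area = pixel count × pixel size² (µm²); mean, SD,
mode (of the rounded-integer histogram, ties to the smallest value),
min, max, median over interior pixels; circularity = 4πA/P² capped at 1,
with P the corner-corrected Crofton perimeter estimate (a rasterized
disk scores ≈ 1, a 40×4 px rectangle ≈ 0.3); Mean_boundary/
StdDev_boundary over a strip = Euclidean dilation of the ROI by 3 px
minus the ROI (an *outer* band — by the segmentation contract the
laminin line lies just outside the interior); Mean_distance = mean of
the edge-distance map over interior pixels. The probability map enters
as channel 5 on a 0–255 scale. Labels are `<roi>:<channel>`; area,
circularity and Mean_distance repeat identically on all channel rows of
one ROI, matching the export convention of the original workflow.

## Quality filtering

Three filters, each with cuts computed on the **full pooled ROI set**
(so results are independent of evaluation order):

- *Segmentation certainty*: two-sided percentile cuts (default 5/95) on
  channel-5 Mean and Mean_boundary; StdDev_boundary is available but
  inactive by default, and configurable as upper-tail-only, since for
  that metric only large values indicate trouble.
- *CSA*: default 10th/99th percentiles, optionally per sample group when
  CSA distributions differ between groups (a deliberate trade-off: group-
  wise cuts preserve biological differences but can introduce bias).
- *Circularity*: keep ROIs strictly above the pooled 1st percentile.

Percentiles are linear-interpolation (type 7). Pass means strictly
inside the cuts; in the degenerate all-ties case nothing is excluded.
Aggregate codes for overlays: 0 failed certainty, 0.4 survived only
certainty, 0.7 survived certainty+CSA, 1 survived all.

Percentile filters remove fixed fractions by construction, so the
defaults encode one dataset's tuning, not a universal truth. The
artifact-discrimination test tunes the circularity cut to the phantom's
known ~5% elongated-fiber content (on real data the analogous choice is
made from the density plots, where elongated fibers form a visible low
mode); with that tuning ≥ 80% of elongated fibers are flagged while
≤ 10% of true fibers are lost.

Replicate selection keeps, per sample, the section with the most
surviving fibers (ties to the lowest section index) and drops samples
whose best section has fewer than 100.

## Typing by mean-shift clustering

Let x_i ∈ R³ be fiber i's (MyHC1, MyHC2A, MyHC2X) MFIs. Within each
sample, each column is divided by its uncentered RMS — removing
staining/imaging gain without centering, so zero intensity stays zero —
then ln(max(x, ε)) with ε = 1e-6. Samples are pooled *after* scaling so
clusters are defined jointly and compositions are comparable across
samples.

`mean_shift` is Gaussian-kernel mean-shift: every point ascends
x ← Σᵢ wᵢxᵢ/Σᵢwᵢ, wᵢ = exp(−‖x−xᵢ‖²/2h²), until the step is below
1e-6 × data diameter (max 500 iterations); converged positions within
h/2 merge into one mode. The bandwidth range h ∈ [0.01, 0.05] is
meaningful on a unit data range, so `cluster_fibers` divides each log
column by its pooled range before clustering (the convention of the
mean-shift implementation used in the original analysis environment).
Clusters holding < 2% of fibers are pruned (label 0) and excluded from
composition denominators. 3–8 retained clusters is the biologically
expected band; counts outside it warn but do not error.

Bandwidth choice is a dataset decision; `choose_bandwidth` implements a
deterministic default — the smallest h in the sweep whose retained count
falls in 3–8 *and* whose pruning discarded ≤ 2% of fibers. The pruning
guard matters: a too-small h shatters the data into hundreds of
micro-clusters, and after pruning the survivor count can masquerade as a
plausible 3.

Cluster naming: dominant isoform of the cluster mean in log space;
'hybrid' when the top two isoform means are within 0.2 log units;
'low-MyHC' when all three means fall below the pooled 10% quantile.
Both margins are config-exposed conventions, not published constants.

On a 2000-fiber synthetic 0.6/0.3/0.1 three-type mixture spread over 4
samples with random per-sample gains, some h in the 0.01–0.05 grid
yields exactly 3 retained clusters with < 2% pruning, adjusted Rand
index ≥ 0.9 against truth, and composition recovered within ±0.05.

## The phantom generator

Phantoms emulate: a quasi-hexagonal fiber mosaic (Lloyd-relaxed Voronoi,
2 iterations, inside an elliptical tissue region), a bright laminin
boundary band (~2 px at the 2.6 µm reference scale, intensity 3000 of
65535), type-dependent log-normal fiber intensities (fiber-level spread
0.25 log units; means per type roughly matching observed 16-bit scales,
hybrids = 0.5/0.5 mixtures of 2A and 2X), per-sample staining gains
(log-normal, sd 0.3), Gaussian detector noise (sd 40), cosine shading,
and artifacts: elongated fibers (anisotropic Voronoi metric, aspect ≥ 4,
emulating longitudinal cuts), fold bands, dirt blobs. Default
composition 0.40/0.35/0.20/0.05 (type1/2A/2X/hybrid), in the range
reported for healthy human leg muscles.

Phantoms do *not* model: point-spread blur, spectral bleed-through,
autofluorescence, intensity gradients within fibers, freezing artifacts,
or realistic tile-structured scanner shading. Passing phantom tests
therefore demonstrates the pipeline's correctness under its stated model
— boundaries bright and thin, types separable in log-MFI space — not its
robustness to every real-world staining pathology; the filter and
bandwidth defaults still require per-dataset tuning on real data.

Ground truth: the truth label map contains fiber *interiors* (boundary
band = background), matching the segmentation contract. Truth CSA is
interior pixel count × pixel size²; stored outline polygons are
marching-squares contours whose area agrees with CSA to ~2% (they are a
visualization aid, not the CSA definition).

## Numerical conventions

- Percentiles: linear interpolation (type 7) throughout.
- Strict inequalities at filter cuts; all-ties degeneracy excludes
  nothing.
- Mode of a float channel: histogram of rounded integers, ties to the
  smallest.
- Watershed: 4-connectivity for seeds and flooding.
- Classification channel: round-half-up of 255 × probability.
- All stochastic steps (phantom generation, annotation sampling, forest
  training) take explicit seeds; fixed seeds give bit-identical outputs.

## Problem sizes used in validation

The test suite and acceptance script run phantoms of 130–500 fibers at
384–768 px and typing mixtures of 2000 fibers — sizes at which the
statistical assertions (recall, ARI, composition error) are stable while
the full suite completes in minutes on a single CPU. The published
workflows this design follows operate on sections of thousands of fibers
and datasets of hundreds of thousands of ROIs; nothing in the
implementation is specific to the smaller scale.
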