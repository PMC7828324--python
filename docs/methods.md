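# Methods

`leukomorph` implements a label-free white-blood-cell (WBC) image-analysis
pipeline for bright-field microscopy: single-cell segmentation, dataset
balancing by geometric augmentation, morphological scoring of neutrophil
activation state, and a classifier-evaluation suite. Because clinical
bright-field WBC images are rarely shareable, the package ships a seeded
synthetic scene generator that plants cells with known geometry, so every
stage can be validated against ground truth.

## Segmentation

Frames are 8-bit single-channel rasters. The threshold is Otsu's: for every
candidate gray level t in 0..254 the histogram is split into a low class
(levels ≤ t; proportion ω₁, mean μ₁) and a high class (ω₂, μ₂), and the
threshold g maximizes the between-class variance ω₁·ω₂·(μ₁−μ₂)². Ties break
toward the lowest gray level; a constant image raises a degenerate-input
error. The implementation is an exact vectorized argmax over all 255
candidates, property-tested against an exhaustive loop.

Foreground polarity is a flag (default: cells darker than background, the
usual bright-field appearance). The binary mask is refined by morphological
opening then closing (3×3 square element, one iteration each, configurable)
— opening removes speckle, closing seals small gaps.

Contours are extracted per 8-connected component by Moore-neighbour
boundary tracing. Area is the component pixel count; perimeter is the chain
length with diagonal steps weighted √2, so an axis-aligned w×h rectangle
measures 2(w−1)+2(h−1) and a digital disk's circularity lands near 0.93
(chain codes slightly overestimate smooth perimeters; the decision
thresholds below absorb that bias). Thin structures are traversed on both
walls and therefore double-counted, as a polygonal boundary should.

Screening rejects, in order: contours whose bounding box comes within
`edge_margin` (default 2 px) of the frame border; contours outside
[`min_area`, `max_area`] (defaults 200 / 20 000 px² at high magnification);
and suspected adhesions — `area > max_area` or solidity (area / convex hull
pixel count) below `solidity_min` (default 0.85). Survivors become square
crops, side = max bbox side + 2×10 px margin, centered on the centroid and
clamped to the frame.

**Limitation worth knowing:** two equal-size overlapping disks never drop
below solidity ≈ 0.88 (tangent equal circles are the floor), so the
solidity arm alone cannot catch same-size adhered pairs. The practical
catch is the area ceiling set per dataset just above the largest plausible
single cell: merged pairs are ~1.9× that. For granulocyte-only synthetic
scenes the package uses `max_area = 3450` px² (largest single disk ≈ 3.2 k,
smallest merged pair ≈ 3.7 k over 30 generator seeds). Watershed splitting
of adhered cells is deliberately out of scope — adhered blobs are
discarded, not rescued.

## Augmentation

Only rotation and flipping are used; photometric edits would distort cell
texture. `plan_balance` assigns each source crop k = ⌈target/n⌉ distinct
(angle, flip) transforms from a fixed grid — default 24 angles (15°
spacing) × flips {none, horizontal} = 48 transforms; vertical flips are
excluded from the default grid because on square crops vflip ≡ hflip ∘
rot180. Per-class output totals are exactly k·n ∈ [target, target + n);
e.g. 211 sources at target 10 000 give 48 × 211 = 10 128.

Arbitrary-angle rotation leaves out-of-support corners. A centered s×s
window avoids them whenever the rotated source side is ≥ s·√2, so sources
are bilinearly enlarged first (factor ≥ √2). Because bilinear resampling
blends with the fill value within one pixel of the support edge, the
effective factor is max(√2, (s+3)·√2 / min_dim) — a ~1.5 % guard over the
geometric minimum that makes outputs strictly fill-free (property-tested
over random angles). Right-angle rotations and flips are exact array
operations and skip enlargement entirely, so identity entries reproduce
the centered crop bit-for-bit. All outputs are 200×200.

## Activation scoring

Activation is called from two shape descriptors of the cell footprint:

- aspect ratio = x/y, the long/short side of the minimum-area rotated
  bounding rectangle (rotating calipers over the convex hull of the
  boundary pixels; +1 px per side for the pixel footprint, making a
  diameter-d disk measure ≈ d). Rotation-invariant by construction.
- roundness = 4π·area / perimeter², with the segmentation module's area
  and chain-perimeter conventions (1 for an ideal circle, π/4 ≈ 0.785 for
  an ideal square, 2π/9 ≈ 0.698 for a 2:1 rectangle).

The footprint comes from gradient-magnitude filtering: the crop is
correlated with the 3×3 horizontal/vertical difference kernels
K1 = [[−1,−1,−1],[0,0,0],[1,1,1]] and K2 = [[−1,0,1],[−1,0,1],[−1,0,1]]
(edge replication at borders), combined as the Euclidean magnitude
√(G1²+G2²) — the standard merge for orthogonal difference kernels — and
rescaled to 0..255. Otsu thresholding of the magnitude keeps the bright
edge ring; closing (radius 2) seals it, hole-filling solidifies it, and a
one-pixel erosion removes the ring's outward bias (without it, footprints
inflate ~1.5 px per side and a 2:1 ellipse measures ≈ 1.89 instead of
≈ 1.96). The largest remaining component (≥ 20 px) is the cell; anything
less raises a measurement failure that batch scoring counts as
"undetected" rather than silently dropping — mirroring real pipelines
where a fraction of crops yields no usable contour.

Decision rule (strict inequalities): **activated** iff aspect ratio > 1.2,
or aspect ratio ≤ 1.2 and roundness < 0.76; otherwise **inactivated**. Low
roundness as the activated signature is the direction consistent with
reference worked measurements (round inactivated cells score ~0.86–0.89,
elongated activated ones ~0.64–0.67); the opposite literal reading is
selectable via `roundness_rule="high_is_activated"` for comparison.

Since upstream classification labels granulocytes (neutrophils ~94–95 %,
eosinophils ~5 %, basophils ~1 %), raw counts are corrected to neutrophils
by multiplying with `neutrophil_fraction` and flooring; the default 0.95 +
floor maps (365, 1328) to (346, 1261). The literal 1 %+5 % complement 0.94
is selectable. Conservation — activated + inactivated + undetected = total
— holds for every batch by construction.

## Evaluation

Standard one-vs-rest definitions from the k×k confusion matrix (rows =
truth): Recall = TP/(TP+FN), Precision = TP/(TP+FP), F1 = 2PR/(P+R),
Accuracy = trace/total. Zero-denominator metrics are reported as NaN, and
macro averages are taken over the defined entries only — silent zeros
would corrupt the averages. The 95 % CI over a set of accuracy samples
(e.g. periodic evaluation checkpoints) is μ̂ ± 1.96·σ/√n with σ the n−1
sample standard deviation. ROC sweeps descending score thresholds (ties
grouped), TPR = TP/(TP+FN), FPR = FP/(FP+TN), AUC by trapezoid;
multi-class reduction is one-vs-rest with macro-averaged AUC. The AUC is
cross-checked in tests against the pairwise Mann–Whitney statistic.

The bundled `ShapeFeatureClassifier` (nearest centroid on standardized
area, perimeter, aspect ratio, roundness, mean intensity, intensity SD;
scores = normalized inverse distances) exists to exercise the evaluation
harness end to end on synthetic data. It makes no claim of matching a deep
network's accuracy on real micrographs.

## Synthetic data: what it emulates, and what it does not

`render_scene` emulates RBC-depleted bright-field frames: background
N(200, 5²), cell footprints N(mean≈120, 8²), whole-frame Gaussian blur
σ = 1 px for defocus, quantized to 8 bits. Default study conditions
(chosen once; all configurable): 512×512 frames, ~8 cells per frame dealt
round-robin so large cells spread evenly; granulocyte disks 48–64 px
diameter, activated granulocytes rendered as gently S-curved capsule
chains with 3:1 elongation, lymphocyte disks 28–40 px, monocyte ellipses
72–92 px with 1.05–1.15 ellipticity. Ground truth records per-cell class,
activation, bbox, edge contact (footprint touches border) and adhesion
groups (union-find over pairwise footprint overlaps). Identical (spec,
seed) renders bit-identical frames; all randomness flows from one
`numpy.random.Generator` per call.

Real bright-field WBC images differ in ways the generator does not model:
no optical point-spread function, halo or vignetting; no intracellular
structure (nucleus lobes, granules); no residual RBCs or debris; contrast
is configurable rather than calibrated to any instrument, since no
intensity statistics for real 100× frames were available. Passing tests
therefore demonstrate that the algorithms are correct and internally
consistent — planted parameters are recovered, screening rules fire on the
situations they target — not that the specific thresholds (1.2, 0.76, area
bounds) transfer unchanged to any particular microscope.

## Numerical choices and degenerate inputs

- Coordinates 0-based row-major; bboxes half-open.
- Otsu ties break toward the lowest gray level; constant images error.
- Single-pixel components: contour of one vertex, perimeter 1.0 by
  convention (screened out by `min_area` in practice).
- Min-area rectangle falls back to axis-aligned extents for collinear or
  <3-point inputs.
- Measurement failures raise typed errors at the unit level and are
  tallied per batch at the pipeline level.
- Problem sizes in the bundled checks (200-cell recovery runs, 100-image
  oracle sweeps, 22-angle augmentation sweeps) are the package's chosen
  desk-scale defaults; every one of them regenerates its inputs from the
  seed at run time.
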