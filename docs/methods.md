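# Methods

This note documents the models, parameter choices and numerical
conventions behind `plantarseg`, and what the synthetic benchmark does
and does not demonstrate.

## Coordinate and box conventions

Images use matrix convention: origin top-left, x rightward (column),
y downward (row).  All boxes are half-open integer rectangles
`[x, x+w) × [y, y+h)`, so areas, intersections and unions are exact
pixel counts and IoU is computed without floating-point geometry.  A
contour is an ordered closed sequence of pixel-centre lattice points;
because points sit at pixel centres, the shoelace area of a traced
contour underestimates the filled pixel count by up to about half the
perimeter — the area-oracle tests use exactly that bound.

## Segmentation backends

**Thresholding.**  The global rule is `dst = max_val` where
`src > thresh` (strict, so a pixel equal to the threshold stays
background) with defaults thresh = 127, max_val = 255.  Otsu's variant
maximises between-class variance over the 256-bin histogram and refuses
constant images; ties resolve to the smallest threshold.  The adaptive
variant thresholds each pixel at its local block mean (odd block,
default 31) minus an offset C (default 2), with reflect padding at the
borders.

**Region split-and-merge.**  The image is zero-padded to the next
power-of-two square so each split yields four equal quadrants, and split
until a region's intensity range (max − min) is at most
`homogeneity_tol` (default 16) or the block side reaches `min_region`
(default 16).  The merge phase joins 4-adjacent regions whose combined
range still satisfies the same criterion, processing candidate pairs
FIFO in region-creation order through a union-find structure; this runs
in near-linear time and terminates at a merge fixpoint (no two adjacent
surviving regions are jointly homogeneous), which the property tests
assert directly.  A pixel is marked foreground when its final region's
*mean* intensity lies strictly inside `(min_thresh, max_thresh)`
(default (50, 100)) — the band isolates transitional regions between
background and loaded sole.  Range homogeneity and the mean-intensity
band test are both interpretation choices: order-independent, simple and
testable.

**Canny.**  Five stages, all from first principles: (1) separable
Gaussian smoothing (default ksize 5, σ 0.6 — light smoothing suited to
scanner composites that are already averaged over many frames, and it
preserves enough step gradient for high double thresholds to remain
reachable on 8-bit input); (2) 3×3 Sobel gradients with reflect
padding and unnormalised L2 magnitude, so magnitudes exceed 255 and
double thresholds like (300, 600) are meaningful; (3) non-maximum
suppression with the gradient direction quantised to four bins and
lattice neighbours (no sub-pixel interpolation), keeping pixels whose
magnitude is ≥ both neighbours along the direction; (4) double
thresholding into strong (≥ max_val) and weak (≥ min_val); (5)
hysteresis keeping the weak pixels whose 8-connected component contains
a strong pixel.  Raising max_val can only remove edges (monotonicity),
and every surviving pixel is ≥ min_val and connected to a strong seed —
both are asserted as properties.  Presets: (100, 200) fine detail,
(200, 300) intermediate, (300, 600) outer contour only; the last is the
pipeline default because the geometric partition needs exactly the outer
foot boundary.

## Contours and foot assignment

Outer borders of 8-connected foreground components are traced with a
border-following walk (clockwise first-neighbour search from the
raster-first pixel, then counterclockwise scans; termination when the
walk is back at the start about to repeat its first move).  Inner
borders (holes) are deliberately ignored.  Contours with shoelace area
strictly greater than `min_area` (default 6000 px²) survive; on 700 px
images this removes toe blobs and sensor specks while keeping sole
regions, which is also how toe exclusion is realised — no separate toe
threshold exists.  Each surviving contour's bounding box goes to the
left foot iff its x is strictly below the image midline; a box
straddling the midline is assigned left and logged.

## Geometric partition

Foot length is the inclusive y-extent of the side's filtered contour
points.  Band lengths floor the 30%/30% forefoot/midfoot shares and give
the heel the remainder, so the three bands always sum to the foot length
(checked exhaustively for lengths 4–2000); lengths below 4 px would
leave an empty band and are refused.  Per-band x-extents come from the
contour points inside the band's half-open y-interval; an empty band
raises an error naming the band, and such feet are recorded as failures
rather than silently mis-partitioned.  The forefoot splits at
`minF_x + (maxF_x − minF_x) // 2`, lateral half = outer forefoot.  The
right foot uses the exact mirror of this construction — its split sits
at `maxF_x + 1 − (maxF_x − minF_x) // 2` — so mirroring an image
mirrors the partition exactly; with a naive floor midpoint on both
sides the two feet would disagree by one pixel whenever the forefoot
spans an even number of columns.

The arch index cuts the toe-excluded footprint into equal y-thirds
(boundaries rounded to the lattice) and takes the middle third's share
of the filled area — filled foreground pixels, not contour points,
since AI is an area ratio; the CLI fills the edge map before computing
it.  Categories: ≤ 0.21 high arch, < 0.26 normal, else flat.  On a
uniform rectangle the index is 1/3 up to a quantisation error of at most
2/length.

## Evaluation protocol

IoU is computed on axis-aligned boxes, matching bounding-box ground
truth.  The detector emits at most one box per (side, region) per image,
so AP reduces to: at each IoU threshold in the default sweep
0.50:0.05:0.95, the fraction of instances whose prediction reaches that
threshold (missed feet count in the denominator); AP averages over the
sweep and mAP over the eight side × region cells.  Whether a published
mAP used one threshold or a sweep is often unstated; the sweep is the
default here, a single-threshold override exists, and reports carry the
protocol used.  Aggregate scores use a two-step mean — normal-group and
abnormal-group means first, then their unweighted mean — which
deliberately differs from the pooled mean when groups are unbalanced;
pooled means are also emitted for transparency.  Feet the pipeline fails
on enter their cells as IoU 0.  Performance bands: poor < 0.6 ≤ good
< 0.90 ≤ excellent.

## Synthetic footprint generator

The generator stands in for a clinical dataset; it emulates morphology,
not biomechanics.  A sole is composed of a forefoot ellipse, a heel
ellipse and a midfoot band whose medial cut is controlled by
`midfoot_contact` — the share of the foot's width in contact through the
arch: defaults 0.5 (normal, "about half contact"), 0.9 (low arch,
near-complete), 0.1 (high arch, minimal).  Heel-tilt types shift the
heel ellipse 10% of foot width medially (inward) or laterally (outward)
and alter the toes (inward drops the hallux; outward keeps only the
hallux).  Toes are detached blobs and therefore excluded from the
partition by the area filter, exactly as in the pipeline.  Concave
pad/band junctions are rounded by a 5 px morphological closing, since
real contact outlines have no re-entrant corners.  Feet default to
420 px length on a 700×700 grid (an adult foot on a 42 cm plate), jittered
per sample in datasets.

The pressure field mimics a piezoresistive contact scan: a sharp onset
to a 120-count rim level, high-load cores (235) under the heel and
metatarsals whose ellipses touch the contact rim at the rear of the heel
and the front of the forefoot, a moderate lateral arch core (165), and
clipped Gaussian sensor noise (sd 2, low because the device output is a
many-frame composite).  Ground-truth boxes apply the package's own
partition rule to the true noise-free sole mask, so evaluation measures
recovery of known geometry through noise and segmentation rather than
disagreement about region definitions.

Dataset composition follows the 80 normal : 30/30/30/30 abnormal mix per
200 footprints (largest-remainder apportionment for other sizes), one
footprint per image, sides alternating, all randomness drawn from a
single seeded generator recorded in the manifest.  `incomplete` samples
(a random band of the sole erased) can be generated but are excluded
from default benchmark runs, mirroring the usual exclusion of severely
fragmented scans.

**What passing the benchmark shows — and what it does not.**  The
surrogate demonstrates internal consistency: with a clean outer
boundary, the Canny + geometric pipeline recovers the true region
geometry almost exactly (mean IoU ≈ 0.97, AP 1.0 at the default
operating point), thresholding degrades where sub-threshold rim and
arch pressures erode its mask, and both degrade gracefully across the
five morphologies.  Real scans have blurrier contact margins, fragmented
edges and annotator variability, none of which the generator reproduces;
absolute scores on real data will be lower, and the split-and-merge
backend in particular finds no contiguous transitional band on these
hard-edged images (its marked blocks all fall below the area filter, so
it scores 0 here despite being a workable mid-tier method on real
scans).  The comparison should be read as an ordering, not as absolute
performance.

## Known limitations

- Single-proposal evaluation: the pipeline never emits two candidate
  boxes for one region, so AP has no confidence-ranking component.
- The partition assumes feet roughly axis-aligned with toes up; rotated
  footprints are out of scope.
- Heel-tilt classification from geometry, toe sub-segmentation and
  dynamic (gait) sequences are not attempted.
- The split-and-merge restart-on-merge loop from the classical
  formulation is realised through an order-preserving union-find
  worklist; the resulting partition satisfies the same fixpoint but a
  pathological criterion could in principle merge in a different order
  than a literal quadratic rescan.
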