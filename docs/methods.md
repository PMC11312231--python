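# Methods

This note records the models, parameter choices and numerical decisions
behind `perioloc`, and what the synthetic evaluation does and does not
establish about clinical data.

## Problem setting

A periapical radiograph shows one or a few whole teeth plus surrounding
alveolar bone. Periodontal bone loss is quantified by the apical distance
between the cemento-enamel junction (CEJ) and the alveolar crest (ALC) on
each tooth flank. The package assumes an upstream instance segmenter has
produced three masks per single-tooth crop — tooth, bone, crown — and
reduces those masks to four landmark points. Everything downstream of the
segmenter is implemented here; the segmenter itself is out of scope and
interchangeable.

## Enhancement

Median filter then CLAHE, in that fixed order: equalization amplifies any
surviving impulse noise, so despeckling must come first.

- `median_kernel` = 3 px (odd, ≥ 1). The smallest standard denoising
  window; larger kernels blur the thin crest contour. Borders are
  edge-replicated so no artificial dark frame perturbs the CLAHE tiles.
- CLAHE `clip_limit` = 2.0, `tiles` = 8×8, 256 histogram bins (one per
  8-bit level). Conventional defaults; nothing in the localization stack
  depends on them. Tiles are sized by integer division with the last
  row/column absorbing the remainder; output pixels are bilinear blends of
  the four surrounding tile LUTs, clamped to the edge tiles beyond the
  outermost tile centers. With one tile and a non-binding clip the
  transform reduces exactly to global histogram equalization, which is how
  the implementation is cross-checked against an independent oracle.
- Histogram clipping uses the real-valued threshold
  `clip_limit · tile_px / 256` and redistributes the excess uniformly in a
  single pass (the redistributed mass may marginally re-exceed the
  threshold; this second-order effect is accepted, as in common
  implementations).

## Mask primitives

Connected components and binary morphology delegate to `scipy.ndimage`
(components are relabeled to raster-scan first-occurrence order so labels
are deterministic); the disk structuring element comes from
`scikit-image`. Retention keeps the label with maximal pixel count, ties
broken toward the smallest label — deterministic and independent of
discovery order. Compositing two binary masks uses fixed codes
{0, 1, 2, 3} (background / primary-only / secondary-only / overlap), which
encodes the relabel-then-overlay idea without any possibility of value
collisions. `extract_main_instance` bridges the two mask flavors: an
instance-labeled mask is reduced directly, a binary mask is first split
into connected components (default 8-connectivity — rendered teeth and
bone are thick blobs, and 8-connectivity matches visual contiguity).

## ALC localization

The crest is the most coronal point where bone overlaps the tooth. After
compositing tooth (primary) and bone (secondary), a k×k window (default
k = 5, always odd) slides with stride 1 over every pixel; border windows
are clipped and still participate. A center is a hit iff its window
contains ≥ 1 tooth-only pixel and ≥ 1 overlap pixel. The sweep is
implemented as two maximum filters with zero padding, which is exactly
the clipped-window "contains" predicate; tests compare it against an
exhaustive double-loop scanner.

Reduction to points: hits are split at the tooth centroid column;
each side reports its minimum-row hit (ties: outermost column — smallest
on the left, largest on the right). The crest is by definition the most
coronal tooth–bone contact, hence minimum row. The raw hit set is also
returned so callers can apply a different reduction. The kernel geometry
biases the recovered row coronally by up to ⌊k/2⌋ pixels (a window
centered above the contact can still contain it), which is the dominant
term in the observed ≈ 2.4 px mean row error on clean masks.

## CEJ localization

A predicted crown rarely aligns with the crown portion of the tooth mask,
so the crown is dilated before compositing. The stopping rule
operationalizes "the crown envelops the tooth's crown portion" without
knowing the true CEJ: stop at the first iterate that covers, *in every
column where the original crown is present*, all tooth pixels above the
original crown's lowest row in that column. The per-column form matters:
a single global crown-bottom row would, on a tilted tooth, drag the
coverage target onto the downhill root flank and force over-dilation
(observed as multi-pixel CEJ bias and envelopment failures at tilts
within ±10°). `max_iterations` defaults to 10 (a 3×3 square element step
per iteration comfortably covers realistic crown under-segmentation);
exceeding it returns the last iterate flagged `enveloped=False` rather
than failing.

The junction set J is every overlap pixel 4-adjacent to a tooth-only
pixel — the one-pixel-thick lower frontier of the dilated crown inside
the tooth (4-adjacency keeps the frontier thin). Points: J is split at
the tooth centroid column and each side reports its extreme-column
element (minimum column left, maximum right), ties broken toward the
larger row — the CEJ is marked on the mesial/distal tooth surfaces, and
crown over-segmentation errors sit coronally. A crown that swallows the
whole tooth leaves J empty; both points are reported absent with an
over-dilation flag, never fabricated.

Disabling dilation (`max_iterations=0`, `envelop_check=False`) is the
ablation baseline: on crowns eroded by 2 px the junction then forms a
ring around the whole shrunken crown, and the extreme-column rule picks
points far coronal to the true CEJ — the suite shows ≈ 26 px mean error
versus ≈ 0.5 px with envelopment dilation.

## Metrics

Standard definitions throughout: precision TP/(TP+FP), recall TP/(TP+FN),
accuracy (TP+TN)/total, Dice, Jaccard, AP as the recall-integral of the
all-points-interpolated precision envelope, mAP as the unweighted
per-class mean. Undefined values (zero denominators, no common
landmarks) are returned as `None`/absent, never coerced to 0 or 1.

Landmark RMSE pools all present point pairs:
`RMSE = √( Σ (Δrow² + Δcol²) / 2n )`, with coordinates divided by the
image dimensions (row/height, col/width) when `normalize=True` (the
default — it makes values comparable across image sizes and keeps them on
the dimensionless scale clinical reports use). `n` counts point pairs;
the factor 2n counts coordinates. The per-point `agreement_pct`,
`100·(1 − d/diagonal)` floored at 0, is this package's own construction
for a single-point agreement percentage and is labeled as such in all
outputs.

## Synthetic scenes

The generator emulates the scene structure the locators rely on, not
radiographic appearance:

- **Tooth**: vertically symmetric profile — elliptical crown cap (top
  third of the crown), constant-width crown body to `cej_row`, linear
  taper to `root_tip_row`. Defaults: 256×256 canvas, crown width 90 px,
  tip width 30 px, crown top row 30, CEJ row 110, apex row 230. A
  single-rooted simplification; the locators consume mask topology, not
  anatomy, and multirooted shapes are an extension point.
- **Crown mask**: exactly the tooth above `cej_row`.
- **Bone**: full-width band from `bone_crest_row` (default 150) minus the
  tooth interior eroded by `bone_overlap_px` = 8, so bone overlaps the
  outer 8 px of the root flank and first touches the tooth exactly at the
  crest row. Radiographically bone superimposes over the root, so a
  several-pixel overlap is the realistic regime; 8 px is chosen so that
  the overlap provably survives the corruption model below (erosion of
  both masks removes 4 px, worst-case opposite jitter 2 px more, leaving
  ≥ 2 px).
- **Tilt**: whole-scene rotation (nearest-neighbor for masks, the exact
  rotation matrix for ground-truth points, both about the pixel-center of
  the canvas).
- **Corruption** (`*_pred` masks): binary erosion by `mask_erosion_px`
  (3×3 square per step, frame treated as foreground so image-edge
  structures are not eaten from outside), then an independent random
  shift in {−1, 0, 1}² per mask; with erosion 0 the predicted masks equal
  the clean ones. `distractor_teeth` partial elliptical blobs (semi-axes
  32×9 px) hug the left/right image borders of the tooth mask only,
  exercising largest-instance retention.
- **Render**: background 85, bone 125, tooth 168 (contrast compressed
  into ≈ [80, 170]), Gaussian noise σ = 8, 5% salt-and-pepper.
- **Suite** (`generate_suite`): per case, CEJ row ±10%, crest 10–70 px
  apical to the CEJ (mild to severe bone loss), tilt uniform in ±10°;
  the standard evaluation suite uses n = 100 with erosion 2 px and two
  distractors. All randomness flows from one integer seed through a
  single `numpy` generator; cases are bit-reproducible.

What passing these tests shows: the locators recover the constructed
crest and junction within their discretization bounds under realistic
mask corruption, tilt and anatomy variation. What they do not show:
robustness to real segmenter failure modes (holes, multi-blob masks,
boundary waviness correlated with image texture), multirooted or crowded
teeth, or genuine radiographic contrast — conclusions about clinical
accuracy require clinical masks.

## Numerical choices and degenerate inputs

- Rounding to 8-bit after CLAHE uses round-half-even; the oracle tests
  use the same convention.
- Empty tooth masks raise; empty hit sets and empty junction sets are
  valid results that yield absent landmarks plus a logged warning.
- The centroid split sends hits at exactly the centroid column to the
  right side (`col ≥ centroid`); with float centroids this boundary case
  is measure-zero in practice and mirror symmetry holds on all tested
  cases.
- Problem sizes: oracle comparisons run on ≤ 32×32 canvases (50–100
  seeded instances each); suite-level guarantees use the 100-case
  256×256 suite. The full test suite runs in well under a minute.
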