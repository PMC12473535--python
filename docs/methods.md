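# Methods

This note documents the models, numerical choices, and open design
decisions behind the package, and what the synthetic experiments do and do
not establish.

## Measurement model

Body length is defined as the arc length of the body's centerline (medial
curve), which is invariant to posture.  The pipeline is two-stage: an
instance stage supplies one binary mask per body (any instance segmenter
can be plugged in through COCO-style JSON; a classical threshold +
watershed stand-in is bundled for synthetic work), and a centerline stage
turns each (image, mask) pair into a one-pixel centerline whose length in
pixels is converted to millimetres by a scalar calibration `mm_per_px`.
The calibration is always an input; for synthetic scenes the default is
0.5262 mm/px, consistent with the px↔mm scale of the reference imaging
geometry the generator emulates.

## Centerline network

Input fusion concatenates the [0, 1]-scaled RGB image with the instance
mask and reduces 4 → 3 channels with a 1×1 convolution.  The fusion kernel
is trained jointly with the rest of the network; the alternative (a fixed
projection) was rejected because the mask channel's optimal weighting is
data-dependent.

The body is a fully convolutional encoder–ASPP–decoder:

- encoder: `encoder_depth` stages (default 3) of two 3×3 conv + ReLU
  layers, 2× average-pooled between stages; stage widths 8/16/32 by
  default;
- bottleneck: the deepest map concatenated with the fused input
  average-pooled to the same resolution (spatial guidance), then parallel
  3×3 dilated convolutions at rates (1, 2, 4) — DeepLab-style ASPP scaled
  to desk-size inputs, where rate 18 would exceed the 12×12 bottleneck —
  concatenated and projected 1×1;
- decoder: per stage, 2× nearest upsampling, concatenation with the
  encoder skip, and two 3×3 conv + ReLU refinements (widths 16/16/8);
- head: 1×1 convolution + sigmoid.

Inputs whose sides are not multiples of `2^encoder_depth` are reflect-
padded and cropped back; the padding adjoint is folded exactly in the
backward pass (all gradients verified against finite differences in the
test suite).  The implementation is plain float64 numpy, so results are
bit-reproducible from a single integer seed controlling initialization,
shuffling, and augmentation draws.

Targets are 3-px-wide bands: the ground-truth polyline rasterized with
Bresenham segments (8-connected, one pixel wide) and dilated once with a
3×3 square element.  The dilation necessarily extends the band by one
pixel beyond each end; this is deliberate (it is the dilation of the
curve) and is absorbed by the thinning stage, which erodes line ends by a
comparable amount.

Loss: `Dice + β·BCE` with a shared stability constant ε inside both the
Dice ratio and the BCE logarithms.  β defaults to 1.0 and ε to 1e−6 (both
exposed; neither value is critical — Dice dominates early training, BCE
sharpens boundaries late).

Training: momentum SGD (lr 0.02, momentum 0.9), multi-step decay
(milestones scaled to run length, γ = 0.1), batch size 4.  Two
stabilizers are added to the textbook recipe: global gradient-norm
clipping at 2.0 and a 4-epoch linear warmup.  Without them this small
unnormalized CNN intermittently collapses into the all-background
attractor (sigmoid saturation after an early momentum overshoot), a
seed-dependent failure.  Per-sample augmentation draws a random dihedral
transform (flips, 90° rotations) when the crop is square.

Inference binarizes at threshold 0.5 (exposed), runs on the instance's
bounding box plus a 16-px margin (the network is fully convolutional, so
this is exact and much faster on multi-instance frames), closes the band
with a radius-3 disk to bridge rare under-confidence gaps, and hands the
band to the skeleton stage.

## Skeleton and length

Zhang–Suen thinning is implemented vectorized (all-pixel neighbor grids
per sub-iteration) with the classic conditions; neighbors are ordered
P2..P9 clockwise from north, borders zero-padded, and the 8-bit
neighborhood code uses bit i for the i-th neighbor in that order.  The
result is reduced to a single open path by taking the longest
endpoint-to-endpoint geodesic of the 8-connected pixel graph (Dijkstra
from each degree-1 pixel; on a closed curve, the overall longest
geodesic; on disconnected input, the largest component, flagged).

Arc length of a raw pixel path is the unit / √2 step sum.  That metric
carries a known digitization bias — a digital straight line at the worst
orientation is ~8% longer than the true segment — so the measurement
chain computes length on a moving-average-smoothed copy of the path
(window 5, endpoints pinned), which removes the staircase inflation
(median recovery error on ground-truth bands drops from ~4% to ~0.5%)
while leaving axis-aligned runs untouched.  This is coordinate averaging,
not a spline re-fit; the raw step-sum definition remains available and
tested.

Skeletons of elongated bodies stop short of the body tips (a medial axis
ends one cap-radius inside a rounded end; learned bands decay near the
spine ends).  The chain therefore extends both path ends along the mean
direction of their last five pixels, in half-pixel steps, for as long as
the candidate pixel is foreground — a parameter-free stop rule.  The
extension is applied identically to every skeleton-based method, so
method comparisons are unaffected by it.  Its known cost is a small
positive bias (roughly the end-cap radius per tip, ~1–2 px) relative to
the generator's spine-length ground truth.

## Baselines

All baselines consume the same body mask and report length through the
same smoothing/extension/calibration chain; only the centerline source
differs.

- **PCFM** (polynomial curve fitting): rotate the pixel cloud so the
  principal axis (θ = ½·atan2(2μ11, μ20−μ02), ties → 0) is horizontal,
  least-squares fit a degree-3 polynomial (degree exposed — its manual
  choice is a documented weakness of the method), sample 200 points over
  the principal extent, rotate back, and keep only samples inside the
  mask.  Fails structurally when the aligned centerline is not a function
  of the principal coordinate (S-shapes, curled bodies).
- **VDBM** (Voronoi medial axis): Voronoi diagram of the sub-pixel
  boundary contour; an edge is kept only if its two generating boundary
  sites subtend ≥ 150° from one of its vertices (the separation-angle
  filter of the simplified medial axis — pixelation burrs subtend tiny
  angles and vanish, axis edges between opposite boundary stretches
  survive).  The longest endpoint geodesic of that graph, coordinate-
  smoothed, is the centerline.  This reproduces the continuous closed
  forms (capsule: body extent − 2·cap radius; circle: near-point) and
  also the method's documented fragility: on strongly curled bodies the
  significant graph fragments and the retained path collapses, which is
  why VDBM posts by far the worst benchmark errors.
- **Morphological skeleton**: Zhang–Suen thinning of the full body mask,
  longest-path pruned.

## Synthetic scenes

A scene emulates the study conditions the pipeline targets: an 848×480
top-down frame of a flat container holding 10–18 (default 12)
non-overlapping curved bodies.  Each body is a disk of tapered radius
r(t) = r_max·(0.35 + 0.65·sin πt) swept along a cubic spline through 4–6
control points laid down by a heading walk whose total absolute turn (the
curvature parameter, default 0.3–2.2 rad) controls curl; the sampled
spine is rescaled so its arc length exactly equals the drawn body length
(40–110 mm at 0.5262 mm/px).  Bodies render semi-translucently
(alpha 0.5–0.9) in shrimp-like hues over a plain or textured background
with Gaussian pixel noise (σ = 3), so foreground contrast is weak — the
property that breaks naive thresholding.  Ground truth per instance is
the mask, the sub-pixel spine polyline, and its exact arc length; export
is PNG + COCO JSON (uncompressed RLE) + a centerline sidecar, and
round-trips bit-exactly.

Desk-scale experiments use 96×96 single-body scenes with lengths 30–46 mm
so bodies fit the crop: training uses 20 such scenes for 30 epochs
(about half a minute on one CPU), evaluation uses 8 held-out scenes, and
the measurement benchmark uses 9 full-size default scenes (≥ 100 bodies).
These sizes are the package's reference configuration; they were chosen
so the complete study, including training, runs in minutes.

What passing synthetic tests does not show: robustness to real optics
(refraction, caustics, motion blur), to amodal occlusion (overlapping
bodies are generated with full per-instance masks), to annotation noise,
or to the domain gap between the swept-disk body model and real shrimp
morphology (rostrum, legs, tail fan).  In particular, on ideal synthetic
masks the classical morphological skeleton is near-optimal by
construction, so the learned route's advantage over it here is small;
its decisive advantages on real data (robustness to ragged masks and
background blending) are not measurable in this sandbox.

## Limitations

- The stand-in segmenter assumes a roughly uniform background; it is a
  contract-filling stand-in, and its confidence scores (normalized areas)
  are not calibrated.
- Length ground truth is the spine of the swept body; tip extension makes
  all measured lengths overshoot it by roughly the end-cap radii.
- The mask-AP evaluator assumes mask AP (the usual convention for
  instance segmentation); box AP is not computed.
- Training is single-CPU numpy: practical for the reference scale
  (~100 k parameters, 96×96 crops), not for production-scale imagery.
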