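# shrimpline

Body-length measurement for curved, elongated aquatic organisms (shrimp)
from top-down images, via dual segmentation: per-instance masks feed a
learned **centerline** segmentation model, the predicted centerline band is
thinned to a one-pixel skeleton, and its arc length — scaled by an
mm-per-px calibration — is the body length.  Because the centerline's arc
length is invariant to posture, the measurement works for straight,
curved, and curled bodies alike.

The package is aimed at aquaculture imaging work: it contains the learned
centerline module and its training loop, the classical comparison methods
(polynomial curve fitting, Voronoi medial axis, morphological skeleton),
the full evaluation stack (MAE/RMSE in px and mm, pixel-wise
precision/recall/F1/mIoU, COCO-style mask AP), and a seeded synthetic
scene generator with exact ground truth so the whole pipeline is testable
without any proprietary data.

## Method

For each detected instance, the RGB image `I` (scaled to [0, 1]) is
concatenated with the instance's binary mask `M_i` and reduced back to
three channels by a jointly-trained 1×1 convolution:

    I_fused = Conv1x1(Concat(I, M_i))

`I_fused` passes through a small encoder; the deepest feature map,
concatenated with a downsampled copy of `I_fused`, enters an ASPP block
(parallel dilated convolutions, rates 1/2/4 at desk scale).  The ASPP
output is upsampled and merged with the encoder skip connections, each
merge followed by convolutional refinement, ending in a 1×1 convolution
and sigmoid: a per-pixel probability `Ŷ` that the pixel lies on the body's
centerline.  Training targets are 3-px-wide bands (rasterized ground-truth
polylines dilated once with a 3×3 element) under the composite loss

    L = 1 − (2·ΣYŶ + ε)/(ΣY + ΣŶ + ε)  +  β·BCE(Y, Ŷ),      β = 1, ε = 1e−6

optimized with momentum SGD (lr 0.02, multi-step decay, warmup, gradient
clipping).  The binarized band is reduced to one pixel width by
Zhang–Suen thinning (two sub-iterations deleting boundary pixels under the
neighbor-count, transition-count, and directional tests, until stable),
resolved to its longest endpoint-to-endpoint geodesic, measured as a
smoothed Euclidean step sum, tip-extended within the mask, and converted
to millimetres.  Accuracy is reported as

    MAE = (1/N) Σ |y_i − ŷ_i|,    RMSE = sqrt((1/N) Σ (y_i − ŷ_i)²)

## Worked example

```python
import shrimpline as sl
from shrimpline import experiments

# train the desk-scale reference model: 20 single-body 96x96 scenes
net, history, _ = experiments.train_reference_model(seed=1)
print(f"loss {history[0]:.3f} -> {history[-1]:.3f}")
print(f"held-out F1 {experiments.reference_f1(net, seed=1):.3f}")

# measure ~108 bodies in full-size scenes by all four methods
report = experiments.run_benchmark(net, seed=1)
for method, e in report.per_method.items():
    print(f"{method:8s} MAE {e.mae_px:6.2f} px ({e.mae_mm:5.2f} mm)  "
          f"RMSE {e.rmse_px:6.2f} px")
```

prints

```
loss 1.638 -> 0.107
held-out F1 0.924
learned  MAE   3.63 px ( 1.91 mm)  RMSE   6.34 px
morph    MAE   3.28 px ( 1.73 mm)  RMSE   3.46 px
pcfm     MAE  10.49 px ( 5.52 mm)  RMSE  19.26 px
vdbm     MAE  47.77 px (25.14 mm)  RMSE  62.05 px
```

The learned route and the plain morphological skeleton are both accurate
on clean synthetic bodies (within ~2 mm); polynomial curve fitting
degrades with body size and curvature, and the Voronoi medial axis —
pruned to its longest significant path — fails badly on strongly curled
bodies, the same qualitative ordering the underlying study reports on
real shrimp.

A command-line interface covers the same pipeline stage by stage:

```bash
shrimpline generate --out scenes --n-scenes 5 --seed 1
shrimpline segment  --image scenes/scene_0000.png --out det.json
shrimpline train    --data scenes --out model.npz
shrimpline measure  --image scenes/scene_0000.png --masks det.json \
                    --model model.npz --mm-per-px 0.5262 --out meas.csv
shrimpline evaluate --scenes scenes --model model.npz \
                    --methods learned,morph,pcfm,vdbm --out report/
```

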