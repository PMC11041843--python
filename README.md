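# makm — Multidimensional Alternating Kernel Method

Cortical-layer segmentation of stained histology by mixture decomposition of
a joint feature histogram. The features are an **equivolumetric cortical
depth** map (0 at the pia, 1 at the gray–white boundary, reparameterized so
each depth shell encloses a constant tissue-volume fraction regardless of
folding) and the **stain intensity** (e.g. SMI-32, which stains layers III
and V darkly and therefore cannot separate them by intensity alone — depth
disambiguates them).

## The method

Let `I : Ω → Y ⊂ R^N` be the multi-channel image and `q` its joint
histogram, a probability density on `Y = [0,1]^N` (50 evenly spaced bins per
channel by default). The model is an M-component Gaussian mixture

```
g_θ(y) = Σ_m ω_m ψ_{K_m}(y − μ_m),    Σ_m ω_m = 1,
```

with `ψ_K` the zero-centered normal density. Components are added one at a
time: at stage M the previous model's **filtered kernel estimate**

```
f_θ(y) = Σ_m ((ρ_m q) * ψ_{S_m})(y),   ρ_m(y) = ω_m ψ_{K_m}(y − μ_m) / g_θ(y)
```

(each component's posterior share of the histogram, re-smoothed with a
kernel oriented by that component) becomes the fixed target, a new component
is seeded where the box-smoothed residual `e = f − g` is largest ("smart
start": mean at the error peak, weight equal to the error mass in the box,
covariance from the error-weighted second moments), and all parameters are
refined by projected gradient descent on `‖f − g_θ‖²_{L2}`.

Voxels are then labeled, after sorting components by mean depth, either by
the naive rule `L(x) = argmax_m ρ_m(I(x))` or by the contiguity-preserving
rounded weighted sum

```
L(x) = ⌊ Σ_m m · ρ_m(I(x)) ⌉ ,
```

which places a voxel split between components 3 and 5 into the anatomically
sensible layer 4 rather than 3.

The package also ships a synthetic cortical-ribbon phantom with *analytic*
equivolumetric depth for annular geometries (`d(r) = (R_o²−r²)/(R_o²−R_i²)`
for a gyral ribbon) and the validation metrics used for laminar
segmentations: per-label Dice overlap and percentile (50/75/95/100)
Hausdorff distances between interface point clouds.

## Worked example

```python
import numpy as np
from makm import *

spec = default_smi32_spec(noise_sd=0.05, seed=1)   # 6-layer gyral ribbon
out = generate_phantom(spec)
image = normalize_channels(out.image)
q = joint_histogram(image, 50)
model, trace = fit_makm(q, FitConfig(mmax=6))
model = sort_components_by_depth(model)
pred = label_contiguous(model, image)

print("final L2 objective per stage:",
      ["%.3f" % o for o in trace.final_objectives])
for k, (d, w, mu) in enumerate(zip(
        [dice(pred, out.truth, k) for k in range(1, 7)],
        model.weights, model.means), start=1):
    print(f"layer {k}: depth {mu[0]:.2f}  intensity {mu[1]:.2f}  "
          f"weight {w:.3f}  Dice {d:.3f}")
a = extract_interface(pred, 3, 4); b = extract_interface(out.truth, 3, 4)
print("III/IV interface hd50 = %.3f mm" % percentile_hausdorff(a, b, 50))
```

prints

```
final L2 objective per stage: ['5.100', '1.885', '0.853', '0.575', '0.082', '0.033']
layer 1: depth 0.05  intensity 0.89  weight 0.107  Dice 0.951
layer 2: depth 0.13  intensity 0.68  weight 0.055  Dice 0.945
layer 3: depth 0.28  intensity 0.27  weight 0.239  Dice 1.000
layer 4: depth 0.49  intensity 0.79  weight 0.179  Dice 1.000
layer 5: depth 0.68  intensity 0.16  weight 0.195  Dice 1.000
layer 6: depth 0.89  intensity 0.58  weight 0.224  Dice 1.000
III/IV interface hd50 = 0.000 mm
```

Each fitted component's mean depth and intensity land on one generated
layer (dark layers III and V at intensities 0.27/0.16, separated by depth
0.28 vs 0.68), the weights recover the layer volume fractions, and the
contiguity rule reproduces the ground-truth laminae at Dice ≥ 0.95 despite
the intensity noise. The stagewise objective is the L2 distance between
each stage's target field and its refined mixture.

The same pipeline is scriptable from the shell:

```
makm simulate --out-dir phantom/
makm fit --channels phantom/depth.tif,phantom/stain.tif --mask phantom/mask.tif \
         --mmax 6 --bins 50 --out model.json --trace trace.csv
makm segment --model model.json --channels phantom/depth.tif,phantom/stain.tif \
             --mask phantom/mask.tif --rule contiguous --out labels.tif
makm evaluate --pred labels.tif --truth phantom/truth.tif --out metrics.csv
```

A scikit-learn style front end wraps the whole pipeline:
`MAKMSegmenter(mmax=6).fit_predict(image)`.

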