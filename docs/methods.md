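# Methods

## Model

The segmentation problem is posed entirely in feature space. Every masked
voxel of a multi-channel image contributes a feature vector — here
`(equivolumetric depth, stain intensity) ∈ [0,1]²` — and the joint histogram
`q` of those vectors is treated as a probability density on a regular bin
grid (unit integral; bins half-open with the top edge closed so depth 1, the
gray–white boundary, is counted). The working assumption is that `q` was
generated by a finite Gaussian mixture in which each component corresponds
to one (part of a) cortical layer: a layer occupies a band of equivolumetric
depth and a characteristic stain level, so in the depth × intensity plane it
is a localized blob. Non-depth channels are affinely rescaled to [0,1] over
the mask before histogramming; the depth channel is used as is. Intensity is
used without dark/light inversion — the mixture is indifferent to monotone
relabeling of the intensity axis.

## Alternating, incremental fit

The mixture is grown one component at a time. At stage M:

1. The previous model's filtered kernel estimate (FKE) is computed on the
   bin grid and frozen as the target `f` (at M = 1 the target is `q`
   itself). Each component's share `ρ_m q` of the histogram is convolved
   with a Gaussian kernel and the shares are summed.
2. A new component is seeded from the residual `e = f − g` ("smart start"):
   the mean at the maximizer of the box-smoothed error `(e * b)` (box kernel
   of `(2·halfwidth+1)^N` bins, unit sum, zero-padded; ties broken at the
   lowest C-order bin), the weight as the error *mass* in that box (smoothed
   error density × box feature-space volume, clamped to [1e-3, 0.5]), and
   the covariance as the error-weighted second moment of the box
   neighborhood, with a box-sized diagonal fallback when the moment matrix
   is not positive definite (the error can be negative inside the box).
   Existing weights are rescaled by (1 − w_new) to restore the simplex.
3. All M components are refined jointly by minimizing the discrete squared
   L2 distance `Σ_bins (f − g_θ)² · bin_volume` over the full parameter set.

If the box-smoothed error is nowhere positive the loop stops early: there is
no under-fit region left for a new component to explain.

### Kernel scale vs. component shape

The FKE smoothing kernel for component m has covariance
`S_m = diag(h) · corr(K_m) · diag(h)`: the bandwidth `h` fixes the kernel's
standard deviation per channel, while the component covariance contributes
only its correlation (orientation). The alternative of scaling the raw
covariance by the bandwidth makes the smoothing length proportional to each
component's own spread, which is unstable in practice: once a component
becomes narrow its share of the histogram is essentially unsmoothed, the
target field is then sharp exactly where the model already fits, and the
residual-driven insertion piles further components onto the sharpest region
instead of the worst-covered one (observed on the layered phantom as five
components tiling a single layer). With the scale reading the target's
resolution is homogeneous and insertion tracks genuine coverage gaps.

Kernels are discretized at bin-center offsets, truncated at 4σ per axis, and
renormalized to unit discrete sum, so convolution (FFT, "same"-size,
zero-padded boundaries) conserves mass up to boundary leakage; a kernel
whose support exceeds 10× the grid is rejected as implausible. A zero
bandwidth is the delta-kernel limit and reproduces the ρ-filtered histogram
bin for bin.

### Optimization

Constraints are enforced by reparameterization: weights through a softmax
over logits (simplex; with one component the weight is pinned to 1), and
covariances through lower-triangular Cholesky factors whose diagonals are
stored in log (symmetric positive definite by construction). Gradients of
the discrete L2 objective are analytic in all blocks (verified against
central finite differences in the tests). Descent uses the Barzilai–Borwein
spectral step as the trial step with Armijo backtracking (constant 1e-4,
halving) — a plain fixed-step rule crawls here because the logit, mean and
log-Cholesky blocks have very different curvatures. Each candidate is
projected onto the box that keeps every Cholesky diagonal at or above half a
bin width: a component narrower than the grid resolution is unrepresentable
and would let the discrete density spike without bound. Iteration stops at a
relative objective change below 1e-8 or at 2000 iterations; the recorded
objective is non-increasing across accepted steps by construction. The whole
fit is deterministic — moment initialization, error-peak insertion and
descent involve no randomness — so reruns are bit-identical.

Responsibilities are floored: wherever the mixture density falls below
1e-12 × the largest density in the evaluated batch (the grid maximum when
evaluating on the bin grid), the responsibility vector is set to zero.
Voxels in that regime are labeled by the nearest component mean in feature
space.

## Labeling

Components are sorted by ascending mean depth (ties broken on the remaining
channels) so that component index order is depth order. The contiguity rule
rounds `Σ_m m·ρ_m` half-up (3.5 → 4) and clips to [1, M]; half-up keeps the
worked 0.51/0.49 example pulling toward the deeper of two straddling
components, and clipping guards the floating-point extremes. The argmax rule
breaks exact ties toward the lowest index. Component-to-anatomical-layer
naming is deliberately manual; `merge_labels` only folds chosen component
groups into layer masks.

## Phantom generator

The phantom emulates a curved cortical ribbon: an annulus (gyral: pia on the
outer circle; sulcal: pia inner; plus a flat slab variant), default radii
2.0/0.5 mm on a 96×96 grid at 0.05 mm spacing, rasterized in 2D by default
(an extruded 3D variant exists for volumetric I/O). Depth is the exact
equivolumetric depth for the geometry — the iso-depth contour at `d`
encloses the fraction `d` of the ribbon area — so gyral layers of equal
volume are radially thinner near the pia and thicken toward the white
matter, the deformation the real depth maps encode. Layers are depth slabs
at prescribed volume fractions; intensity is a per-layer mean plus i.i.d.
Gaussian noise clipped to [0,1] (depth stays noiseless, mirroring its role
as a given geometric channel).

The default six-layer specification mimics SMI-32 contrast: volume fractions
(0.08, 0.08, 0.24, 0.18, 0.20, 0.22) and mean intensities (0.90, 0.70,
0.30, 0.80, 0.20, 0.60), i.e. dark III and V, light I/II/IV/VI, with layer
IV about 0.23 mm thick at mid-column — inside the 0.2–0.3 mm range typical
of carnivore auditory cortex. The intensity profile is plausible rather than
calibrated; no quantitative per-layer staining curve exists to calibrate
against. What the phantom does **not** emulate: anisotropic slice spacing
and partial-volume effects, stitching/registration artifacts, within-layer
staining gradients, or depth-map estimation error (depth is analytic, not
estimated). Passing phantom tests therefore demonstrates the estimator and
labeling machinery, not robustness to those acquisition confounds.

## Evaluation

Dice is the standard `2|A∩B|/(|A|+|B|)` per label (defined as 1 when both
sets are empty). Interfaces between adjacent labels are extracted as the
physical midpoints of voxel faces separating the two labels — a point-cloud
stand-in for surface meshes, adequate at test resolutions — and compared by
percentile Hausdorff distances: directed nearest-neighbor distances pooled
in both directions, percentile taken with linear interpolation; the 100th
percentile is the classical symmetric Hausdorff maximum. The pooled
symmetric construction was chosen because it is the standard "robust
Hausdorff" and makes the metric symmetric in its arguments.

## Problem sizes and defaults

| parameter | default | why |
|---|---|---|
| bins per channel | 50 | resolves six layers in depth (≈4–12 bins each) without starving bins of counts at 10³–10⁵ voxels |
| Mmax | 12 | over-segmentation budget used for real cortex; phantoms use 6 (one per layer) |
| bandwidth | 2 bin widths per channel | one-to-two bin widths is the conventional smoothing scale for a filtered kernel estimate |
| box halfwidth | 1 (3 bins/axis) | smallest neighborhood that is an "average error within a region" |
| tol / max_iter | 1e-8 / 2000 | looser settings leave the joint refinement visibly unconverged (components fail to redistribute across layers) |

Tests and the worked example run the full pipeline on the 96×96 ribbon
(≈4.7k masked voxels, 50² bins, Mmax = 6), which fits in ~10 s; parameter
recovery uses 10⁵ samples on 50² bins.

## Known limitations

- The Gaussian kernel class is fixed a priori; heavy-tailed or skewed
  stain distributions are approximated, not modeled.
- The number of components is chosen by the user, not selected.
- The L2 objective is evaluated on the truncated grid, so density placed
  outside [0,1]^N is unpenalized; normalization pins data to the domain
  edges where this matters most (mitigated by the Cholesky floor and the
  simplex constraint, but edge-hugging components can still sit slightly
  off-grid).
- Depth maps are consumed as input; estimating equivolumetric depth from
  surfaces is out of scope, and depth-map error propagates directly into
  the feature space.
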