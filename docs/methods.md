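# Methods

## Model

An observed fluorescence image is modelled additively, `Y = Is + B + N`:
a foreground `Is` carrying the neuronal signal, a background `B`, and
noise `N`. Estimation minimises, over `Is >= 0` and `B >= 0`,

```
1/2 ||Y - Is - B||²₂ + λ₁||Is||₁ + 1/2 λ₂ ||∇^(k₀) Is||²₂ + 1/2 λ₃ ||∇^(k₁) B||²₂
```

The L1 term encodes foreground sparsity; the two quadratic terms penalise
the k-th order finite differences of each component along both in-plane
axes. A k-th order difference annihilates polynomials up to degree k−1,
so a higher order (`k₁ > k₀`) lets the background vary smoothly at larger
scales while still suppressing texture — the background is the smoother
component by construction. The problem is convex for any non-negative
weights.

## Difference operators

`∇^(k)` is defined by the template `[-1, ..., -1, k]` (length k+1, zero
sum): `(∇^(k)u)(t) = k·u(t) − Σ_{i=1..k} u(t−i)`. Applied along an axis
of extent m it yields extent m+k with the first and last k positions
structurally zero (implicit zero padding; reflective or periodic variants
are deliberately not used). The adjoint is correlation with the reversed
template restricted to the rows the forward operator can reach; this is
the exact transpose under the Frobenius inner product, verified in the
tests both by the inner-product identity on random pairs and against
dense-matrix algebra on all shapes up to 8×8 (`operators.forward_matrix`
exists precisely to support that cross-check). Axes shorter than k+1
contribute zero penalty, which lets the high default background order
(`k₁ = 5`) run on thin tiles.

The spectrum of the composite `∇ᵀ∇` along one axis is bounded by
`(k² + k)²` (loose but closed-form; the tests measure e.g. 37.8 against
the bound 900 for k = 5 at extent 12). With the data term's identity
Hessian and both axes, the partial gradients are Lipschitz with constants
at most `Ls = 1 + 2λ₂(k₀²+k₀)²` and `L_B = 1 + 2λ₃(k₁²+k₁)²` — 8.2 and
901 at the defaults — whose reciprocals are the fixed step sizes.

## Parameters

| name | default | units / meaning |
|------|---------|-----------------|
| λ₁ | 0.1 | weight of the foreground L1 term |
| λ₂ | 0.1 | weight of the foreground smoothness term |
| λ₃ | 0.5 | weight of the background smoothness term |
| k₀ | 2 | foreground difference order |
| k₁ | 5 | background difference order (k₀ < k₁ enforced) |
| floor | 3 | hard foreground threshold, intensity counts on an 8-bit-like scale |
| max_iter | 200 | iteration cap per slice |
| tol | 1e-3 | relative-change stopping tolerance |
| prox_mode | "floor" | "floor" = hard floor; "soft" = exact L1 prox |

The weights and orders are fixed values meant to be used unchanged across
datasets; none are tuned per image. The floor is interpreted on the raw
intensity scale of the input; for 16-bit data scale it accordingly
(`--floor` on the CLI).

## Initialization

The background guess clips `Y` from above at its global median (bright
structures occupy a small fraction of a neuronal image, so the median is
a background statistic) and smooths the result 20 times with a normalised
3×3 binomial kernel (`[1,2,1]⊗[1,2,1]/16`, reflective boundaries);
repeated small-kernel passes approximate one wide Gaussian, and the
reflective boundary preserves constants exactly. The foreground guess is
`max(Y − B₀, 0)`. The kernel width is a package convention — the recipe's
origin fixes the repeat count but not the kernel.

## Solver

Block proximal gradient descent, foreground block first, then the
background at the fresh foreground (Gauss–Seidel order, which preserves
the descent guarantee of the exact-prox mode). Each foreground update is
a gradient step of length `1/Ls`, a clamp at zero, then the proximal /
threshold step:

* **floor mode (default)**: the hard floor `T(·, 3)` — entries strictly
  below the floor are zeroed (entries equal to the floor are kept). This
  is what removes residual noise, but it is *not* the proximal map of
  `λ₁||·||₁`; the objective is consequently not guaranteed to decrease
  monotonically, and in practice it can rise while the iterates still
  converge. A zeroed pixel can only return if a single step lifts it past
  the floor, which the step bound `(|data gradient| + smoothing
  fill-in)/Ls` rarely allows — the floor acts as a ratchet.
* **soft mode**: shrinkage by `λ₁/Ls` plus the zero clamp — the exact
  proximal map of the L1 term with non-negativity. This mode is a
  textbook monotone-descent method; the tests verify non-increasing
  objective traces and agreement (1e-3 relative) with an independent
  bound-constrained solver (L-BFGS-B on the equivalent smooth program:
  under `Is >= 0` the L1 term is linear).

Stopping: the larger of the two relative block changes (Frobenius norm,
`||Δx|| / (||x|| + 1e-8)`) below `tol`, or `max_iter`. Everything is
deterministic; identical inputs give bit-identical outputs. Ablation
variants drop either the L1/threshold machinery (`no_sparse`,
"sparsity-ablation") or set λ₂ = 0 (`no_smooth`, "smooth-ablation"); the
background penalty is kept in both since the contrast of interest is
between the two foreground terms.

## Volumes and tiling

Stacks are processed as independent 2D z-slices: the difference penalties
are defined in-plane, typical axial sampling is coarser than lateral, and
per-slice median initialization tracks intensity drift along z. Volumes
larger than memory are covered by disjoint half-open tiles (default at
most 512³), each decomposed independently and written back in sequence
with no blending — a 2560×2560×512 volume yields exactly 25 tiles.
Tiling along z only is bit-identical to the untiled computation; in-plane
seams inherit each tile's zero-padded boundary and differ in a band of
about k₁ pixels, which the tests bound on the interior.

## Synthetic benchmark

The 2D generator emulates a low-contrast neurite on a flat field: a
vertical bar (default 80×10) of excess intensity `delta ∈ {5,10,15,20}`
on a background of 200, blurred with a 7×7 mean filter (reflective
boundary), plus per-pixel uniform noise on [−2.5, 2.5]; groups of images
share geometry and differ only in noise, each image seeded independently
from `(seed, index)`. The bar is kept wider than the mean filter so that
its core retains the full nominal excess after blurring — the groups are
*defined* by their foreground-minus-background contrast — and it is
oriented vertically so that an image row crosses it the way a line scan
crosses a neurite; profile correlations are computed along the central
crossing row against the pre-blur truth. The generator does not emulate
optical PSFs, Poisson/EMCCD noise, intensity-dependent gain, or curved
neurites, so passing benchmarks demonstrate the decomposition mechanics,
not photometric realism. A 3D companion places non-overlapping bright
spheres on a smooth ramp and returns ground-truth centres for the
point-matching metrics.

## Evaluation metrics

Intensity profiles are bilinear samples on a line segment. Point matching
follows the per-point rule: a detected point is a true positive when its
nearest gold point lies strictly within the radius (6 μm by convention;
distances Euclidean in μm after voxel-spacing scaling), judged against
the full gold set; a gold point is missed when no detection lies within
the radius. Precision is detected-sided (`tp/(tp+fp)`); recall is
gold-sided (fraction of gold points found) because the per-point rule is
many-to-one and `tp/(tp+fn)` would overstate recall when several
detections share one gold point. An optional greedy one-to-one mode
exists for soma counting. Displayed scores round half away from zero to
two decimals.

## Known limitations

* At contrasts comparable to the floor plus the noise amplitude
  (delta ≈ 5 with noise ±2.5 and floor 3), the hard floor removes genuine
  signal: the blur skirt sits below the floor, noise dips push bar pixels
  under it, and the ratchet prevents recovery. In that regime the
  benchmark measures higher profile correlation for the sparsity-ablation
  variant (which keeps the whole skirt plus noise) than for the full
  model; at delta ≥ 10 the full model leads both ablations. The soft
  mode does not ratchet but also does not denoise as aggressively.
* Monotone objective descent is only guaranteed in soft mode.
* Slice-wise processing ignores axial coupling; structures aligned with z
  receive no smoothness prior along z.
* Below extent `k+1` an axis contributes no penalty, so very thin tiles
  lose background regularisation along that axis.
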