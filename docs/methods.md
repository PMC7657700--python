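# Methods

`acmseg` implements four region-based active-contour models in a shared
level-set framework, a deterministic phantom generator, and a scoring
harness. This note records the models, the numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Level-set framework

A contour is the zero level of a scalar field φ on the pixel grid, with
the convention φ > 0 inside. Region membership is made differentiable by
the regularized Heaviside

    H_ε(φ) = ½(1 + (2/π) arctan(φ/ε)),    δ_ε(φ) = ε / (π(φ² + ε²)),

where δ_ε is exactly dH_ε/dφ. Every model evolves φ by explicit Euler on
a gradient flow

    φ ← φ + Δt · [ δ_ε(φ)(data force + s²·ν·κ) + μ(∇²φ − κ) ],

where κ = div(∇φ/|∇φ|) is the level-line curvature, the ν-term penalizes
contour length, and the μ-term is the distance-regularization force of
∫½(|∇φ|−1)² dx, which keeps φ close to a signed distance function and
removes any need for reinitialization. φ is initialized as a binary step:
+ρ strictly inside a seed region, 0 on its inner boundary ring, −ρ
outside (default seed: a centered rectangle covering 40% of each
dimension).

Discretization: central differences for first derivatives, the 5-point
stencil for the Laplacian, replicate (Neumann) borders for the
differential operators, and |∇φ| floored at 1e-10 where it divides.

### Intensity scale

Images are normalized to [0, 1] on load and all fitted statistics live on
that scale, but the data and length terms of the flow are multiplied by
s² = `intensity_scale`² (default 255²). This is algebraically identical
to evolving on native 8-bit intensities, which is the setting in which
the customary parameter values (Δt = 0.1, λ₁ = λ₂ = 1, μ = 1,
ν = 0.01·255·255) produce convergence in tens to hundreds of iterations.
Without the s² factor the distance-regularization term dwarfs the data
term and the contour effectively freezes. Config files accept ν in the
printed 8-bit convention and divide by 255² internally.

## The four models

* **Chan–Vese (`cv`)** fits one constant per side (e₁ inside, e₂
  outside). Data force: −λ₁(I−e₁)² + λ₂(I−e₂)². Fails when shading makes
  one object's intensities overlap the background's.
* **Local binary fitting (`lbf`)** fits Gaussian-windowed local mean
  fields h₁(x), h₂(x) (window std σ) and penalizes the windowed squared
  residuals. Tracks smooth inhomogeneity at the σ scale but is known to
  be sensitive to where the contour starts.
* **Global division (`min`)** splits each side of the contour at its own
  mean into a brighter and a darker sub-population (means g₁₁ ≥ g₁₂
  inside, g₂₁ ≥ g₂₂ outside) and penalizes the residual to the matching
  sub-mean. This absorbs impulse noise and two-level objects that defeat
  a single per-side constant. The split H(I − e) is a hard indicator:
  it is frozen during each φ update, so the flow needs no smoothness in
  it, and a smoothed split's arctan tails would leak large
  cross-population residuals and destabilize the region.
* **Hybrid (`hybrid`)** blends the LBF and global-division data terms
  pixelwise:

      E = Σ (1−F)·[local terms] + F·[global terms] + length + penalty,

  gated by the adaptive weight

      F = clamp₀¹[ p(h₁+h₂)/α · Avg(I_T) · (1 − I_T) ],

  where I_T is the local intensity range in a T×T window and Avg(I_T)
  its image mean (the image's overall contrast variation). The weight
  rises with the image's inhomogeneity level and is switched off near
  boundaries (I_T → 1), where the local terms must decide; a perfectly
  flat image (Avg(I_T) = 0) degenerates to the pure local model. With
  F ≡ 0 the hybrid update is bitwise the LBF update; with F ≡ 1 bitwise
  the global-division update.

All statistics (h, e, g) and the weight F are refitted from the current
φ at the start of each iteration and held frozen through the update
(alternating minimization). The evolution force is therefore exactly the
negative gradient of the discretized energy at fixed statistics — the
test suite verifies this against central finite differences (step 1e-6)
to 1e-4 relative error for all four models.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| λ₁, λ₂ | region-term weights | 1, 1 | published values |
| μ | distance-regularization weight | 1.0 | published value |
| ν | length weight (unit scale) | 0.01 | 0.01·255² in 8-bit units; cv uses 0.1/255², lbf/min 0.001 |
| ε | Heaviside/Dirac width | 1.0 | not published; common in this literature |
| Δt | Euler step | 0.1 | published value |
| σ | local-fitting window std (px) | 5.0 (hybrid), 3.0 (others) | published values |
| ρ | initial step height | 2.0 | not published; any O(1) value behaves alike |
| p | weight scale ∈ [0,1] | 0.5 | not published; midpoint |
| α | weight denominator scale | 0.3 | not published; calibrated so the pre-clamp weight lies inside (0,1) on the phantom suite |
| T | contrast window (px) | 21 | tied to σ=5 via T = 2·ceil(2σ)+1 |
| max_iter, tol | stopping | 3000, 2e-5 | converged when the changed-pixel fraction of the mask stays below tol for 5 consecutive iterations |

Convergence is declared on the binary mask, not on φ, because φ keeps
drifting under the distance penalty after the mask is static. The
tolerance is deliberately tight: on strongly shaded objects the contour
creeps through the dim rim at a few pixels per iteration, and a looser
tolerance stops runs at slightly different rims.

## Phantoms

The generator renders hard-edged shapes (disk, rectangle, two-blob,
ring, two-level disk, step edge) at chosen foreground/background
intensities, then applies a multiplicative shading field and noise:
`clip01(shape · bias + noise)`, with the exact pre-degradation mask as
ground truth. Shading fields (linear ramp, Gaussian lobes, sinusoid) are
strictly positive with max/min ratio 1/(1−a) at amplitude a; by default
they never exceed 1 (no clipping of the base intensities), and a
unit-mean variant is available for amplitude sweeps that must not
confound inhomogeneity with overall darkening. Noise (Gaussian or salt
impulse) is seeded and bit-reproducible.

Two named phantoms anchor the comparisons:

* `BIAS_DISK` — a disk whose illumination peaks at its center and falls
  ≈3:1 toward the rim, plus a dim second shading lobe in the background
  whose brightened pixels overlap the darkened rim. A global two-mean
  threshold necessarily misclassifies the rim and the lobe (cv ≈ 0.886
  here), while windowed local statistics recover the boundary (hybrid
  ≈ 0.9996).
* `SALT_BLOB` — a two-level object (dim shell, bright core) under 10%
  salt noise; the dim shell falls below a two-mean threshold, while the
  four-way global division fits both object levels and absorbs the
  impulses (min ≈ 0.954 vs cv ≈ 0.834).

What the phantoms do **not** emulate: anti-aliased or weak (blurred)
boundaries unless requested, textured tissue, anatomically realistic
shapes, scanner-specific noise statistics. Passing these tests shows the
models behave as designed under controlled shading and noise; it does
not certify accuracy on clinical images.

## Initialization robustness and its limits

All the models here are symmetric under exchanging the labels of the two
regions, and gradient descent is local. Consequently, initialization
independence holds for seed boxes that overlap the object with a clear
brightness differential — the regime the robustness experiment samples
(default-size boxes with centers across the middle third of the frame;
verified exhaustively at the corners of that domain). A box confined to
a far background corner can converge to the label-swapped solution or
stall at a spurious equilibrium; no member of this model family avoids
that, because the energy cannot distinguish a labeling from its
complement.

## Energy monotonicity

The φ-update is exact gradient descent at frozen statistics, but the
recorded energy trace is not strictly monotone, for two reasons: the
explicit-Euler step at Δt = 0.1 (on the 8-bit data scale) overshoots
near equilibria, and the per-iteration refits of the adaptive weight F
and of the e-thresholded splits change the energy landscape itself
(they are modeled coefficients, not variational parameters). The
two-mean model's trace is monotone in practice; the local and hybrid
traces descend during active evolution and jitter near stationarity.
A backtracking line search makes every step monotone but collapses
segmentation quality — the scheme relies on the alternating refits to
make progress — so the shipped implementation keeps the plain published
dynamics and reports descent fractions as measured.

## Problem sizes

All shipped experiments run on 128×128 phantoms; a full hybrid
segmentation (≈300–1600 iterations) takes seconds on one core. The
finite-difference oracle uses 8×8 instances, where exhaustive per-pixel
central differences are exact enough at step 1e-6 and cheap.
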