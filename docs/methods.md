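# Methods

## The optical model

Skin is treated as two stacked absorbing layers over a scattering base:
melanin in the epidermis, hemoglobin in the dermis. For internally reflected
light the modified Lambert–Beer model makes observed optical density
(−log reflectance) linear in the pigment concentrations:

```
d_c(x, y) = m(x,y)·w_mel,c + h(x,y)·w_hem,c + bias_c − s(x,y)·ℓ_c
```

per channel `c ∈ {R,G,B}`. `m`, `h` are unitless relative concentrations;
`w_mel`, `w_hem` are absorbance vectors (density per unit concentration,
non-negative — pigments only absorb); `bias` is the stationary component of
skin colour; `s` is a signed log-intensity shading offset acting along the
unit illumination direction `ℓ = (1,1,1)/√3` by default. The sign convention
is that positive `s` brightens: reflectance is
`exp(−(m·w_mel + h·w_hem + bias) + s·ℓ)`. Reflectance is clamped to
`[2⁻¹⁶, 1]` before any logarithm and clamped pixels are flagged so
round-trip checks can exclude them.

Surface (specular) reflection is assumed already removed (optically, with
polarizers, in a real capture rig); there is no radiative-transfer or
spectral modelling, no BRDF, and no oxy/deoxy-hemoglobin distinction.

## Separation

1. **Colour plane.** Densities of a small region with little illumination
   change (default: the central 25 % window) are decomposed by PCA; the top
   two principal directions span the skin colour distribution plane. The ROI
   must contain ≥ 16 pixels and genuinely 2-D colour variation (the second
   principal variance must exceed 1e−12) — a one-pigment image is rank-1 and
   is rejected rather than silently mis-decomposed.
2. **Shading removal.** Every pixel's density is written exactly as
   `origin + u·b_u + v·b_v + s·ℓ` by solving the 3×3 system — an *oblique*
   projection along `ℓ` onto the plane, exact to machine precision. It is
   orthogonal only in the special case `ℓ ∥ normal`.
3. **Pigment axes.** Within the 2-D plane coordinates the two concentration
   fields are the statistically independent sources; fixed-point ICA with a
   tanh contrast and deflation finds them. Numerical details: symmetric
   whitening; the first component starts at the global maximum of the
   log-cosh negentropy proxy on a 180-point angle grid (in 2-D the contrast
   landscape is a single angle, so a global scan is cheap and removes any
   dependence on the starting point); the plain fixed-point update can enter
   a period-2 oscillation on some inputs, so the stabilised (Newton,
   step-halving) form takes over whenever the iteration stops contracting;
   tolerance 1e−8, at most 500 iterations, two further seeded restarts, best
   solution by summed |excess kurtosis|. Non-convergence raises with
   iteration diagnostics; near-Gaussian plane coordinates trigger a warning
   since ICA directions are then unstable.
4. **Ambiguity resolution.** ICA leaves sign, scale and order free. Scale:
   lifted 3-D directions are unit-normalised, the scale moving into the
   concentrations. Sign: a pigment absorbs, so each lifted density direction
   must point toward darkening (positive component sum). Order: the
   direction with the larger G-to-R density ratio is labelled hemoglobin
   (hemoglobin absorbs green strongly; that is what makes inflamed skin
   red), the other melanin.
5. **Bias and projection.** The bias point is placed at the per-axis minimum
   (configurable percentile) of the projected concentrations, flooring
   concentrations at zero; a 2×2 solve then yields `m`, `h` per pixel.
   Negative values are kept in the returned maps for diagnostics and clamped
   to zero only when concentrations are handed to calibration.

## Calibration

A patch is a pair of pigment concentrations; the grid is the full cross
product of 30 equally spaced levels per pigment over a configurable range
(default [0, 1]) — 900 patches. Each concentration has an RGB encoding
`exp(−(c·w + bias))` and a CMYK target obtained through a pluggable colour
transform. The default transform is the naive under-colour-removal formula
(`K = 1 − max(R,G,B)`, chromatic inks renormalised by `1 − K`); a
profile-based transform can be substituted where a real press profile is
available.

Hardware-free measurement: patch CMYK targets are "printed" by a virtual
press — per-channel ink density vectors, layered transmittance over a white
reflector, the deeper hemoglobin layer down-weighted (0.8) for the partial
masking a scattering stack produces — and the observed colour is decomposed
against the pigment basis. The measured per-layer RGB encoding is the
observed density minus the *other* layer's nominal contribution and the
bias; the cross-talk this retains (the other layer's deviation from nominal
plus the out-of-plane press residual) is what makes the three log-RGB
channels per layer informative rather than collinear. The nominal grid
itself, by contrast, is exactly collinear per layer (all three log channels
are linear in the one concentration), and the regression fitter rejects it
with condition diagnostics.

Estimators, all mapping the 6-vector (melanin RGB ⊕ hemoglobin RGB) to the
8-vector of layer CMYK values, all clamped to [0, 1]:

* **LUT** — nearest stored patch by root-mean-square feature distance, ties
  to the lowest patch index. Exact hits return the stored CMYK unchanged.
* **Regression** — per output channel and layer, ordinary least squares of
  `D_i = a_R log R + a_G log G + a_B log B + b` (a per-channel intercept:
  each channel is its own regression). Log features are guarded at 2⁻¹⁶.
* **Neural network** — per layer, a fully connected 3→20→30→20→4 network
  (ReLU hidden activations, 1414 trainable parameters), trained with Adam
  (step 1e−3, batch 32, mean-squared error, 30 epochs by default) on
  standardised inputs, seed-deterministic, loss curves recorded.

Leave-one-out cross-validation reports the overall RMSE over all held-out
CMYK components and the per-patch RMS errors; for the LUT the n-fold loop
collapses to a self-excluded nearest-neighbour scan. Methods are compared
with a two-sided *paired* t-test on the matched per-patch errors (LOOCV
yields matched pairs; an unpaired test would waste that structure) at
α = 0.05; identical error vectors short-circuit to p = 1 with a degeneracy
flag.

## Halftoning and the layer stack

Each CMYK channel is binarised independently by Floyd–Steinberg error
diffusion: plain raster scan, threshold 0.5 (ties fire a dot), error pushed
7/16 right, 3/16 down-left, 5/16 down, 1/16 down-right, off-image targets
dropped, accumulated values never clamped before thresholding. Only the
largest dot size is used — even ink deposition matters more than tonal
resolution when layers are stacked. Channels are resampled to the printer's
anisotropic grid (nearest neighbour, so concentration boundaries survive)
*before* halftoning so the dot statistics live on the device raster.

The job is the fixed top-to-bottom stack clear₁ / melanin / clear₂ /
hemoglobin / clear₃ / white. The colored layers are always a single physical
layer (concentration is carried by area gradation, i.e. the dot pattern);
the white base plays the role of paper; clear spacers modulate apparent
pigment depth, with thickness expressed only as a sublayer count (physical
thickness per sublayer is device-dependent and recorded as metadata).
Crossing clear₂, clear₃ ∈ {2, 4, 6} enumerates the nine standard sample
configurations in grid order. Jobs serialise as one 1-bit PNG per ink
channel plus a versioned JSON manifest (layer order, kinds, sublayer counts,
dims, dpi, config hash) and round-trip losslessly.

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated:

* **Phantoms.** `gradient` (orthogonal ramps) and `blobs` (Gaussian
  hemoglobin spots) are structural fixtures. `palm_like` is the realistic
  one: each pigment field is a smooth base (Gaussian-filtered noise, sd 10 %
  of the image) plus abundant sparse fine-scale texture — blurred
  exponential-amplitude spots (freckle-like for melanin, amplitude 0.28,
  capped at 5× scale; mottling for hemoglobin) and five sinusoidal vessel
  ridges — plus a smooth shading field (amplitude ≈ 0.08 with a gentle
  radial falloff). Fine-scale texture is not decoration: blind source
  separation needs many effectively independent samples, and a field built
  from a few smooth modes has so few that ICA directions are
  unidentifiable. The texture contrast is set so that the *ideal* inverse
  (known basis) retains r ≈ 0.96 at sensor noise σ = 0.005 — recovery
  experiments then measure estimation error rather than an arbitrary
  signal-to-noise choice. The spot amplitude cap matters too: unbounded
  tails create isolated very dark pixels whose density noise (σ/ρ) is huge.
* **Sensor noise** is i.i.d. Gaussian in reflectance, seed-deterministic.
* **The virtual press** is the hardware stand-in for printing and
  photographing patches: smooth, monotone (more ink never brightens any
  channel) and injective over the patch grid (the layer depth-weighting
  breaks the melanin/hemoglobin sum symmetry).

What the generator does *not* emulate: camera optics and demosaicing,
specular residue, ink dot gain and bleed, clear-layer scattering, spatially
correlated sensor noise. Passing recovery tests on these phantoms therefore
demonstrates the correctness of the algorithms under the stated model, not
performance on any particular camera/printer pair — the calibration stage
exists precisely because real devices deviate from the model.

## Problem sizes and numerical choices

Recovery experiments run on 128×128 phantoms (16 384 pixels gives ICA
stable higher-order statistics while keeping a 20-seed noisy experiment
interactive); calibration uses the full 900-patch grid everywhere except
the network LOOCV smoke test, which runs on a reduced grid since 900
network retrainings are slow and add nothing over the regression case.
End-to-end determinism is checked at 96×96 with the 2×/3.33× anisotropic
upsample. Oblique decomposition and concentration projection are exact
linear solves; the 2×2 projection rejects condition numbers above 1e8; the
regression fitter rejects design condition numbers above 1e10.

## Known limitations

* The default absorbance vectors are plausible shapes, not measured spectra;
  nothing downstream depends on their exact values, and recovery tests
  compare only against whatever basis generated the data.
* With one pigment entirely absent the colour plane is rank-1 and the
  labelling of the second ICA axis is undefined; the pipeline rejects the
  former and cannot be expected to label the latter.
* The ICC-profile colour transform of a production press is replaced by the
  naive UCR formula; the transform is pluggable.
* LOOCV error magnitudes on the virtual press are smaller than on a
  physical print-photograph loop, whose noise and model mismatch are larger
  than the virtual press emulates. Relative comparisons between estimators
  are meaningful; absolute RMSE values are not transferable to hardware.
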