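# Methods

## Model

The network is a two-layer hierarchical generative model with convolutional
structure (weight sharing stands in for retinotopy).  Layer 1 explains the
image through a bank of `M_s` unit-norm 7×7 kernels `W_S`; layer 2 explains
the *pooled* first-layer response through `M_c` unit-norm 4×4 kernels `W_C`.
Both layers use stride 1 and non-negative activities.  The objective

    F = ½‖x − W_Sᵀγ_S‖² + ½‖p_S(γ_S) − W_Cᵀγ_C‖² + λ_S‖γ_S‖₁ + λ_C‖γ_C‖₁

is minimised in two nested senses: over activities (inference, per image
batch) and over kernels (learning, across batches).  The coupling term makes
inference *predictive*: the second-layer prediction error is routed back to
layer 1 through the argmax switches recorded by the pooling forward pass
(unpooling).  This feedback is what lets a feature-space pooling reorganise
the first-layer dictionary into an orientation map; with
`feedback_enabled=False` the first-layer update ignores the top-down error
and only the γ_C update sees the second layer.

Assumptions worth stating: the model is rate-based and has no temporal
dynamics (a "response" is the converged activity to a static frame);
convolution implies exact weight sharing; max-pooling is winner-take-all,
not energy pooling; the ℓ1 penalty is a convex surrogate for a hard
sparseness budget.

## Inference

Inference is proximal-gradient descent with the non-negative soft-threshold
prox, alternating block updates (γ_S, then γ_C with refreshed errors).
Pooling switches are recomputed every iteration — the pooling is part of the
forward model, not a fixed routing.  Design choices:

* **Step size.** `inference_step="auto"` uses 0.9/L per layer, where L is
  the squared spectral norm of the layer's convolutional operator (20 power
  iterations) plus, for layer 1, the worst-case overlap multiplicity of the
  pooling switches (the norm bound of the selection map).
* **Acceleration.** Plain ISTA needs hundreds of iterations at these
  overcompleteness levels (L ≈ 40–50 for the first layer), so updates are
  Nesterov-accelerated.  Under the auto step rule every iteration is
  loss-checked: if a switch flip (the one place the descent bound can fail)
  or the extrapolation raises F, the momentum is restarted and the step
  backtracked, so the recorded loss trace is non-increasing by construction.
  The training/probing hot path uses a leaner variant that tracks the
  objective at the extrapolated point and restarts on increase, with
  step-halving only if an unaccelerated step still rises (a stale Lipschitz
  estimate between refreshes).
* **Stopping.** Relative loss change below `inference_tol` (default 1e-4,
  1e-3 at reduced scale) or `inference_max_iters` (default 200; 20 during
  reduced-scale training, 60 during probing).
* **Initialisation.** Activities start at zero for every batch; kernels are
  i.i.d. standard normal, renormalised to unit norm.
* **Degenerate inputs.** An all-zero image has the zero code as a fixed
  point; a user-chosen oversized step raises a convergence error naming the
  step size rather than returning garbage.

## Learning

Kernels follow the activity/error correlation (a product of pre- and
post-synaptic rates, i.e. Hebbian in form): `W ← W + (ω/B)·(γ ⋆ ε)` with
momentum β on the update velocity, then each kernel is rescaled to unit
Euclidean norm.  ω = 0.01, β = 0.9.  The gradient is averaged over the
batch; because kernels are renormalised the division by B only rescales the
effective step.  A kernel whose update collapses to zero norm is kept at its
previous value and flagged.  The sparsity penalties ramp linearly from 0 to
their target (0.1) over the first half of training, then stay constant; the
ramp matters — with λ_C at full strength from the start the second layer
never activates and `W_C` receives no gradient.

## Input statistics

Training inputs are whitened with the retina-style filter
`f·exp(−(f/f_c)⁴)`, `f_c = 0.4 × Nyquist` (the standard sparse-coding
preprocessing), then each image is contrast-normalised into [−1, 1].
Per-image (not batch-global) normalisation is deliberate: with batch-global
scaling the typical contrast is so low relative to λ = 0.1 that the second
layer is silenced entirely.  Probe sequences are whitened with the same
filter but scaled by a single factor per sequence, because the
frame-to-frame amplitude modulation is exactly what F1/F0 measures.

The synthetic image generator composes randomly oriented, randomly placed
hard-edged bars (uniform orientations on [0°, 180°), lengths size/4–size,
widths 0.6–1.8 px, both polarities) over 1/f background noise, zero mean
per image.  It emulates the two statistics the model depends on — an
approximately 1/f amplitude spectrum (measured log-log slope ≈ −1.15) and
sparse oriented structure — and is seed-deterministic.  It does **not**
reproduce occlusion, curvature, textures, luminance distributions or
long-range contour correlations of photographs; passing tests therefore
show that the pooling/feedback mechanism works on natural-like second-order
statistics, not that the learned dictionaries match those from natural
scenes in detail.

## Geometry

Composite receptive fields follow the standard recursion
`r ← r + (k − 1)·jump`.  At the reference architecture (7×7 conv, 2×2/2
pool, 4×4 conv) both layers see 14×14 input pixels for a second-layer unit
(7 px for layer 1).  Zero padding before the spatial pooling is chosen
per input size as the smallest symmetric padding making the strided window
arithmetic exact; padding does not change receptive-field size.  The
feature poolings need channel counts compatible with their topology
(perfect squares for the toroidal grid), which the layer sizes
{36, 49, 64, 81, 100, 121} satisfy.

## Measurements

* **Optimal parameters.**  Each unit's probe optimum (orientation,
  frequency) is found the way an experimenter would: a grating battery over
  a (θ, f0) grid is presented drifting at a few phases and the argmax of
  the unit's peak response is taken.  This is robust for second-layer units,
  whose image-space receptive fields are only available through the
  (noisier) linear back-projection `V_c* = argmin ½‖x − V_cᵀγ_C‖²`
  (ridge 1e-3, conjugate gradients with FFT convolution operators on ~120
  images).  Log-Gabor fits of the kernels (layer 1) and of `V_c*` (layer 2)
  provide the map quantities: preferred orientation and phase per unit, and
  the bandwidth-derived HWHH.  The log-Gabor model is a log-normal radial ×
  Gaussian angular frequency envelope; phase and amplitude come from
  projecting the kernel on the quadrature pair, and the fit is coarse-grid
  search refined by Nelder–Mead.
* **Tuning curves.**  Each unit is probed with a 14-px-diameter masked
  sinusoidal grating at its (quantised) optimal orientation and frequency:
  32 phases over 360° (drift) or 32 orientations over 180° (rotate), one
  converged inference per frame, response read at the spatial position of
  the unit's maximal response over the sweep.  Units sharing a quantised
  optimum share one inference pass.  F1 is taken at one cycle per sweep for
  both protocols; the 180° rotation cycle is a convention (orientation is
  π-periodic).
* **Classification.**  Simple if F1/F0 > 1.  Units with zero mean response
  under either protocol are excluded from the percentages and counted as
  non-responsive.  χ is also obtained by fitting the rectified sinusoid
  directly (multi-start least squares); χ and F1/F0 are linked by the
  closed-form mapping implemented in `chi_to_f1f0` (checked to 1% across
  χ ∈ [−3, 0.9] by the test suite).
* **Maps.**  LHI uses σ = 1 unit on the declared feature topology (ring or
  torus), Gaussian truncated at 3σ, normalised by the truncated window
  weight.  Pinwheels are strict 3×3 toroidal local minima with LHI < 0.2;
  density is pinwheels per column-sized patch, `ρ = n/(M_s/c)` with
  `c = (180°/mean HWHH)²` (the per-column-area reading; the alternative
  grouping is available behind a flag).  HWHH for this purpose comes from
  the rotating-grating curve (half width at half of peak minus baseline);
  the log-Gabor bandwidth-derived HWHH is reported alongside.
* **Population statistics.**  R percentages over responsive units; χ
  summarised as median ± MAD; paired one-tailed Wilcoxon signed-rank test
  of χ_φ < χ_θ; OLS regression of HWHH on LHI with the raw slope p-value
  (no multiple-testing correction — one regression per network).

## Reduced scale

The reference training scale (96×96 natural images, batch 32, 28 125
iterations) is impractical for routine CPU runs, so the package's
`reduced` scale uses 24×24 synthetic images, batches of 8–10, 1 000–3 000
iterations, 15–20 accelerated inference iterations per batch (tolerance
1e-3) and 36+36 units, with the λ ramp over the first 20 % of training so
that most of the run happens at full sparsity, where the map-organising
competition acts.  24 px was chosen because its FFT sizes are fast and the
resulting map chain (γ_S 18×18 → pooled 9×9 → γ_C 6×6) supports every
pooling variant.

What this scale does and does not show.  The robust phenomena reproduce:
every first-layer unit is simple (F1/F0 ≈ π/2); spatial pooling alone
leaves second-layer units orientation selective; feature pooling plus
feedback raises the first-layer map smoothness (LHI) above both the
spatial-only network and the feedback-ablated control; and the χ
distribution under drifting gratings sits well below the one under
rotating gratings (paired signed-rank p < 0.05).  The *asymptotic*
percentages do not fully reproduce: the fraction of complex cells under
combined spatial+ring pooling reaches roughly half the population rather
than all of it, because the feature-ring organisation that makes every
unit phase invariant is still partial at a few thousand updates (the
reference runs used ~28 000 and show the maps emerging gradually).  For
the same reason the feature-only network transiently shows a few
complex-like units: with an unorganised phase map, a 2×2 feature window
pools quadrature-like random phases; full-length training organises both
the orientation and the phase map, making windows phase-coherent and
removing that invariance.  Only a minority of second-layer units respond
to masked gratings at all at this scale; percentages over responsive
units are correspondingly coarse.

## Known limitations

* Non-convexity: the joint problem (activities × kernels × max switches) is
  non-convex; different seeds give different dictionaries, and the descent
  guarantee applies to inference at fixed kernels only.
* Small populations at reduced scale make the R percentages coarse
  (1 unit ≈ 3 %), and a minority of second-layer units stay silent to
  grating probes (they are excluded, as in the experimental convention).
* The single-precision training path limits loss reproducibility to
  bit-identity on the same BLAS/FFT builds, not across platforms.
* The STL-10 loader is provided but optional; no result in the repository
  depends on external data.
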