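# Methods

This note documents the models, procedures, and numerical choices behind
`veiscope`, in the order a study runs them.

## Stimulus space and standardization

All stimuli are grayscale grids, by default 36 rows × 64 columns at
2°/pixel, in a unitless z-score-like intensity space. Every synthesized or
screened stimulus is repeatedly projected onto a fixed intensity budget —
mean 0 and RMS contrast 0.25 (the standard deviation of pixel intensities) —
and clipped to ±1.0 after the projection. The RMS target keeps synthetic
stimuli inside the contrast regime a predictive model is trained on; the clip
bound emulates a display's finite range and is chosen so that at most ~1% of
pixels of a standardized naturalistic image clip. Because clipping follows
the moment matching, post-clip moments can drift slightly (mean by ~1e-4,
RMS by a few percent on heavy-tailed inputs); tests account for that.

## Analytic model neurons

A simple cell responds with `max(0, ⟨I, G⟩)`, the rectified inner product of
the stimulus with a 2D Gabor filter

    G(x, y) = exp(−((x−μx)² + (y−μy)²) / 2σ²) · cos(2π(x cosθ + y sinθ)/λ + ψ),

with coordinates in degrees about the grid center. A complex cell follows the
classical energy model: `sqrt(a² + b²)` over a quadrature pair (ψ and
ψ + π/2), which makes it exactly invariant to the phase of a preferred
grating. Populations are sampled with θ ~ U[0, π), ψ ~ U[0, 2π),
σ ~ U[4.4°, 10.9°] (matched to mouse V1 L2/3 receptive-field sizes) and
λ ~ U[σ, 2σ] degrees/cycle, which enforces the constraint λ ≤ 2σ so the
envelope holds at least about one full carrier cycle.

One deliberate deviation from textbook rectification: below threshold, the
simple cell's `grad` returns the gradient of the underlying linear drive
rather than zero. Ascending the drive is the only direction that can ever
re-activate the cell, and without it activation maximization would stall on
roughly half of all random initializations.

Poisson response sampling uses a default gain of 10 spikes per unit response,
putting strongly driven cells in the tens-to-hundreds-of-counts regime where
noise is informative but not overwhelming.

## MEI synthesis and the receptive-field mask

The most exciting input (MEI) is found by 1,000 steps of plain gradient
ascent (learning rate 1.0) from Gaussian white noise, with the gradient
blurred by a σ = 1.0 Gaussian at every step (suppressing high-frequency
artifacts, at the cost of a deliberate smoothness bias) and the image
re-standardized after every step. On a noiseless simple cell this recovers
the constrained optimum — the standardized, clipped projection of the
generating Gabor — with correlation ≈ 0.86 and ≥ 85% of its activation; the
residual gap is the blur bias, which we keep because it is part of the
stated procedure.

The receptive-field mask is extracted from the MEI by |z| > 1.5 thresholding
of the pixel z-scores, binary closing, keeping the largest connected
component, taking its convex hull, and smoothing with a σ = 1.5 Gaussian;
the result is a weighted mask in [0, 1].

## VEI synthesis (diverse exciting inputs)

Twenty images are initialized as the MEI plus Gaussian noise (s.d. 0.05) and
jointly optimized to minimize

    L = (1/n) Σᵢ max(c − rᵢ/r_MEI, 0) − λ · minᵢⱼ d(Iᵢ, Iⱼ),   c = 0.85,

where d is the Euclidean distance weighted by the (non-binarized) MEI mask.
The minimum (not mean) pairwise distance is regularized so the optimizer
always pushes apart the currently closest pair instead of forming clusters.
Schedules follow the stated procedure: 3,000 iterations, learning rate 1,000
dropping to 100 at iteration 2,000, blurred gradients, per-step
standardization. The run is repeated over a log-spaced grid of 8 diversity
weights λ ∈ [1e−4, 5e−2] and the set from the largest λ whose minimum
activation ratio still meets the floor is selected.

Because the push-pull equilibrium of the joint loss tends to settle
marginally below the floor (minimum ratios ~0.845 at exactly the λ where
phase diversity emerges), the optimizer ends with a short activation-only
cleanup phase (up to 200 iterations) that lifts any stragglers back above
the floor with minimal displacement. This enforces the constraint the loss
expresses; with it, complex-cell VEIs cover all four phase quadrants at the
selected λ while the floor holds exactly.

A noteworthy property of *noiseless linear-rectified* cells: the constraint
⟨I, G⟩ ≥ 0.85·r_MEI leaves √(1−0.85²) ≈ 53% of the RMS budget free in the
orthogonal complement of the filter, much of it smooth and inside the mask.
A correct optimizer finds this freedom, so analytic simple-cell VEIs do not
collapse onto the parametric (Gabor-family) lower bound — their mean pairwise
distance sits well above it. Trained predictive models do not extrapolate
exact linearity into that orthogonal cap, which is why simple cells modeled
through twins (and recorded neurons) show much lower diversity.

## Diversity index and its calibration

The diversity of a VEI set is its mean pairwise masked distance d. The index

    D = (d − d_lower) / (d_upper − d_lower)

is anchored at reference populations of noiseless simple (D = 0) and complex
(D = 1) cells. Reference VEIs are found independently of the gradient
optimizer, by exhaustive search over a dense standardized Gabor stimulus
bank (16 orientations × 32 phases × 5 wavelengths × 5 envelope positions per
cell; the phase axis is denser than the other axes because phase-selective
cells otherwise admit fewer than 20 stimuli at the 85% floor). Among
admissible stimuli (response ≥ 85% of the bank maximum), 20 are selected
greedily to maximize the minimum pairwise distance. The bank is standardized
but *not* clipped: clipping re-couples pairwise distance to envelope size
and destroys the parameter-independence of the reference distances (the
population coefficient of variation is ~4% for simple and ~2% for complex
cells without the clip, ~15% with it).

## Digital twins

The twin is an LN-LN subunit cascade fitted per cell in three steps:

1. **Receptive-field localization** by reverse correlation with isotropic
   bandpass energy maps (frequency band and position), followed by a local
   oriented grid search scoring each (θ, λ) candidate by the joint fit of
   its quadrature outputs and local energy to the response.
2. **Subunit bank**: quadrature Gabor patches at two envelope scales (0.6λ
   and 0.35λ — about 1 and 1.8 octaves of bandwidth, echoing a multi-scale
   readout) on a 2-pixel position grid covering the estimated field.
3. **Readout fit**: per position, four rectified channels (±cos, ±sin) and
   one local energy channel feed a readout trained by Adam on the Poisson
   loss (1/m) Σ (r̂ − r log r̂), with an ELU + 1 output so the rate stays
   positive and decoupled weight decay (5e−3 per step) on the coefficients.
   The decay matters beyond regularization: the channel basis is collinear
   in distribution (relu(z) − relu(−z) equals the linear output), and weight
   left in near-null directions by an unconverged fit is exactly what
   gradient synthesis later exploits off-manifold; with the decay, the
   twin's MEI transfers to the generating cell at several times its best
   naturalistic response. The subunit kernels are fixed, so the fit is a
   well-behaved generalized linear problem; members of an ensemble differ
   only in readout initialization.

Training stimuli mix naturalistic 1/f images with flatter-spectrum
(exponent 0.3) probes; pure 1/f pools carry almost no power at near-Nyquist
carriers, leaving such cells unidentifiable. Held-out correlations with the
generating cells are typically 0.94–0.99 (simple) and 0.7–0.97 (complex);
cells whose twins miss a 0.4 correlation floor are excluded from population
analyses, mirroring the exclusion of unreliable or poorly predicted neurons
in vivo.

The subunit twin matters scientifically, not just practically: through the
*exact* analytic cells, a fixed-subfield pattern and a shifting texture
combine inside one global inner product (simple) or one global quadrature
sum (complex), so their phases interfere and partial-texture composites lose
activation for both classes alike. A trained, spatially pooled model adds
subfield contributions locally — the property that makes the bipartite
parameterization meaningful. The simulated-population bipartite results are
therefore computed through twins, with the analytic cells as ground truth
for everything the twin is checked against.

## Bipartite parameterization and the BII

Texture-based VEIs are composites `m_V · crop(T) + m_F · MEI`. The variable
subfield series is grown from the pixel-variance map across the
nonparametric VEIs (fractions 0.20–0.60 of total variance in steps of 0.05
at full scale, 0.1 at desk scale); the fixed subfield is the in-mask
complement. Per series member, the canvas T (the m_V bounding box dilated by
50% per side) is first optimized to maximize the mean response over random
crops, then jointly refined under the VEI loss with the composites as the
optimization variables' images (fixed crop offsets, canvas-scale learning
rates 200→20 — gentler than the image-space schedule because all twenty
crop gradients funnel into one shared canvas). Rendered sets share one
affine standardization so fixed-subfield pixels are bit-identical across
the set.

All in-silico activation ratios use the masked, re-standardized MEI as the
reference response — the same uniform presentation protocol applied to every
stimulus — otherwise model response to content outside the mask hull imposes
a spurious ceiling on every composite.

VEIs_partial are the member maximizing the harmonic mean H = 2r̄d̄/(r̄+d̄) of
activation and diversity, each normalized by its maximum over the series.
The bipartite invariance index is the trapezoidal area (101 uniform points)
under a quadratic smoothing spline of clamped activation ratio versus
variable-subfield relative area (masks binarized at 0.3), with the series
anchored at size 0 (pure MEI, ratio 1) and size 1 (the full-texture model).
The spline's smoothing parameter is chosen by leave-one-out error over the
series. Both anchor points and the use of ratios (rather than raw
activations) are our resolutions of genuinely open details, documented here.

Controls: the two-variable-subfield model optimizes an independent texture
for each subfield (each optimized with the other filled by MEI content); the
no-spatial-division model mixes a full-field texture with the MEI at weights
(1−c, c) over a grid of c ∈ [0, 1], with spline interpolation providing
activation-at-matched-diversity and diversity-at-matched-activation
comparisons. Subfield manipulations mask one subfield with a binary mask
whose edge smoothing is restricted to regions outside the kept subfield, or
swap content with moment-matched natural crops / another neuron's texture.

Subfield frequency preference uses the radial power spectrum in ten
equal-width bins up to Nyquist (mean power per annulus, DC excluded), with
the median frequency interpolated from the cumulative binned power; the
comparison set substitutes the fixed-subfield content with texture crops, so
the difference in median frequency is attributable to that subfield.

## Segmentation alignment

The ternary bipartite mask is +1 on the binarized (0.3) variable subfield,
−1 on the rest of the binarized MEI mask, 0 outside. The matching score
against an object/background segmentation is s = Σ(bip·seg)/Σ|bip|,
affinely rescaled to [0, 1] so that 1 means the variable subfield coincides
with the object and 0 the perfect reversal (the raw value is also exposed).
Grating scenes composite contrast-matched object and background gratings
through a σ = 1.5 blurred segmentation boundary, with wavelengths drawn from
a high band (5.83–15.55 °/cycle) and a low band (15.55–58.3 °/cycle).
Boundary crops require at least 20% of both object and background within the
receptive field (10%/30% variants supported).

## Connectomics statistics

Pairwise metrics are re-centered per presynaptic neuron (value − presyn mean
+ global mean), which preserves within-presyn order and the grand mean.
Synapse counts are adjusted by each presynaptic neuron's conversion rate
(total synapses / total co-travel over its connected and ADP pairs):
adjusted = observed − expected + regional rate × co-travel, conserving the
total count. Conversion-rate curves use equal-count octile bins of the
metric among connected pairs by default, keep a bin only if it holds
strictly more than 10 connected pairs and ≥ 2.5% of all connected pairs, and
attach bootstrap standard deviations from resampling pairs with replacement.
The exponential fit y = a·exp(−bx) + c is least-squares with both decaying
and growing initializations (the better SSE wins) and R² about the mean of
y; constant data return R² = 0 by that convention. The weighted bootstrap
difference-of-means test resamples each group with its sampling weights
(adjusted synapse counts for connected pairs, co-travel for ADP controls);
the two-sided p is floored at 1/n_resamples. A Poisson regression with
presynaptic fixed effects stands in for a mixed model with random
intercepts; with ~20 presynaptic neurons the fixed-effect version is the
standard small-sample simplification.

## Synthetic fixtures and what they do not emulate

The 1/f-spectrum image pool reproduces only the second-order statistics of
natural scenes — no phase structure, objects, or occlusions — so screening
tests demonstrate mechanics (ranking, distance filters), not ecological
claims. Blob segmentation masks are thresholded smoothed Gaussian fields
with a single 4-connected object occupying 20–80% of the frame. The planted
bipartite neuron multiplies a softplus-gated fixed-template match with the
rectified maximum over integer shifts of a high-frequency texture template
(shifted templates are unit-normalized inside the subfield so every shift is
exactly as excitable — shift tolerance by construction); the softplus keeps
gradients alive for synthesis. The synthetic connectome plants like-to-like
log-odds (β = 2), an invariance hierarchy (Δ = 0.15), and an exponentially
decaying conversion rate (rate 2 per diversity unit) at the scale of ~20
presynaptic and ~500 postsynaptic neurons.

## Problem sizes

The default population studies use 60 cells per class for diversity
calibration and 20 per class for the bipartite study; twins train on 1,000
mixed-spectrum images with a single-member ensemble and shortened schedules
(VEI 300 + 80 cleanup iterations at a single diversity weight — the
bipartite study consumes the VEIs only through their variance pattern —
texture 60 steps, refinement 40 iterations at λ = 1e−4). These are the
package's desk-scale choices; every schedule is configurable upward, and
`BIIStudyConfig` documents them in one place.

## Known limitations

- The twin is a single-layer subunit cascade. It reproduces local additivity
  and partial shift tolerance, but not the deeper pooling of a multi-layer
  network. BII medians computed through it land near 0.6–0.7 for both
  simulated classes with substantial seed-to-seed scatter, rather than
  separating them as deep twins do: complex-cell composites still lose
  activation at subunit scale in mid-size members, and simple-cell twins
  inherit some spurious tolerance from weight spread across correlated
  neighboring subunits. The class ordering is preserved on average but is
  not stable at 20-cell scale.
- Analytic linear-rectified cells possess a large exactly-invariant
  orthogonal cap that no recorded neuron exhibits; properties tied to
  simple-cell VEI collapse hold only through twins, not through the
  analytic cells.
- Gradient-based syntheses carry the smoothness bias of blurred gradients;
  reported activations are optimizer outputs, not global optima.
- The bootstrap difference test assumes exchangeability within groups; the
  per-presyn corrections remove only first-order presynaptic heterogeneity.
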