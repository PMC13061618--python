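# veiscope

An in-silico toolkit for characterizing the invariances of visual neurons.
Given any differentiable model of a neuron — built-in analytic Gabor simple
cells and energy-model complex cells, a digital twin fitted to recorded
responses, or any user predictor exposing `respond`/`grad` — `veiscope`
synthesizes its most exciting input (MEI), a set of maximally diverse
exciting inputs (VEIs), and quantifies what kind of invariance those inputs
reveal. It is written for computational and systems neuroscientists studying
receptive-field organization in early visual cortex.

## What it computes

**VEIs.** Starting from the MEI, twenty images are jointly optimized to
minimize

```
L = (1/n) Σᵢ max(c − rᵢ/r_MEI, 0) − λ · minᵢⱼ d(Iᵢ, Iⱼ),     c = 0.85,
```

so each image keeps at least 85% of the MEI response while the set is
maximally mutually dissimilar (masked pixel distance d within the
receptive-field mask). The spread of a neuron's VEIs *is* its invariance.

**Diversity index.** `D = (d − d_lower)/(d_upper − d_lower)`, the mean
pairwise VEI distance affinely normalized between noiseless simple cells
(D = 0, no invariance) and noiseless complex cells (D = 1, full phase
invariance), calibrated by exhaustive search over a dense Gabor stimulus
bank.

**Bipartite invariance.** VEIs are re-parameterized as
`m_V·crop(T) + m_F·MEI` — a variable subfield tolerating crops of an
optimized texture canvas T plus a fixed subfield holding MEI content — over
a series of subfield sizes grown from the VEIs' pixel-variance map. The
bipartite invariance index (BII) is the area under the spline-fit curve of
activation versus variable-subfield size; the harmonic mean of activation
and diversity selects the partial-texture VEIs. Control parameterizations
(two variable subfields; no spatial division) and subfield manipulations
(masking, content swaps, radial-frequency comparison) probe necessity and
specificity.

**Segmentation alignment.** A ternary bipartite mask (+1 variable subfield,
−1 fixed) is scored against object/background segmentations with a matching
score in [0, 1] (1 = variable subfield on the object, 0 = reversed), with
grating-scene composition and crop screening utilities.

**Functional connectomics.** Pairwise-table statistics: per-presynaptic
corrections of functional metrics and synapse counts, synapse-conversion-rate
curves with bootstrap bands, weighted bootstrap group comparisons, and
exponential-decay fits.

Digital twins (LN-LN subunit cascades trained on the Poisson loss) and
synthetic fixtures (1/f image pools, blob segmentations, a planted
bipartite ground-truth neuron, synthetic connectome tables) make every
stage testable offline. See `docs/methods.md` for models, assumptions, and
numerical choices.

## Worked example

```python
import numpy as np
from veiscope import (GaborParams, SynthesisConfig, make_complex_cell,
                      synthesize_mei, synthesize_veis,
                      calibrate_diversity_bounds, diversity_index)

cell = make_complex_cell(GaborParams(sigma=6.0, wavelength=10.0,
                                     theta=0.3, phase=1.0))
config = SynthesisConfig(seed=1)
mei = synthesize_mei(cell, config)
veis = synthesize_veis(cell, mei, config)
print(f"MEI activation      {mei.activation:.1f}")
print(f"min VEI/MEI ratio   {veis.meta['min_activation_ratio']:.3f}")
print(f"selected lambda     {veis.lambda_used:.0e}")
print(f"mean pairwise dist  {veis.mean_pairwise_distance:.1f}")

calib = calibrate_diversity_bounds(n_cells=10, seed=0)
print(f"diversity index     {diversity_index(veis.mean_pairwise_distance, calib):.2f}")
```

prints

```
MEI activation      31.5
min VEI/MEI ratio   0.850
selected lambda     5e-02
mean pairwise dist  15.1
diversity index     0.98
```

Every VEI of the energy-model cell keeps ≥ 85% of the MEI response while
the set spans the phase circle; its diversity index lands at the complex-cell
anchor (≈ 1), exactly as the energy model's phase invariance predicts. The
same calls run unchanged on a fitted digital twin
(`fit_digital_twin(...).as_neuron()`).

A thin CLI wraps the same library calls:
`veiscope vei --kind complex --seed 1 --out out/`,
`veiscope bipartite ...`, `veiscope connectomics ...`,
`veiscope fixtures ...` (see `veiscope --help`).

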