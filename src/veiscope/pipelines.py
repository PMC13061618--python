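"""End-to-end study pipelines composing the library modules.

These are the canonical experiment recipes: simulate analytic cells, fit
digital twins to their noisy responses, synthesize MEIs and VEIs, and push
the results through the diversity and bipartite-invariance analyses. Problem
sizes are parameterized so the same recipe runs at exploratory or full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bipartite import bipartite_analysis
from .models import ModelNeuron, sample_poisson_responses, simulate_cells
from .synthesis import SynthesisConfig, synthesize_mei, synthesize_veis
from .synthetic import naturalistic_images
from .twin import fit_digital_twin


@dataclass
class BIIStudyConfig:
    """Problem sizes for the simulated-cell bipartite-invariance study.

    Defaults are the desk-scale settings: 20 cells per class, twins trained
    on 1,000 mixed-spectrum synthetic images, a single diversity weight and
    shortened optimization schedules. The procedures are identical to the
    full-scale ones; only iteration counts and grid densities differ.
    """

    n_cells: int = 20
    n_train_images: int = 1000
    gain: float = 10.0
    n_members: int = 1
    vei_iters: int = 300
    cleanup_iters: int = 80
    #: a single diversity weight at the top of the usual grid: the bipartite
    #: study consumes the nonparametric VEIs only through their pixel-variance
    #: pattern, for which the most diverse admissible set is the informative one
    lambda_grid: tuple = (5e-2,)
    fractions: tuple = (0.2, 0.3, 0.4, 0.5, 0.6)
    texture_steps: int = 60
    texture_crops: int = 8
    refine_iters: int = 40
    refine_lambda: float = 1e-4
    twin_iters: int = 450
    subunit_stride: int = 3      # halves the subunit count at equal fit quality
    min_fit_corr: float = 0.4    # twin quality floor for inclusion
    oversample: int = 6          # extra cells sampled to absorb exclusions


def fit_twin_for_cell(cell: ModelNeuron, train_pool, heldout_pool,
                      gain: float, seed: int, n_members: int = 2,
                      **fit_kwargs):
    """Fit a digital twin to a cell's Poisson responses; return (twin, fit
    correlation on held-out images against the noiseless cell)."""
    noisy = sample_poisson_responses(cell, train_pool, gain=gain,
                                     seed=seed) / gain
    twin = fit_digital_twin(train_pool, noisy, n_members=n_members, seed=seed,
                            **fit_kwargs)
    truth = np.array([cell.respond(im) for im in heldout_pool])
    preds = twin.predict(heldout_pool)
    fit_corr = (np.corrcoef(preds, truth)[0, 1]
                if preds.std() > 0 and truth.std() > 0 else 0.0)
    return twin, float(fit_corr)


def twin_training_pool(n_images: int, seed: int):
    """Mixed-spectrum training stimuli: half naturalistic (1/f), half
    flatter-spectrum probes so near-Nyquist carriers stay identifiable."""
    half = n_images // 2
    return (naturalistic_images(half, seed=seed)
            + naturalistic_images(n_images - half, spectral_exponent=0.3,
                                  seed=seed + 1))


def simulated_cell_bii_population(kind: str, config: BIIStudyConfig,
                                  seed: int, verbose: bool = False):
    """Median BII over a population of simulated cells, via digital twins.

    For each analytic cell: sample Poisson responses to the synthetic image
    pool, fit a subunit twin, verify its held-out fit against the noiseless
    cell (cells whose twins miss the quality floor are excluded, as poorly
    predicted neurons are excluded in vivo), then synthesize the MEI and
    VEIs and run the bipartite series + BII pipeline on the twin.

    Returns (biis, fit_correlations) for the included cells.
    """
    rng = np.random.default_rng(seed)
    pool = twin_training_pool(config.n_train_images, seed=int(rng.integers(2**31)))
    held = naturalistic_images(200, seed=int(rng.integers(2**31)))
    cells = simulate_cells(config.n_cells + config.oversample, kind,
                          seed=int(rng.integers(2**31)))
    biis, fits = [], []
    for i, cell in enumerate(cells):
        if len(biis) >= config.n_cells:
            break
        cell_seed = int(rng.integers(2**31))
        twin, fit_corr = fit_twin_for_cell(
            cell, pool, held, config.gain, cell_seed, config.n_members,
            n_iter=config.twin_iters, subunit_stride=config.subunit_stride)
        if fit_corr < config.min_fit_corr:
            if verbose:
                print(f"  {kind} cell {i}: excluded (fit {fit_corr:.2f})")
            continue
        model = twin.as_neuron()
        syn = SynthesisConfig(seed=cell_seed, vei_iters=config.vei_iters,
                              lambda_grid=config.lambda_grid,
                              cleanup_iters=config.cleanup_iters)
        mei = synthesize_mei(model, syn)
        veis = synthesize_veis(model, mei, syn)
        result = bipartite_analysis(
            model, mei, veis, fractions=config.fractions, config=syn,
            n_steps=config.texture_steps, n_crops=config.texture_crops,
            n_render=20, n_refine_iters=config.refine_iters,
            refine_lambda=config.refine_lambda, seed=cell_seed)
        biis.append(result.bii)
        fits.append(fit_corr)
        if verbose:
            print(f"  {kind} cell {i}: fit {fit_corr:.2f} BII {result.bii:.3f}")
    return np.array(biis), np.array(fits)
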