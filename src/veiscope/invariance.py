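"""Diversity-index calibration and computation, representational similarity,
and greedy selection of natural VEIs.

The diversity of a VEI set is its average pairwise Euclidean distance within
the receptive-field mask. To place that raw distance on an interpretable
scale, the index is affinely normalized between two analytic reference
populations: noiseless simple cells (no invariance, index 0) and noiseless
energy-model complex cells (full phase invariance, index 1). Reference VEIs
are found by exhaustive search over a dense Gabor stimulus grid rather than by
gradient synthesis, so the calibration is independent of the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .images import (
    DEFAULT_DEG_PER_PIXEL,
    DEFAULT_SHAPE,
    as_array,
    pairwise_masked_distances,
    standardize,
)
from .models import ModelNeuron, sample_gabor_population, make_simple_cell, make_complex_cell
from .synthesis import MEIResult, VEISet, extract_mei_mask


def mean_pairwise_distance(images, mask=None) -> float:
    """Mean masked Euclidean distance over all unordered image pairs."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    if mask is None:
        mask = np.ones_like(as_array(images[0]))
    return float(pairwise_masked_distances(images, mask).mean())


def greedy_max_min_selection(images, mask, k: int, start: int | None = None,
                             activations=None) -> list[int]:
    """Greedy subset of k images maximizing the minimum pairwise distance.

    The seed element is the highest-activating image when activations are
    given (ties broken by index), else index 0; each subsequent pick
    maximizes its distance to the closest already-selected image. The result
    is deterministic and permutation-invariant given a fixed seed element.
    """
    n = len(images)
    if k > n:
        raise ValueError("k exceeds the pool size")
    flat = (np.stack([as_array(im) for im in images]) * as_array(mask)).reshape(n, -1)
    if start is None:
        start = 0 if activations is None else int(np.argmax(activations))
    selected = [start]
    min_dist = np.linalg.norm(flat - flat[start], axis=1)
    min_dist[start] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        d_new = np.linalg.norm(flat - flat[nxt], axis=1)
        min_dist = np.minimum(min_dist, d_new)
        min_dist[nxt] = -np.inf
    return selected


@dataclass
class DiversityCalibration:
    d_lower: float
    d_upper: float
    per_cell_simple: np.ndarray | None = None
    per_cell_complex: np.ndarray | None = None

    def __post_init__(self):
        if not (self.d_upper > self.d_lower >= 0):
            raise ValueError("calibration requires d_upper > d_lower >= 0")


def _gabor_stimulus_grid(cell_params, shape, deg_per_pixel, n_theta=16,
                         n_phase=32, n_wavelength=5, n_position=5):
    """Dense standardized Gabor stimulus bank around a cell's parameters.

    The grid spans all orientations and phases, wavelengths bracketing the
    cell's own (clipped to the lambda <= 2 sigma constraint), and a small set
    of envelope positions around the cell center.
    """
    rows, cols = shape
    y = (np.arange(rows) - (rows - 1) / 2.0)[:, None] * deg_per_pixel
    x = (np.arange(cols) - (cols - 1) / 2.0)[None, :] * deg_per_pixel
    thetas = np.linspace(0.0, np.pi, n_theta, endpoint=False)
    phases = np.linspace(0.0, 2.0 * np.pi, n_phase, endpoint=False)
    lam_lo = max(2.0 * deg_per_pixel, 0.7 * cell_params.wavelength)
    lam_hi = min(2.0 * cell_params.sigma, 1.4 * cell_params.wavelength)
    lam_hi = max(lam_hi, lam_lo * 1.01)
    wavelengths = np.geomspace(lam_lo, lam_hi, n_wavelength)
    offsets = [(0.0, 0.0)]
    step = cell_params.sigma / 2.0
    for dx, dy in ((step, 0), (-step, 0), (0, step), (0, -step)):
        offsets.append((dx, dy))
    offsets = offsets[:n_position]

    bank = []
    for mu_x, mu_y in offsets:
        env = np.exp(-(((x - cell_params.mu_x - mu_x) ** 2
                        + (y - cell_params.mu_y - mu_y) ** 2)
                       / (2.0 * cell_params.sigma**2)))
        for theta in thetas:
            proj = x * np.cos(theta) + y * np.sin(theta)
            for lam in wavelengths:
                arg = 2.0 * np.pi * proj / lam
                cos_a, sin_a = np.cos(arg), np.sin(arg)
                for psi in phases:
                    carrier = cos_a * np.cos(psi) - sin_a * np.sin(psi)
                    bank.append(env * carrier)
    stack = np.stack(bank)
    flat = stack.reshape(len(bank), -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    rms = flat.std(axis=1, keepdims=True)
    flat = flat / np.maximum(rms, 1e-12) * 0.25
    # No clipping here: the reference stimuli stay exact standardized Gabors,
    # which is what makes their pairwise distances independent of the cell's
    # parameters (clipping would re-couple distance to envelope size).
    return flat.reshape(stack.shape)


def _batch_responses(cell: ModelNeuron, bank, shape, deg_per_pixel) -> np.ndarray:
    """Vectorized responses for the analytic cell kinds; generic loop otherwise."""
    from .models import gabor_image

    if cell.params is not None and cell.label.startswith(("simple", "complex")):
        flat = bank.reshape(len(bank), -1)
        f1 = gabor_image(cell.params, shape, deg_per_pixel).ravel()
        if cell.label.startswith("simple"):
            return np.maximum(flat @ f1, 0.0)
        f2 = gabor_image(cell.params.shifted(np.pi / 2.0), shape,
                         deg_per_pixel).ravel()
        return np.hypot(flat @ f1, flat @ f2)
    return np.array([cell.respond(im) for im in bank])


def exhaustive_gabor_veis(cell: ModelNeuron, shape=DEFAULT_SHAPE,
                          deg_per_pixel=DEFAULT_DEG_PER_PIXEL, n_veis: int = 20,
                          floor: float = 0.85, **grid_kwargs):
    """Reference VEIs for an analytic cell via exhaustive Gabor-grid search.

    Among standardized Gabor stimuli with response >= floor * max, greedily
    select n_veis maximizing the minimum pairwise distance within the cell's
    receptive-field mask.
    """
    if cell.params is None:
        raise ValueError("exhaustive search requires a Gabor-parameterized cell")
    bank = _gabor_stimulus_grid(cell.params, shape, deg_per_pixel, **grid_kwargs)
    return _veis_from_bank(cell, bank, shape, deg_per_pixel, n_veis, floor)


def _veis_from_bank(cell, bank, shape, deg_per_pixel, n_veis, floor):
    responses = _batch_responses(cell, bank, shape, deg_per_pixel)
    best = int(np.argmax(responses))
    mask = extract_mei_mask(bank[best])
    admissible = np.flatnonzero(responses >= floor * responses[best])
    if len(admissible) < n_veis:
        raise ValueError(
            f"Gabor grid too coarse: only {len(admissible)} admissible stimuli "
            f"(< {n_veis}); refine the grid resolution")
    pool = bank[admissible]
    idx = greedy_max_min_selection(pool, mask, n_veis,
                                   activations=responses[admissible])
    return [pool[i] for i in idx], mask


def calibrate_diversity_bounds(n_cells: int = 60, shape=DEFAULT_SHAPE,
                               deg_per_pixel=DEFAULT_DEG_PER_PIXEL,
                               seed: int = 0, n_veis: int = 20,
                               floor: float = 0.85,
                               **grid_kwargs) -> DiversityCalibration:
    """Estimate d_lower/d_upper as the median average pairwise VEI distance of
    noiseless simple- and complex-cell populations (n_cells each)."""
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    population = sample_gabor_population(n_cells, seed)
    per_simple, per_complex = [], []
    for params in population:
        # the simple and complex cell of the same parameters share one bank
        bank = _gabor_stimulus_grid(params, shape, deg_per_pixel, **grid_kwargs)
        for maker, sink in ((make_simple_cell, per_simple),
                            (make_complex_cell, per_complex)):
            cell = maker(params, shape, deg_per_pixel)
            veis, mask = _veis_from_bank(cell, bank, shape, deg_per_pixel,
                                         n_veis, floor)
            sink.append(mean_pairwise_distance(veis, mask))
    return DiversityCalibration(
        d_lower=float(np.median(per_simple)),
        d_upper=float(np.median(per_complex)),
        per_cell_simple=np.array(per_simple),
        per_cell_complex=np.array(per_complex),
    )


def diversity_index(d: float, calib: DiversityCalibration) -> float:
    """Affine normalization of an average pairwise distance: 0 at the simple-
    cell bound, 1 at the complex-cell bound. Real neurons may fall outside
    [0, 1]."""
    if calib.d_upper == calib.d_lower:
        raise ValueError("degenerate calibration: d_upper equals d_lower")
    return float((d - calib.d_lower) / (calib.d_upper - calib.d_lower))


@dataclass
class LatentBasis:
    """Low-dimensional basis of predicted population responses.

    Holds the PCA components over a library of stimuli, truncated at the
    smallest dimension explaining at least ``var_threshold`` of the response
    variance, plus the population used to embed new stimuli.
    """

    population: list
    mean_: np.ndarray
    components_: np.ndarray          # (n_retained, n_neurons)
    explained_variance_ratio_: np.ndarray
    n_retained: int

    def embed(self, image) -> np.ndarray:
        r = np.array([m.respond(as_array(image)) for m in self.population])
        return (r - self.mean_) @ self.components_.T


def _population_responses(population, images) -> np.ndarray:
    return np.array([[m.respond(as_array(im)) for m in population]
                     for im in images])


def build_latent_basis(population, mei_library, var_threshold: float = 0.95) -> LatentBasis:
    """PCA basis of population responses to an MEI library, truncated at the
    smallest dimensionality explaining ``var_threshold`` of the variance."""
    if len(mei_library) < 2:
        raise ValueError("need at least 2 library images")
    responses = _population_responses(population, mei_library)
    pca = PCA()
    pca.fit(responses)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_retained = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_retained = min(n_retained, len(pca.explained_variance_ratio_))
    return LatentBasis(
        population=list(population),
        mean_=pca.mean_,
        components_=pca.components_[:n_retained],
        explained_variance_ratio_=pca.explained_variance_ratio_[:n_retained],
        n_retained=n_retained,
    )


def representational_similarity(basis: LatentBasis, images_a, images_b) -> float:
    """Mean pairwise cosine similarity between latent embeddings of two image
    sets. Pairs with a zero-norm latent vector are skipped (and counted)."""
    za = [basis.embed(im) for im in images_a]
    zb = [basis.embed(im) for im in images_b]
    sims, skipped = [], 0
    for a in za:
        na = np.linalg.norm(a)
        for b in zb:
            nb = np.linalg.norm(b)
            if na == 0 or nb == 0:
                skipped += 1
                continue
            sims.append(float(a @ b / (na * nb)))
    if not sims:
        raise ValueError(f"all {skipped} pairs had zero-norm latents")
    return float(np.mean(sims))


def refine_mei_mask(model: ModelNeuron, mei: MEIResult, keep_fraction: float = 0.95,
                    max_erosions: int = 10) -> np.ndarray:
    """Shrink the MEI mask until the masked MEI's activation drops below
    ``keep_fraction`` of the full MEI activation."""
    from scipy import ndimage

    support = mei.mask > 0.3
    weight = mei.mask.copy()
    r_full = mei.activation
    refined = weight * support
    for _ in range(max_erosions):
        masked = standardize(refined * mei.image) if (refined * mei.image).std() > 0 else None
        if masked is None or model.respond(masked) < keep_fraction * r_full:
            break
        support = ndimage.binary_erosion(support)
        if not support.any():
            break
        refined = weight * support
    return refined


def _match_moments(image, ref, support) -> np.ndarray:
    """Affinely adjust ``image`` so its mean/RMS over ``support`` match ``ref``'s."""
    arr = as_array(image).copy()
    vals = arr[support]
    ref_vals = as_array(ref)[support]
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero-variance crop within the mask")
    arr[support] = (vals - vals.mean()) / sd * ref_vals.std() + ref_vals.mean()
    return arr


def select_natural_veis(crop_pool, model: ModelNeuron, mei: MEIResult,
                        threshold: float = 0.85, k: int = 20) -> VEISet:
    """Greedy selection of natural crops that act like VEIs.

    Crops are masked by the refined MEI mask, matched in mean and RMS to the
    masked MEI, and retained if they reach ``threshold`` of the MEI response;
    if at least k remain, a greedy max-min-distance subset of k is returned
    (seeded at the most-activating crop). With fewer than k admissible crops
    all of them are returned with ``constraint_violated`` set.
    """
    refined = refine_mei_mask(model, mei)
    support = refined > 0.3
    if not support.any():
        raise ValueError("refined mask is empty")
    masked_mei = refined * mei.image
    processed, acts = [], []
    for crop in crop_pool:
        masked = refined * as_array(crop)
        try:
            matched = _match_moments(masked, masked_mei, support)
        except ValueError:
            continue
        matched = matched * (refined > 0)
        processed.append(matched)
        acts.append(model.respond(matched))
    acts = np.array(acts)
    admissible = np.flatnonzero(acts >= threshold * mei.activation)
    flagged = len(admissible) < k
    if len(admissible) == 0:
        return VEISet(images=[], activations=np.array([]), lambda_used=np.nan,
                      min_pairwise_distance=np.nan, mean_pairwise_distance=np.nan,
                      constraint_violated=True)
    pool = [processed[i] for i in admissible]
    if flagged:
        chosen = list(range(len(pool)))
    else:
        chosen = greedy_max_min_selection(pool, refined, k,
                                          activations=acts[admissible])
    images = [pool[i] for i in chosen]
    dists = (pairwise_masked_distances(images, refined)
             if len(images) > 1 else np.array([np.nan]))
    return VEISet(
        images=images,
        activations=acts[admissible][chosen],
        lambda_used=np.nan,
        min_pairwise_distance=float(np.min(dists)),
        mean_pairwise_distance=float(np.mean(dists)),
        constraint_violated=flagged,
        meta={"min_activation_ratio": float(acts[admissible][chosen].min()
                                            / mei.activation)},
    )
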