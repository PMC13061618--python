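"""Gradient-based synthesis of most-exciting and varied-exciting inputs.

The most exciting input (MEI) of a model neuron is found by plain gradient
ascent on the predicted response, with the gradient Gaussian-blurred at every
step to suppress high-frequency artifacts and the image re-standardized to a
fixed mean and RMS contrast after every step.

Varied exciting inputs (VEIs) are a set of n images that each keep at least a
fraction c of the MEI response while being maximally mutually dissimilar. The
set minimizes

    L = (1/n) sum_i max(c - r_i / r_MEI, 0) - lambda * min_{i,j} d(I_i, I_j)

where d is the Euclidean distance in pixel space measured within the MEI mask.
The minimum (not average) pairwise distance is regularized so the optimizer
pushes apart the most similar pair rather than forming clusters. The synthesis
is run over a grid of diversity weights lambda and the set from the largest
lambda whose minimum activation ratio still meets the floor c is selected.

Distance-matched control sets (random directions at the VEIs' distance from
the MEI, and natural crops at that distance) probe whether VEIs are specific
directions of the invariance manifold rather than generic proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .images import (
    DEFAULT_CLIP,
    STD_MEAN,
    STD_RMS,
    as_array,
    masked_distance,
    pairwise_masked_distances,
    standardize,
)
from .models import ModelNeuron


@dataclass
class SynthesisConfig:
    """Knobs of MEI/VEI synthesis; defaults follow the reference procedure."""

    c: float = 0.85                      # activation floor relative to the MEI
    lambda_grid: tuple = tuple(np.geomspace(1e-4, 5e-2, 8))
    mei_iters: int = 1000
    mei_lr: float = 1.0
    vei_iters: int = 3000
    vei_lr: float = 1000.0               # decays to vei_lr_late
    vei_lr_late: float = 100.0
    vei_lr_decay_at: int = 2000
    cleanup_iters: int = 200             # activation-only floor-restoring phase
    grad_blur_sigma: float = 1.0
    std_mean: float = STD_MEAN
    std_rms: float = STD_RMS
    clip: tuple = DEFAULT_CLIP
    n_veis: int = 20
    init_noise_sd: float = 0.05          # additive noise s.d. on MEI copies
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.c < 1.0:
            raise ValueError("c must lie in (0, 1)")
        lam = np.asarray(self.lambda_grid, dtype=float)
        if lam.ndim != 1 or len(lam) < 1 or np.any(np.diff(lam) <= 0):
            raise ValueError("lambda_grid must be strictly increasing")
        if self.n_veis < 2:
            raise ValueError("n_veis must be >= 2")

    def _std(self, img):
        return standardize(img, self.std_mean, self.std_rms, self.clip)


@dataclass
class MEIResult:
    image: np.ndarray
    activation: float
    mask: np.ndarray


@dataclass
class VEISet:
    images: list
    activations: np.ndarray
    lambda_used: float
    min_pairwise_distance: float
    mean_pairwise_distance: float
    constraint_violated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def min_activation_ratio(self):
        return self.meta.get("min_activation_ratio")


def extract_mei_mask(mei_image, z_threshold: float = 1.5,
                     smooth_sigma: float = 1.5) -> np.ndarray:
    """Weighted receptive-field mask from an MEI.

    Pipeline: pixel-wise |z-score| -> threshold -> binary closing -> largest
    connected component -> convex hull -> Gaussian smoothing. The result is a
    weighted mask in [0, 1] that is exactly zero away from the hull (up to the
    Gaussian tail).
    """
    arr = as_array(mei_image)
    z = (arr - arr.mean()) / arr.std()
    supra = np.abs(z) > z_threshold
    if not supra.any():
        raise ValueError("no RF found: no pixel exceeds the z-score threshold")
    closed = ndimage.binary_closing(supra)
    labels, n_comp = ndimage.label(closed)
    if n_comp == 0:
        raise ValueError("no RF found after closing")
    sizes = ndimage.sum_labels(np.ones_like(arr), labels, range(1, n_comp + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    hull = morphology.convex_hull_image(largest)
    mask = ndimage.gaussian_filter(hull.astype(float), smooth_sigma)
    return np.clip(mask, 0.0, 1.0)


def synthesize_mei(model: ModelNeuron, config: SynthesisConfig | None = None,
                   shape=(36, 64)) -> MEIResult:
    """Gradient-ascend a standardized image to maximize the model response."""
    config = config or SynthesisConfig()
    rng = np.random.default_rng(config.seed)
    img = config._std(rng.standard_normal(shape))
    for _ in range(config.mei_iters):
        g = model.grad(img)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient during MEI synthesis")
        g = ndimage.gaussian_filter(g, config.grad_blur_sigma)
        img = config._std(img + config.mei_lr * g)
    activation = model.respond(img)
    return MEIResult(image=img, activation=activation, mask=extract_mei_mask(img))


def _min_pair(images, mask):
    """Index pair and distance of the closest pair under the masked metric."""
    flat = (np.stack(images) * mask).reshape(len(images), -1)
    sq = np.sum(flat**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    np.fill_diagonal(d2, np.inf)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return i, j, float(np.sqrt(max(d2[i, j], 0.0)))


def _vei_descent(model, mei: MEIResult, config: SynthesisConfig, lam: float,
                 rng) -> list[np.ndarray]:
    """One VEI optimization run at a fixed diversity weight lambda."""
    n = config.n_veis
    mask = mei.mask
    imgs = [config._std(mei.image + config.init_noise_sd * rng.standard_normal(mei.image.shape))
            for _ in range(n)]
    r_mei = mei.activation
    for it in range(config.vei_iters):
        lr = config.vei_lr if it < config.vei_lr_decay_at else config.vei_lr_late
        grads: dict[int, np.ndarray] = {}
        # activation floor term (hinge): only images below the floor get pushed
        ratios = model.respond_batch(imgs) / r_mei
        for k in range(n):
            if ratios[k] < config.c:
                grads[k] = -model.grad(imgs[k]) / (n * r_mei)
        # diversity term: push apart the currently closest pair
        i, j, d = _min_pair(imgs, mask)
        if d > 0:
            pair_grad = (mask**2) * (imgs[i] - imgs[j]) / d
            grads[i] = grads.get(i, 0.0) - lam * pair_grad
            grads[j] = grads.get(j, 0.0) + lam * pair_grad
        for k, g in grads.items():
            g = ndimage.gaussian_filter(g, config.grad_blur_sigma)
            imgs[k] = config._std(imgs[k] - lr * g)
    # constraint cleanup: the joint push-pull equilibrium can leave images
    # marginally below the floor; a short activation-only phase restores the
    # constraint with minimal displacement (diversity is left untouched)
    for _ in range(config.cleanup_iters):
        ratios = model.respond_batch(imgs) / r_mei
        below = [k for k in range(n) if ratios[k] < config.c]
        if not below:
            break
        for k in below:
            g = ndimage.gaussian_filter(model.grad(imgs[k]) / (n * r_mei),
                                        config.grad_blur_sigma)
            imgs[k] = config._std(imgs[k] + config.vei_lr_late * g)
    return imgs


def _make_set(model, mei, config, lam, imgs, violated=False) -> VEISet:
    acts = model.respond_batch(imgs)
    dists = pairwise_masked_distances(imgs, mei.mask)
    return VEISet(
        images=imgs, activations=acts, lambda_used=lam,
        min_pairwise_distance=float(dists.min()),
        mean_pairwise_distance=float(dists.mean()),
        constraint_violated=violated,
        meta={"min_activation_ratio": float(acts.min() / mei.activation)},
    )


def synthesize_veis(model: ModelNeuron, mei: MEIResult,
                    config: SynthesisConfig | None = None) -> VEISet:
    """Synthesize the VEI set across the lambda grid and select the largest
    lambda whose minimum activation ratio still meets the floor c.

    If no lambda satisfies the floor, the smallest-lambda set is returned with
    ``constraint_violated`` set.
    """
    config = config or SynthesisConfig()
    if mei.activation <= 0:
        raise ValueError("MEI activation must be positive")
    rng = np.random.default_rng(config.seed)
    candidates: list[VEISet] = []
    for lam in config.lambda_grid:
        imgs = _vei_descent(model, mei, config, float(lam), rng)
        candidates.append(_make_set(model, mei, config, float(lam), imgs))
    feasible = [s for s in candidates
                if s.meta["min_activation_ratio"] >= config.c]
    if feasible:
        # lambda grid is increasing; the last feasible set has the largest lambda
        return feasible[-1]
    worst = candidates[0]
    worst.constraint_violated = True
    return worst


def synthesize_distance_controls(model: ModelNeuron, mei: MEIResult,
                                 veis: VEISet,
                                 config: SynthesisConfig | None = None,
                                 lam: float | None = None) -> VEISet:
    """Synthesize controls matched in masked distance to the MEI.

    d_target is the minimum masked distance from the VEIs to the MEI. The
    controls drift outward toward d_target while their minimum pairwise
    distance is regularized, and after every step each control is radially
    projected back inside the d_target ball around the MEI, so every control
    is at most as far from the MEI as the closest VEI.
    """
    config = config or SynthesisConfig()
    d_target = min(masked_distance(im, mei.image, mei.mask) for im in veis.images)
    if d_target <= 1e-9:
        raise ValueError("degenerate VEIs: zero distance to the MEI")
    if lam is None:
        lam = float(config.lambda_grid[-1])
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_veis
    mask = mei.mask
    imgs = [config._std(mei.image + config.init_noise_sd * rng.standard_normal(mei.image.shape))
            for _ in range(n)]
    for it in range(config.vei_iters):
        lr = config.vei_lr if it < config.vei_lr_decay_at else config.vei_lr_late
        grads = []
        for k in range(n):
            d_k = masked_distance(imgs[k], mei.image, mask)
            # d(L)/d(I_k) for the (d_target - d) term: -grad of d
            g = np.zeros_like(mei.image) if d_k == 0 else \
                -(mask**2) * (imgs[k] - mei.image) / (d_k * n)
            grads.append(g)
        i, j, d = _min_pair(imgs, mask)
        if d > 0:
            pair_grad = (mask**2) * (imgs[i] - imgs[j]) / d
            grads[i] -= lam * pair_grad
            grads[j] += lam * pair_grad
        for k in range(n):
            g = ndimage.gaussian_filter(grads[k], config.grad_blur_sigma)
            img = config._std(imgs[k] - lr * g)
            d_k = masked_distance(img, mei.image, mask)
            if d_k > d_target:
                # shrink the masked deviation from the MEI back onto the ball
                img = mei.image + (img - mei.image) * (d_target / d_k)
            imgs[k] = img
    out = _make_set(model, mei, config, lam, imgs)
    out.meta["d_target"] = d_target
    return out


def sample_natural_controls(crop_pool, mei: MEIResult, d_target: float,
                            n_controls: int = 20) -> list[np.ndarray]:
    """Natural crops whose masked distance to the MEI lies in [0.8, 1.0] * d_target.

    Returns at most ``n_controls`` crops (closest to d_target first); an empty
    selection is reported as an empty list, not an error.
    """
    if d_target <= 0:
        raise ValueError("d_target must be positive")
    scored = []
    for crop in crop_pool:
        d = masked_distance(crop, mei.image, mei.mask)
        if 0.8 * d_target <= d <= d_target:
            scored.append((abs(d - d_target), as_array(crop)))
    scored.sort(key=lambda t: t[0])
    return [c for _, c in scored[:n_controls]]


def neuronal_space_distance(population, img_a, img_b,
                            target: ModelNeuron | None = None) -> float:
    """Dissimilarity of two images in a population's representational space:
    the negative Pearson correlation of the population response vectors.

    RF centers are aligned to the target neuron's center (by translating the
    input before each neuron's prediction) so that all neurons view the
    stimulus at the same retinotopic location. Identical images give exactly
    -1.
    """
    if len(population) < 3:
        raise ValueError("need at least 3 neurons")
    target = target or population[0]

    def respond_aligned(img):
        arr = as_array(img)
        out = []
        for neuron in population:
            dr = int(round(neuron.rf_center[0] - target.rf_center[0]))
            dc = int(round(neuron.rf_center[1] - target.rf_center[1]))
            out.append(neuron.respond(np.roll(arr, (dr, dc), axis=(0, 1))))
        return np.array(out)

    r_a = respond_aligned(img_a)
    r_b = respond_aligned(img_b)
    if r_a.std() == 0 or r_b.std() == 0:
        raise ValueError("zero-variance population response vector")
    r = np.corrcoef(r_a, r_b)[0, 1]
    return float(-r)
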