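"""Synthetic fixtures: naturalistic image pools, segmentation blobs, a planted
bipartite ground-truth neuron, and synthetic connectome tables.

Every generator is a pure function of its seed and arguments, so the entire
pipeline is testable offline with no external dataset. The naturalistic pool
emulates only the second-order (1/f amplitude-spectrum) statistics of natural
images; the blob masks emulate single-object/background segmentations; the
synthetic connectome plants like-to-like connectivity, an invariance
hierarchy, and an exponentially decaying synapse-conversion rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import DEFAULT_DEG_PER_PIXEL, DEFAULT_SHAPE, as_array, standardize
from .models import GaborParams, ModelNeuron, gabor_image


def naturalistic_images(n: int, shape=DEFAULT_SHAPE, spectral_exponent: float = 1.0,
                        seed: int = 0, clip=None) -> list[np.ndarray]:
    """Random-phase images with a 1/f^exponent amplitude spectrum, standardized.

    Exponent 1 approximates the spectral statistics of natural scenes;
    exponent 0 gives white noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    freq = np.hypot(fy, fx)
    freq[0, 0] = 1.0  # DC removed by standardization anyway
    amplitude = freq ** (-spectral_exponent)
    amplitude[0, 0] = 0.0
    out = []
    for _ in range(n):
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(rows, cols))
        spectrum = amplitude * np.exp(1j * phase)
        img = np.real(np.fft.ifft2(spectrum))
        out.append(standardize(img, clip=clip))
    return out


def blob_segmentation_masks(n: int, shape=DEFAULT_SHAPE, smoothness: float = 4.0,
                            seed: int = 0) -> list[np.ndarray]:
    """Ternary object/background masks from thresholded smoothed noise fields.

    Each mask holds +1 on a single 4-connected object region and -1 on the
    background, with object area fraction in [0.2, 0.8]. Fields failing the
    fraction bound are redrawn.
    """
    rng = np.random.default_rng(seed)
    masks: list[np.ndarray] = []
    n_px = shape[0] * shape[1]
    while len(masks) < n:
        field = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness)
        # threshold at a random quantile so object sizes vary across masks
        q = rng.uniform(0.3, 0.7)
        binary = field > np.quantile(field, q)
        labels, n_comp = ndimage.label(binary)  # default 4-connectivity
        if n_comp == 0:
            continue
        sizes = ndimage.sum_labels(np.ones(shape), labels, index=range(1, n_comp + 1))
        obj = labels == (1 + int(np.argmax(sizes)))
        frac = obj.sum() / n_px
        if not (0.2 <= frac <= 0.8):
            continue
        masks.append(np.where(obj, 1, -1).astype(np.int8))
    return masks


def _softplus(z: float) -> float:
    return float(np.logaddexp(0.0, z))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class PlantedBipartiteNeuron:
    """Ground-truth neuron with a fixed and a shift-tolerant subfield.

    The response is ``softplus(<m_f * I, fixed_template>)`` times the
    rectified maximum over integer shifts of ``<m_v * I, shift(texture)>``:
    strong only when the fixed low-frequency pattern is present AND some
    translate of the high-frequency texture matches the variable subfield.
    The softplus keeps gradients alive everywhere for synthesis (a documented
    deviation from a hard rectifier).
    """

    m_v_true: np.ndarray
    m_f_true: np.ndarray
    fixed_template: np.ndarray
    shifted_textures: np.ndarray  # (n_shifts, rows, cols), each masked by m_v
    neuron: ModelNeuron = None

    def respond(self, image) -> float:
        arr = as_array(image)
        fixed_drive = _softplus(np.sum(self.m_f_true * arr * self.fixed_template))
        drives = np.tensordot(self.shifted_textures, self.m_v_true * arr, axes=2)
        return fixed_drive * max(0.0, float(drives.max()))

    def grad(self, image) -> np.ndarray:
        arr = as_array(image)
        zf = np.sum(self.m_f_true * arr * self.fixed_template)
        fixed_drive = _softplus(zf)
        drives = np.tensordot(self.shifted_textures, self.m_v_true * arr, axes=2)
        k = int(np.argmax(drives))
        var_drive = max(0.0, float(drives[k]))
        g = np.zeros_like(arr)
        # product rule; subgradient at the argmax shift
        g += var_drive * _sigmoid(zf) * self.m_f_true * self.fixed_template
        if drives[k] > 0:
            g += fixed_drive * self.shifted_textures[k] * self.m_v_true
        return g


def planted_bipartite_neuron(shape=DEFAULT_SHAPE, freq_fixed_low: float = 0.04,
                             freq_variable_high: float = 0.12, seed: int = 0,
                             deg_per_pixel=DEFAULT_DEG_PER_PIXEL,
                             shift_stride: int = 2) -> PlantedBipartiteNeuron:
    """Build the planted neuron: low-frequency fixed subfield on the left of
    an elliptical RF, high-frequency shift-tolerant texture on the right.

    Frequencies are in cycles/degree; the variable subfield's texture must be
    the higher-frequency of the two.
    """
    if freq_variable_high <= freq_fixed_low:
        raise ValueError("freq_variable_high must exceed freq_fixed_low")
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2.0)[:, None]
    c = (np.arange(cols) - (cols - 1) / 2.0)[None, :]
    rf = ((r / (0.38 * rows)) ** 2 + (c / (0.30 * cols)) ** 2) <= 1.0
    m_f = (rf & (c < 0)).astype(float)
    m_v = (rf & (c >= 0)).astype(float)

    rng = np.random.default_rng(seed)
    fixed = gabor_image(
        GaborParams(mu_x=-0.15 * cols * deg_per_pixel, sigma=0.22 * cols * deg_per_pixel,
                    theta=rng.uniform(0, np.pi),
                    wavelength=1.0 / freq_fixed_low, phase=rng.uniform(0, 2 * np.pi)),
        shape, deg_per_pixel)
    texture_theta = rng.uniform(0, np.pi)
    base = gabor_image(
        GaborParams(mu_x=0.15 * cols * deg_per_pixel, sigma=0.22 * cols * deg_per_pixel,
                    theta=texture_theta, wavelength=1.0 / freq_variable_high,
                    phase=0.0),
        shape, deg_per_pixel)
    max_shift = int(round(1.0 / freq_variable_high / deg_per_pixel))
    shifts = []
    for dy in range(-max_shift, max_shift + 1, shift_stride):
        for dx in range(-max_shift, max_shift + 1, shift_stride):
            t = np.roll(base, (dy, dx), axis=(0, 1)) * m_v
            # unit norm within the subfield: every shift is exactly as
            # excitable as every other (shift tolerance by construction)
            shifts.append(t / np.linalg.norm(t))
    planted = PlantedBipartiteNeuron(
        m_v_true=m_v, m_f_true=m_f, fixed_template=fixed * m_f,
        shifted_textures=np.stack(shifts))
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    planted.neuron = ModelNeuron(planted.respond, planted.grad, center,
                                 "planted-bipartite")
    return planted


def synthetic_connectome(n_pre: int = 20, n_post: int = 500,
                         like_to_like_beta: float = 2.0,
                         hierarchy_delta: float = 0.15,
                         decay_rate: float = 2.0,
                         base_rate: float = 0.5,
                         seed: int = 0) -> pd.DataFrame:
    """Synthesize a pairwise connectivity table with planted effects.

    Each neuron carries a latent functional embedding (whose cosine similarity
    yields MEI/VEI similarities) and a diversity index. Connection log-odds
    increase with similarity (``like_to_like_beta``) and decrease with
    presynaptic diversity (``decay_rate``); connected postsynaptic partners
    have diversity shifted by ``hierarchy_delta``; the per-pair synapse count
    is Poisson in the co-travel distance times a conversion rate that decays
    exponentially with presynaptic diversity. Default sizes (20 presynaptic,
    500 postsynaptic neurons, ~700 connected pairs) mirror the scale of
    published functional-connectomics analyses.
    """
    if base_rate <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    dim = 8
    u_pre = rng.standard_normal((n_pre, dim))
    u_post = rng.standard_normal((n_post, dim))
    u_pre /= np.linalg.norm(u_pre, axis=1, keepdims=True)
    u_post /= np.linalg.norm(u_post, axis=1, keepdims=True)
    div_pre = rng.uniform(0.0, 1.0, n_pre)
    div_post_base = rng.uniform(0.0, 1.0, n_post)

    sim = u_pre @ u_post.T  # (n_pre, n_post) in [-1, 1]
    vei_sim = np.clip(sim + 0.1 * rng.standard_normal(sim.shape), -1, 1)
    # intercept tuned so the expected connected count is ~7% of pairs at the
    # default effect sizes
    logit = -2.7 + like_to_like_beta * sim - decay_rate * (div_pre[:, None] - 0.5)
    connected = rng.uniform(size=sim.shape) < _sigmoid(logit)

    co_travel = rng.lognormal(mean=-1.0, sigma=0.5, size=sim.shape)  # mm
    conv_rate = base_rate * np.exp(-decay_rate * div_pre)[:, None]
    n_syn = np.where(connected,
                     1 + rng.poisson(conv_rate * co_travel * 10.0), 0)

    div_post = np.where(
        connected,
        div_pre[:, None] + hierarchy_delta + 0.1 * rng.standard_normal(sim.shape),
        div_post_base[None, :] + 0.1 * rng.standard_normal(sim.shape))

    pre_idx, post_idx = np.meshgrid(np.arange(n_pre), np.arange(n_post),
                                    indexing="ij")
    return pd.DataFrame({
        "presyn_id": pre_idx.ravel(),
        "postsyn_id": post_idx.ravel(),
        "connected": connected.ravel(),
        "n_syn": n_syn.ravel(),
        "co_travel_mm": co_travel.ravel(),
        "mei_similarity": sim.ravel(),
        "vei_similarity": vei_sim.ravel(),
        "diversity_pre": np.broadcast_to(div_pre[:, None], sim.shape).ravel(),
        "diversity_post": div_post.ravel(),
    })
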