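"""Alignment between bipartite receptive-field structure and object-background
segmentation: ternary masks, the matching score, boundary-crop filtering,
grating-scene composition, and in-silico crop screening.

A bipartite mask labels each pixel of the binarized receptive field +1
(variable subfield) or -1 (fixed subfield), 0 outside; a segmentation mask
labels object (+1) versus background (-1). Their matching score is the
normalized overlap, rescaled so that 1 means the variable subfield coincides
with the object and 0 means the perfect reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import as_array, standardize
from .models import GaborParams, gabor_image

#: wavelength bands (degrees/cycle): high spatial frequency = short period
HIGH_FREQ_BAND = (5.83, 15.55)
LOW_FREQ_BAND = (15.55, 58.3)


def bipartite_mask(m_mei, m_v, threshold: float = 0.3) -> np.ndarray:
    """Ternary mask: +1 inside the binarized variable subfield, -1 on the rest
    of the binarized MEI mask, 0 outside."""
    mei_b = as_array(m_mei) > threshold
    if not mei_b.any():
        raise ValueError("binarized MEI mask is empty")
    v_b = as_array(m_v) > threshold
    out = np.zeros(mei_b.shape, dtype=np.int8)
    out[mei_b] = -1
    out[mei_b & v_b] = 1
    return out


def matching_score(bip, seg, return_raw: bool = False):
    """Alignment between a bipartite mask and a segmentation label.

    raw = sum(bip * seg) / sum(|bip|) lies in [-1, 1]; the returned score is
    the affine rescale (raw + 1) / 2 so perfect alignment of variable subfield
    with object gives 1 and the perfect reversal gives 0. Pixels outside the
    receptive field (bip == 0) do not contribute.
    """
    bip = np.asarray(bip, dtype=float)
    seg = np.asarray(seg, dtype=float)
    if bip.shape != seg.shape:
        raise ValueError("masks must share one grid")
    denom = np.abs(bip).sum()
    if denom == 0:
        raise ValueError("empty bipartite mask")
    raw = float((bip * seg).sum() / denom)
    score = (raw + 1.0) / 2.0
    return (score, raw) if return_raw else score


def boundary_crop_filter(seg_crop, rf_mask, min_fraction: float = 0.2) -> bool:
    """True iff both object and background occupy at least ``min_fraction`` of
    the receptive-field mask (i.e. the crop contains an object boundary)."""
    seg = np.asarray(seg_crop)
    rf = np.asarray(rf_mask, dtype=bool)
    if not rf.any():
        raise ValueError("empty RF mask")
    inside = seg[rf]
    n = inside.size
    obj_frac = np.count_nonzero(inside > 0) / n
    bg_frac = np.count_nonzero(inside < 0) / n
    return bool(obj_frac >= min_fraction and bg_frac >= min_fraction)


@dataclass
class GratingSceneSpec:
    """Parameters of a composited object/background grating scene.

    ``scene_type``: 'single' (one full-field grating, mask ignored),
    'orientation' (same frequency, different orientations), 'frequency'
    (same orientation, frequencies from the two wavelength bands), or 'both'.
    Wavelengths in degrees/cycle; boundary blur sigma in pixels.
    """

    scene_type: str = "both"
    object_wavelength: float = 10.0
    object_theta: float = 0.0
    object_phase: float = 0.0
    background_wavelength: float = 30.0
    background_theta: float = np.pi / 2
    background_phase: float = 0.0
    boundary_blur_sigma: float = 1.5


def sample_grating_scene_spec(scene_type: str, seed: int) -> GratingSceneSpec:
    """Draw a scene spec of the requested type, with object and background
    parameters sampled independently and frequency constraints per type."""
    rng = np.random.default_rng(seed)
    obj_lam = rng.uniform(*HIGH_FREQ_BAND)
    bg_lam = rng.uniform(*LOW_FREQ_BAND)
    if rng.uniform() < 0.5:  # either region may carry the high frequency
        obj_lam, bg_lam = bg_lam, obj_lam
    theta_o = rng.uniform(0, np.pi)
    theta_b = rng.uniform(0, np.pi)
    if scene_type in ("single",):
        bg_lam, theta_b = obj_lam, theta_o
    elif scene_type == "orientation":
        bg_lam = obj_lam
    elif scene_type == "frequency":
        theta_b = theta_o
    elif scene_type != "both":
        raise ValueError(f"unknown scene type {scene_type!r}")
    return GratingSceneSpec(
        scene_type=scene_type,
        object_wavelength=obj_lam, object_theta=theta_o,
        object_phase=rng.uniform(0, 2 * np.pi),
        background_wavelength=bg_lam, background_theta=theta_b,
        background_phase=rng.uniform(0, 2 * np.pi))


def _full_field_grating(wavelength, theta, phase, shape, deg_per_pixel):
    # very wide envelope = effectively a pure grating
    g = gabor_image(GaborParams(sigma=1e6, theta=theta, wavelength=wavelength,
                                phase=phase), shape, deg_per_pixel)
    return standardize(g, clip=None)


def compose_grating_scene(seg_mask, spec: GratingSceneSpec, deg_per_pixel: float = 2.0,
                          seed: int | None = None) -> np.ndarray:
    """Composite object and background gratings through a segmentation mask.

    The two gratings are contrast-matched (identical mean and RMS) before
    compositing; the object-background boundary is blurred by blending through
    a Gaussian-smoothed (sigma = 1.5) mask. ``scene_type == 'single'`` ignores
    the mask and returns the object grating.
    """
    seg = np.asarray(seg_mask)
    shape = seg.shape
    obj = _full_field_grating(spec.object_wavelength, spec.object_theta,
                              spec.object_phase, shape, deg_per_pixel)
    if spec.scene_type == "single":
        return obj
    bg = _full_field_grating(spec.background_wavelength, spec.background_theta,
                             spec.background_phase, shape, deg_per_pixel)
    w = ndimage.gaussian_filter((seg > 0).astype(float), spec.boundary_blur_sigma)
    return w * obj + (1.0 - w) * bg


def screen_crops(model, crops, mei, top_k: int = 100, contrast_match: bool = True,
                 seed: int = 0, n_reference: int = 100):
    """Rank a crop pool by model response and return the top-k plus a random
    reference sample.

    Crops are masked by the MEI mask and matched to the MEI's mean and RMS
    within the mask before scoring (``contrast_match``). Returns
    (top_indices, top_activations, reference_indices, flagged) where
    ``flagged`` marks a pool smaller than top_k (the full ranking is then
    returned).
    """
    mask = mei.mask
    support = mask > 0.3
    mei_vals = (mask * mei.image)[support]
    processed = []
    for crop in crops:
        arr = mask * as_array(crop)
        if contrast_match:
            vals = arr[support]
            sd = vals.std()
            if sd > 0:
                arr = arr.copy()
                arr[support] = (vals - vals.mean()) / sd * mei_vals.std() + mei_vals.mean()
        processed.append(arr)
    acts = np.array([model.respond(a) for a in processed])
    order = np.argsort(acts)[::-1]
    flagged = top_k > len(crops)
    k = min(top_k, len(crops))
    rng = np.random.default_rng(seed)
    n_ref = min(n_reference, len(crops))
    reference = rng.choice(len(crops), size=n_ref, replace=False)
    return order[:k], acts[order[:k]], reference, flagged


def sliding_crops(scene, window: int = 36, stride: int = 2):
    """All (row, col, crop) windows of a scene, scanned with a fixed stride."""
    arr = as_array(scene)
    rows, cols = arr.shape
    out = []
    for r in range(0, rows - window + 1, stride):
        for c in range(0, cols - window + 1, stride):
            out.append((r, c, arr[r:r + window, c:c + window]))
    return out
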