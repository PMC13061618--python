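"""Texture-generative parameterization of VEIs and the bipartite invariance
index (BII).

A neuron's VEIs are re-parameterized as the sum of two complementary
receptive-field subfields,

    VEI = m_V * crop(T) + m_F * MEI,

where ``T`` is a texture canvas optimized so that random crops of it maximize
the neuron's response, ``m_V`` is a variable-subfield mask grown from the
pixels of highest across-VEI variance, and ``m_F`` is its in-mask complement
holding the MEI content fixed. Letting ``m_V`` cover the whole receptive field
recovers a fully shift-invariant (full-texture) model; a series of
intermediate ``m_V`` sizes traces the trade-off between activation and
diversity, which a quadratic smoothing spline summarizes as an area under the
curve -- the BII. Control parameterizations treat both subfields as
shift-invariant or remove the spatial division entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline

from .images import as_array, pairwise_masked_distances, standardize
from .models import ModelNeuron
from .synthesis import MEIResult, SynthesisConfig, VEISet, _min_pair

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.20, 0.601, 0.05), 2))
MASK_BINARIZE_THRESHOLD = 0.3


@dataclass
class SubfieldMasks:
    """Weighted MEI mask partitioned into variable and fixed subfields."""

    m_mei: np.ndarray
    m_v: np.ndarray
    m_f: np.ndarray
    variance_fraction: float

    @property
    def size(self) -> float:
        """Variable-subfield area relative to the full mask (binarized)."""
        mei_b = self.m_mei > MASK_BINARIZE_THRESHOLD
        v_b = self.m_v > MASK_BINARIZE_THRESHOLD
        return float(v_b.sum() / max(mei_b.sum(), 1))


def variable_mask_series(veis: VEISet, m_mei, fractions=DEFAULT_FRACTIONS) -> list[SubfieldMasks]:
    """Grow variable-subfield masks from the across-VEI pixel variance map.

    Pixels inside the MEI mask are added in descending variance order until
    each target fraction of the total variance is enclosed; the fixed subfield
    is the in-mask complement, so ``m_v + m_f == m_mei`` pixelwise.
    """
    if len(veis.images) < 2:
        raise ValueError("need at least 2 VEIs for a variance map")
    m_mei = as_array(m_mei)
    stack = np.stack([as_array(im) for im in veis.images])
    var_map = stack.var(axis=0) * (m_mei > 0)
    total = var_map.sum()
    if total <= 0 or np.ptp(var_map[m_mei > 0]) < 1e-15:
        raise ValueError("degenerate (uniform) variance map across VEIs")
    order = np.argsort(var_map.ravel())[::-1]
    cumulative = np.cumsum(var_map.ravel()[order])
    series = []
    for frac in fractions:
        n_keep = int(np.searchsorted(cumulative, frac * total) + 1)
        indicator = np.zeros(var_map.size, dtype=bool)
        indicator[order[:n_keep]] = True
        indicator = indicator.reshape(var_map.shape)
        m_v = m_mei * indicator
        series.append(SubfieldMasks(
            m_mei=m_mei, m_v=m_v, m_f=m_mei - m_v,
            variance_fraction=float(cumulative[n_keep - 1] / total)))
    return series


@dataclass
class TextureCanvas:
    """Optimized texture canvas with the geometry needed to crop from it."""

    texture: np.ndarray              # canvas array, larger than the m_v bbox
    bbox: tuple                      # (rmin, rmax, cmin, cmax) in the image grid
    offset_range: tuple              # (max_row_offset, max_col_offset), inclusive
    m_v: np.ndarray
    weight: float = 1.0

    def crop_to_image(self, offset, shape) -> np.ndarray:
        """Embed the canvas crop at ``offset`` into a full-size image array."""
        rmin, rmax, cmin, cmax = self.bbox
        oy, ox = offset
        out = np.zeros(shape)
        out[rmin:rmax, cmin:cmax] = self.texture[oy:oy + (rmax - rmin),
                                                 ox:ox + (cmax - cmin)]
        return out

    def random_offsets(self, n, rng):
        return [(int(rng.integers(0, self.offset_range[0] + 1)),
                 int(rng.integers(0, self.offset_range[1] + 1)))
                for _ in range(n)]


def _mask_bbox(mask, margin_frac=0.5):
    support = as_array(mask) > MASK_BINARIZE_THRESHOLD
    if not support.any():
        raise ValueError("empty variable-subfield mask")
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    rmin, rmax = rows[0], rows[-1] + 1
    cmin, cmax = cols[0], cols[-1] + 1
    my = max(1, int(np.ceil(margin_frac * (rmax - rmin))))
    mx = max(1, int(np.ceil(margin_frac * (cmax - cmin))))
    return (rmin, rmax, cmin, cmax), (my, mx)


def optimize_texture(model: ModelNeuron, masks: SubfieldMasks,
                     fixed_part=None, config: SynthesisConfig | None = None,
                     n_steps: int = 1000, n_crops: int = 16, lr: float = 1.0,
                     weight: float = 1.0, seed: int = 0) -> TextureCanvas:
    """Gradient-ascend a texture canvas so random crops maximally activate the
    model when composited with the fixed subfield content.

    Each step samples ``n_crops`` random offsets, composites
    ``weight * m_v * crop + fixed_part``, standardizes the composite (treated
    as a projection, not differentiated through beyond its scale factor), and
    accumulates the blurred response gradient back into the canvas. The canvas
    itself is kept standardized. The canvas extends the m_v bounding box by
    50% per side, so every admissible crop fully covers the box.
    """
    config = config or SynthesisConfig()
    m_v = as_array(masks.m_v)
    shape = m_v.shape
    fixed = np.zeros(shape) if fixed_part is None else as_array(fixed_part)
    (rmin, rmax, cmin, cmax), (my, mx) = _mask_bbox(m_v)
    bh, bw = rmax - rmin, cmax - cmin
    rng = np.random.default_rng(seed)
    canvas = standardize(rng.standard_normal((bh + 2 * my, bw + 2 * mx)),
                         clip=None)
    bbox = (rmin, rmax, cmin, cmax)
    offset_range = (2 * my, 2 * mx)
    window = m_v[rmin:rmax, cmin:cmax]
    for _ in range(n_steps):
        grad = np.zeros_like(canvas)
        for _k in range(n_crops):
            oy = int(rng.integers(0, offset_range[0] + 1))
            ox = int(rng.integers(0, offset_range[1] + 1))
            comp = fixed.copy()
            comp[rmin:rmax, cmin:cmax] += weight * window * canvas[oy:oy + bh, ox:ox + bw]
            pre_rms = comp.std()
            if pre_rms == 0:
                continue
            scale = config.std_rms / pre_rms
            g_img = model.grad(standardize(comp, config.std_mean,
                                           config.std_rms, config.clip))
            grad[oy:oy + bh, ox:ox + bw] += (scale * weight
                                             * window * g_img[rmin:rmax, cmin:cmax])
        grad = ndimage.gaussian_filter(grad / n_crops, config.grad_blur_sigma)
        canvas = standardize(canvas + lr * grad, clip=None)
    return TextureCanvas(texture=canvas, bbox=bbox, offset_range=offset_range,
                         m_v=m_v, weight=weight)


def render_texture_veis(canvas: TextureCanvas, masks: SubfieldMasks,
                        fixed_part=None, n: int = 20, seed: int = 0,
                        config: SynthesisConfig | None = None,
                        model: ModelNeuron | None = None) -> VEISet:
    """Composite n random canvas crops with the fixed subfield content.

    A single shared affine standardization (computed from the set-average
    moments) is applied to all composites, so the fixed-subfield pixels stay
    bit-identical across the set while the set statistics match the standard
    intensity budget.
    """
    config = config or SynthesisConfig()
    shape = canvas.m_v.shape
    fixed = np.zeros(shape) if fixed_part is None else as_array(fixed_part)
    rng = np.random.default_rng(seed)
    offsets = canvas.random_offsets(n, rng)
    composites = [fixed + canvas.weight * canvas.m_v * canvas.crop_to_image(o, shape)
                  for o in offsets]
    means = np.array([c.mean() for c in composites])
    rmss = np.array([c.std() for c in composites])
    mu, sd = means.mean(), rmss.mean()
    if sd == 0:
        raise ValueError("degenerate (constant) composites")
    scale = config.std_rms / sd
    images = [np.clip((c - mu) * scale + config.std_mean, *config.clip)
              for c in composites]
    acts = (model.respond_batch(images) if model is not None
            else np.full(n, np.nan))
    dists = pairwise_masked_distances(images, masks.m_mei)
    return VEISet(images=images, activations=acts, lambda_used=np.nan,
                  min_pairwise_distance=float(dists.min()),
                  mean_pairwise_distance=float(dists.mean()),
                  meta={"offsets": offsets})


def refine_texture_veis(model: ModelNeuron, canvas: TextureCanvas,
                        masks: SubfieldMasks, fixed_part, mei_activation: float,
                        config: SynthesisConfig | None = None,
                        n: int = 20, n_iters: int = 300, seed: int = 0,
                        lam: float | None = None, lr_early: float = 200.0,
                        lr_late: float = 20.0,
                        model_for_acts: ModelNeuron | None = None) -> VEISet:
    """Jointly optimize the canvas under the VEI loss with the texture
    parameterization: crop offsets are drawn once, and the canvas is updated
    so the n composites satisfy the activation floor while their minimum
    pairwise (mask-weighted) distance is maximized.

    With ``lam=None`` the configured lambda grid is swept and the largest
    feasible weight is selected, mirroring the nonparametric VEI rule.
    """
    config = config or SynthesisConfig()
    shape = canvas.m_v.shape
    fixed = np.zeros(shape) if fixed_part is None else as_array(fixed_part)
    rng = np.random.default_rng(seed)
    offsets = canvas.random_offsets(n, rng)
    rmin, rmax, cmin, cmax = canvas.bbox
    bh, bw = rmax - rmin, cmax - cmin
    window = canvas.m_v[rmin:rmax, cmin:cmax] * canvas.weight
    m2 = as_array(masks.m_mei) ** 2
    lam_grid = [lam] if lam is not None else list(config.lambda_grid)
    scorer = model_for_acts or model

    def run(lam_value, texture0):
        texture = texture0.copy()
        for it in range(n_iters):
            # gentler rates than the image-space schedule: every crop's
            # gradient funnels into the one shared canvas
            lr = lr_early if it < n_iters * 2 // 3 else lr_late
            composites = []
            for oy, ox in offsets:
                comp = fixed.copy()
                comp[rmin:rmax, cmin:cmax] += window * texture[oy:oy + bh, ox:ox + bw]
                composites.append(comp)
            mu = np.mean([c.mean() for c in composites])
            sd = np.mean([c.std() for c in composites])
            if sd == 0:
                break
            scale = config.std_rms / sd
            images = [np.clip((c - mu) * scale + config.std_mean, *config.clip)
                      for c in composites]
            grad = np.zeros_like(texture)
            # d(loss)/dT for the hinge: -(1/(n r_MEI)) dr/dT on active crops
            ratios = model.respond_batch(images) / mei_activation
            for k, (oy, ox) in enumerate(offsets):
                if ratios[k] < config.c:
                    g_img = model.grad(images[k])
                    grad[oy:oy + bh, ox:ox + bw] -= (
                        scale * window * g_img[rmin:rmax, cmin:cmax]
                        / (n * mei_activation))
            # d(loss)/dT for -lambda * min pairwise distance
            i, j, d = _min_pair(images, masks.m_mei)
            if d > 0:
                pg = m2 * (np.asarray(images[i]) - np.asarray(images[j])) / d
                oy, ox = offsets[i]
                grad[oy:oy + bh, ox:ox + bw] -= (lam_value * scale * window
                                                 * pg[rmin:rmax, cmin:cmax])
                oy, ox = offsets[j]
                grad[oy:oy + bh, ox:ox + bw] += (lam_value * scale * window
                                                 * pg[rmin:rmax, cmin:cmax])
            grad = ndimage.gaussian_filter(grad, config.grad_blur_sigma)
            texture = standardize(texture - lr * grad, clip=None)
        # final composites with the shared affine
        composites = []
        for oy, ox in offsets:
            comp = fixed.copy()
            comp[rmin:rmax, cmin:cmax] += window * texture[oy:oy + bh, ox:ox + bw]
            composites.append(comp)
        mu = np.mean([c.mean() for c in composites])
        sd = max(np.mean([c.std() for c in composites]), 1e-12)
        scale = config.std_rms / sd
        images = [np.clip((c - mu) * scale + config.std_mean, *config.clip)
                  for c in composites]
        return texture, images

    best = None
    for lam_value in lam_grid:
        texture, images = run(float(lam_value), canvas.texture)
        acts = scorer.respond_batch(images)
        dists = pairwise_masked_distances(images, masks.m_mei)
        cand = VEISet(images=images, activations=acts, lambda_used=float(lam_value),
                      min_pairwise_distance=float(dists.min()),
                      mean_pairwise_distance=float(dists.mean()),
                      meta={"min_activation_ratio": float(acts.min() / mei_activation),
                            "offsets": offsets})
        feasible = cand.meta["min_activation_ratio"] >= config.c
        if feasible:
            best = cand          # grid is increasing: keep the largest feasible
        elif best is None and lam_value == lam_grid[0]:
            cand.constraint_violated = True
            best = cand
    return best


def harmonic_selection(series) -> int:
    """Argmax of the harmonic mean H = 2 r d / (r + d) over a series of
    (mean activation, mean pairwise distance) pairs, each normalized by its
    maximum over the series."""
    pairs = np.asarray([(m[0], m[1]) for m in series], dtype=float)
    if len(pairs) < 2:
        raise ValueError("need at least 2 series members")
    r = pairs[:, 0]
    d = pairs[:, 1]
    if np.max(r) <= 0:
        raise ValueError("all-zero activation in the series")
    r = r / r.max()
    d = d / d.max() if d.max() > 0 else d
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(r + d > 0, 2.0 * r * d / (r + d), 0.0)
    return int(np.argmax(h))


def fit_activation_spline(sizes, activations, k: int = 2):
    """Quadratic smoothing spline of activation versus subfield size, with the
    smoothing parameter chosen by leave-one-out error over the series.

    Duplicate sizes are aggregated by their mean before fitting.
    """
    sizes = np.asarray(sizes, dtype=float)
    activations = np.asarray(activations, dtype=float)
    order = np.argsort(sizes)
    xs, ys = [], []
    for x in np.unique(sizes[order]):
        xs.append(x)
        ys.append(activations[sizes == x].mean())
    xs = np.array(xs)
    ys = np.array(ys)
    if len(xs) < 3:
        raise ValueError("need at least 3 distinct series points")
    n = len(xs)
    var = max(ys.var(), 1e-12)
    candidates = [f * n * var for f in (0.0, 0.001, 0.01, 0.05, 0.1, 0.3)]
    best_s, best_err = candidates[-1], np.inf
    if n >= 5:
        for s in candidates:
            errs = []
            for i in range(n):
                keep = np.arange(n) != i
                try:
                    sp = UnivariateSpline(xs[keep], ys[keep], k=k, s=s)
                except Exception:
                    errs = None
                    break
                errs.append((float(sp(xs[i])) - ys[i]) ** 2)
            if errs is not None and np.mean(errs) < best_err:
                best_err = float(np.mean(errs))
                best_s = s
    return UnivariateSpline(xs, ys, k=min(k, n - 1), s=best_s)


def bipartite_invariance_index(series) -> float:
    """AUC of the spline-fit activation-versus-size curve on [0, 1].

    ``series`` is a sequence of (variable-subfield relative size, normalized
    activation ratio) pairs; activations are clamped to [0, 1] before the
    trapezoidal integration over 101 uniform size samples.
    """
    pts = np.asarray(series, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 series points")
    spline = fit_activation_spline(pts[:, 0], np.clip(pts[:, 1], 0.0, 1.0))
    grid = np.linspace(0.0, 1.0, 101)
    curve = np.clip(spline(grid), 0.0, 1.0)
    return float(np.trapezoid(curve, grid))


@dataclass
class SeriesMember:
    masks: SubfieldMasks
    canvas: TextureCanvas
    veis: VEISet
    mean_activation_ratio: float
    mean_pairwise_distance: float


@dataclass
class BipartiteResult:
    series: list                      # SeriesMember per variance fraction
    full: SeriesMember                # m_v = m_mei (full-texture model)
    selected_index: int
    veis_partial: VEISet
    bii: float
    bii_points: np.ndarray = field(default=None)


def bipartite_analysis(model: ModelNeuron, mei: MEIResult, veis: VEISet,
                       fractions=DEFAULT_FRACTIONS,
                       config: SynthesisConfig | None = None,
                       n_steps: int = 1000, n_crops: int = 16,
                       n_render: int = 20, n_refine_iters: int = 300,
                       refine_lambda: float | None = None,
                       seed: int = 0) -> BipartiteResult:
    """Full bipartite pipeline for one neuron.

    Builds the variable-mask series from the VEIs' variance map, optimizes a
    texture per series member and for the full-texture model, jointly refines
    the texture-based VEIs under the activation-floor/diversity loss, selects
    VEIs_partial by the harmonic mean of normalized activation and diversity,
    and computes the BII from the activation-versus-size curve anchored at
    size 0 (pure MEI, ratio 1) and size 1 (full-texture model).
    """
    config = config or SynthesisConfig()
    # uniform in-silico presentation protocol: every stimulus, including the
    # MEI reference, is masked by the receptive-field mask and re-standardized
    # before its response is read out, so activation ratios compare
    # like-with-like
    masked_mei = standardize(mei.mask * mei.image, config.std_mean,
                             config.std_rms, config.clip)
    ref_activation = model.respond(masked_mei)
    if ref_activation <= 0:
        raise ValueError("masked MEI evokes no response")
    masks_series = variable_mask_series(veis, mei.mask, fractions)
    members = []
    for i, masks in enumerate(masks_series):
        fixed = masks.m_f * mei.image
        canvas = optimize_texture(model, masks, fixed, config, n_steps,
                                  n_crops, seed=seed + i)
        refined = refine_texture_veis(model, canvas, masks, fixed,
                                      ref_activation, config, n_render,
                                      n_refine_iters, seed=seed + i,
                                      lam=refine_lambda)
        members.append(SeriesMember(
            masks=masks, canvas=canvas, veis=refined,
            mean_activation_ratio=float(np.mean(refined.activations)
                                        / ref_activation),
            mean_pairwise_distance=refined.mean_pairwise_distance))
    full_masks = SubfieldMasks(m_mei=mei.mask, m_v=mei.mask,
                               m_f=np.zeros_like(mei.mask), variance_fraction=1.0)
    full_canvas = optimize_texture(model, full_masks, None, config, n_steps,
                                   n_crops, seed=seed + len(members))
    full_refined = refine_texture_veis(model, full_canvas, full_masks, None,
                                       ref_activation, config, n_render,
                                       n_refine_iters,
                                       seed=seed + len(members),
                                       lam=refine_lambda)
    full = SeriesMember(
        masks=full_masks, canvas=full_canvas, veis=full_refined,
        mean_activation_ratio=float(np.mean(full_refined.activations)
                                    / ref_activation),
        mean_pairwise_distance=full_refined.mean_pairwise_distance)

    selected = harmonic_selection(
        [(m.mean_activation_ratio, m.mean_pairwise_distance) for m in members])
    points = ([(0.0, 1.0)]
              + [(m.masks.size, m.mean_activation_ratio) for m in members]
              + [(1.0, full.mean_activation_ratio)])
    bii = bipartite_invariance_index(points)
    return BipartiteResult(series=members, full=full, selected_index=selected,
                           veis_partial=members[selected].veis, bii=bii,
                           bii_points=np.asarray(points))


def two_variable_veis(model: ModelNeuron, masks_series, mei: MEIResult,
                      config: SynthesisConfig | None = None,
                      n_steps: int = 1000, n_crops: int = 16,
                      n_render: int = 20, seed: int = 0) -> VEISet:
    """Control model in which BOTH subfields are shift-invariant textures.

    For each series member, a texture is optimized independently for the
    variable subfield and for its in-mask complement (each optimized with the
    other subfield filled by MEI content), random crops of the two are
    composited, and the harmonic-mean rule selects the returned set.
    """
    config = config or SynthesisConfig()
    candidates = []
    for i, masks in enumerate(masks_series):
        comp_masks = SubfieldMasks(m_mei=masks.m_mei, m_v=masks.m_f,
                                   m_f=masks.m_v,
                                   variance_fraction=1.0 - masks.variance_fraction)
        c1 = optimize_texture(model, masks, masks.m_f * mei.image, config,
                              n_steps, n_crops, seed=seed + 2 * i)
        c2 = optimize_texture(model, comp_masks, masks.m_v * mei.image, config,
                              n_steps, n_crops, seed=seed + 2 * i + 1)
        rng = np.random.default_rng(seed + i)
        shape = masks.m_mei.shape
        composites = []
        for o1, o2 in zip(c1.random_offsets(n_render, rng),
                          c2.random_offsets(n_render, rng)):
            composites.append(masks.m_v * c1.crop_to_image(o1, shape)
                              + masks.m_f * c2.crop_to_image(o2, shape))
        images = [standardize(c, config.std_mean, config.std_rms, config.clip)
                  for c in composites]
        acts = model.respond_batch(images)
        dists = pairwise_masked_distances(images, masks.m_mei)
        candidates.append(VEISet(
            images=images, activations=acts, lambda_used=np.nan,
            min_pairwise_distance=float(dists.min()),
            mean_pairwise_distance=float(dists.mean()),
            meta={"mean_activation_ratio": float(acts.mean() / mei.activation)}))
    idx = (0 if len(candidates) == 1 else harmonic_selection(
        [(s.meta["mean_activation_ratio"], s.mean_pairwise_distance)
         for s in candidates]))
    return candidates[idx]


@dataclass
class NoSpatialDivisionResult:
    veis: VEISet
    c_grid: np.ndarray
    activations: np.ndarray          # mean activation ratio per c
    diversities: np.ndarray          # mean pairwise distance per c

    def activation_at_matched_diversity(self, d_ref: float) -> float:
        """Spline-interpolated activation ratio at a reference diversity."""
        return self._interp(self.diversities, self.activations, d_ref)

    def diversity_at_matched_activation(self, r_ref: float) -> float:
        return self._interp(self.activations, self.diversities, r_ref)

    @staticmethod
    def _interp(x, y, x0) -> float:
        order = np.argsort(x)
        xs, ys = np.asarray(x)[order], np.asarray(y)[order]
        xs, keep = np.unique(xs, return_index=True)
        ys = ys[keep]
        if len(xs) >= 4:
            sp = UnivariateSpline(xs, ys, k=2, s=len(xs) * max(ys.var(), 1e-12) * 0.05)
            return float(sp(np.clip(x0, xs[0], xs[-1])))
        return float(np.interp(x0, xs, ys))


def no_spatial_division_veis(model: ModelNeuron, mei: MEIResult,
                             c_grid=None, config: SynthesisConfig | None = None,
                             n_steps: int = 1000, n_crops: int = 16,
                             n_render: int = 20, seed: int = 0) -> NoSpatialDivisionResult:
    """Control model with two fully overlapping subfields:

        VEI = (1 - c) * m_MEI * crop(T) + c * MEI,

    where c in [0, 1] weights the fixed MEI component (c = 1 reproduces the
    MEI; c = 0 is the full-texture model). The harmonic-mean rule selects the
    returned set; the stored per-c curves allow matched-activation /
    matched-diversity comparisons against other VEI sets.
    """
    config = config or SynthesisConfig()
    if c_grid is None:
        c_grid = np.linspace(0.0, 1.0, 6)
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any((c_grid < 0) | (c_grid > 1)):
        raise ValueError("c_grid must lie within [0, 1]")
    full_masks = SubfieldMasks(m_mei=mei.mask, m_v=mei.mask,
                               m_f=np.zeros_like(mei.mask), variance_fraction=1.0)
    candidates, acts, divs = [], [], []
    for i, c in enumerate(c_grid):
        if c >= 1.0:
            images = [mei.image.copy() for _ in range(n_render)]
            a = np.full(n_render, mei.activation)
            dists = np.array([0.0])
        else:
            canvas = optimize_texture(model, full_masks, c * mei.image, config,
                                      n_steps, n_crops, weight=1.0 - c,
                                      seed=seed + i)
            rendered = render_texture_veis(canvas, full_masks, c * mei.image,
                                           n_render, seed=seed + i,
                                           config=config, model=model)
            images, a = rendered.images, rendered.activations
            dists = pairwise_masked_distances(images, mei.mask)
        d_pairs = float(np.mean(dists))
        candidates.append(VEISet(
            images=images, activations=np.asarray(a), lambda_used=np.nan,
            min_pairwise_distance=float(np.min(dists)),
            mean_pairwise_distance=d_pairs,
            meta={"c": float(c)}))
        acts.append(float(np.mean(a) / mei.activation))
        divs.append(d_pairs)
    idx = harmonic_selection(list(zip(acts, divs)))
    return NoSpatialDivisionResult(veis=candidates[idx], c_grid=c_grid,
                                   activations=np.array(acts),
                                   diversities=np.array(divs))


def subfield_manipulation(mei: MEIResult, veis_partial: VEISet,
                          masks: SubfieldMasks, mode: str,
                          replacement_pool=None, replacement_canvas=None,
                          seed: int = 0) -> list[np.ndarray]:
    """Mask out or swap the content of one subfield of each partial-texture VEI.

    Modes: ``mask_fixed`` / ``mask_variable`` zero one subfield with a binary
    mask whose edge smoothing is restricted to regions outside the kept
    subfield, so the kept subfield's pixels stay bit-identical.
    ``swap_fixed_natural`` replaces the fixed-subfield content with natural
    crops matched in mean/RMS to the original fixed content;
    ``swap_variable_texture`` replaces the variable content with crops from a
    different neuron's texture canvas, contrast-matched likewise.
    """
    v_sup = masks.m_v > MASK_BINARIZE_THRESHOLD
    f_sup = masks.m_f > MASK_BINARIZE_THRESHOLD
    rng = np.random.default_rng(seed)

    def keep_mask(kept_support):
        smoothed = ndimage.gaussian_filter(kept_support.astype(float), 1.5)
        return np.where(kept_support, 1.0, smoothed)

    out = []
    if mode == "mask_fixed":
        w = keep_mask(v_sup)
        out = [as_array(im) * w for im in veis_partial.images]
    elif mode == "mask_variable":
        w = keep_mask(f_sup)
        out = [as_array(im) * w for im in veis_partial.images]
    elif mode == "swap_fixed_natural":
        if not replacement_pool:
            raise ValueError("swap_fixed_natural requires a replacement_pool")
        for im in veis_partial.images:
            arr = as_array(im)
            crop = as_array(replacement_pool[int(rng.integers(len(replacement_pool)))])
            ref = arr[f_sup]
            vals = crop[f_sup]
            if vals.std() == 0:
                raise ValueError("zero-variance replacement crop")
            matched = (vals - vals.mean()) / vals.std() * ref.std() + ref.mean()
            swapped = arr.copy()
            swapped[f_sup] = matched
            out.append(swapped)
    elif mode == "swap_variable_texture":
        if replacement_canvas is None:
            raise ValueError("swap_variable_texture requires a replacement_canvas")
        shape = masks.m_mei.shape
        for im in veis_partial.images:
            arr = as_array(im)
            o = replacement_canvas.random_offsets(1, rng)[0]
            crop = replacement_canvas.crop_to_image(o, shape)
            ref = arr[v_sup]
            vals = crop[v_sup]
            if vals.std() == 0:
                raise ValueError("zero-variance texture crop")
            matched = (vals - vals.mean()) / vals.std() * ref.std() + ref.mean()
            swapped = arr.copy()
            swapped[v_sup] = matched
            out.append(swapped)
    else:
        raise ValueError(f"unknown manipulation mode: {mode!r}")
    return out


def radial_power_spectrum(image, deg_per_pixel: float, n_bins: int = 10):
    """Mean power per radial frequency annulus, in ten equal-width bins over
    (0, Nyquist] cycles/degree. Returns (bin_centers, mean_power)."""
    arr = as_array(image)
    if np.all(arr == 0):
        raise ValueError("all-zero image has no power spectrum")
    power = np.abs(np.fft.fft2(arr)) ** 2
    fy = np.fft.fftfreq(arr.shape[0], d=deg_per_pixel)[:, None]
    fx = np.fft.fftfreq(arr.shape[1], d=deg_per_pixel)[None, :]
    freq = np.hypot(fy, fx)
    nyquist = 0.5 / deg_per_pixel
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.zeros(n_bins)
    for i in range(n_bins):
        sel = (freq > edges[i]) & (freq <= edges[i + 1])
        if sel.any():
            means[i] = power[sel].mean()
    return centers, means


def median_radial_frequency(images, deg_per_pixel: float, n_bins: int = 10) -> float:
    """Median frequency of the set-averaged radial power spectrum, by linear
    interpolation of the cumulative power over the bins."""
    spectra = []
    centers = None
    for im in images:
        centers, means = radial_power_spectrum(im, deg_per_pixel, n_bins)
        spectra.append(means)
    mean_spectrum = np.mean(spectra, axis=0)
    total = mean_spectrum.sum()
    if total <= 0:
        raise ValueError("zero total power")
    cum = np.cumsum(mean_spectrum) / total
    nyquist = 0.5 / deg_per_pixel
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    for i in range(n_bins):
        if cum[i] >= 0.5:
            prev = cum[i - 1] if i > 0 else 0.0
            frac = (0.5 - prev) / max(cum[i] - prev, 1e-15)
            return float(edges[i] + frac * (edges[i + 1] - edges[i]))
    return float(edges[-1])


def subfield_median_frequency(veis_partial, substituted_set,
                              deg_per_pixel: float, n_bins: int = 10):
    """Median radial frequencies of the partial-texture VEIs and of the set
    whose fixed-subfield content was substituted by texture crops.

    The two sets differ only in the fixed-subfield content, so the difference
    between the returned (f_fixed, f_variable) pair -- the median frequency of
    the original set versus the substituted (texture-everywhere) set -- is
    attributable to the fixed subfield. f_variable > f_fixed indicates a
    higher-frequency-preferring variable subfield.
    """
    images_a = veis_partial.images if isinstance(veis_partial, VEISet) else veis_partial
    images_b = (substituted_set.images if isinstance(substituted_set, VEISet)
                else substituted_set)
    f_fixed = median_radial_frequency(images_a, deg_per_pixel, n_bins)
    f_variable = median_radial_frequency(images_b, deg_per_pixel, n_bins)
    return f_fixed, f_variable
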