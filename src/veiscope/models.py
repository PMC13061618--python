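"""Analytic model neurons: Gabor simple cells and energy-model complex cells.

A simple cell responds with a rectified inner product between the stimulus and
a 2D Gabor filter; a complex cell (classical energy model) responds with the
magnitude of the outputs of a quadrature pair of Gabor filters, which makes it
invariant to the spatial phase of a preferred grating. Both are wrapped in the
:class:`ModelNeuron` contract -- a deterministic, differentiable map from an
image to a nonnegative scalar -- which all synthesis routines consume. Any
user-supplied predictor satisfying the same contract (``respond`` plus an
analytic ``grad``) can be used in place of the built-ins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .images import (
    DEFAULT_DEG_PER_PIXEL,
    DEFAULT_SHAPE,
    as_array,
    grid_coordinates,
)

#: Gaussian-envelope s.d. range (degrees) matched to receptive-field sizes of
#: mouse V1 L2/3 neurons
SIGMA_RANGE = (4.4, 10.9)


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a 2D Gabor: Gaussian envelope times a cosine grating.

    ``mu_x``/``mu_y`` center the envelope (degrees, x rightward along columns,
    y downward along rows), ``sigma`` is the envelope s.d. (degrees), ``theta``
    the grating orientation (radians), ``wavelength`` the grating period
    (degrees/cycle) and ``phase`` the cosine phase (radians).
    """

    mu_x: float = 0.0
    mu_y: float = 0.0
    sigma: float = 6.0
    theta: float = 0.0
    wavelength: float = 10.0
    phase: float = 0.0

    def __post_init__(self):
        vals = (self.mu_x, self.mu_y, self.sigma, self.theta,
                self.wavelength, self.phase)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("Gabor parameters must be finite")
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ValueError("sigma and wavelength must be positive")

    def shifted(self, dphase: float) -> "GaborParams":
        return GaborParams(self.mu_x, self.mu_y, self.sigma, self.theta,
                           self.wavelength, self.phase + dphase)


def gabor_image(params: GaborParams, shape=DEFAULT_SHAPE,
                deg_per_pixel=DEFAULT_DEG_PER_PIXEL) -> np.ndarray:
    """Evaluate the Gabor on the pixel grid (coordinates in degrees, centered).

    I(x, y) = exp(-((x-mu_x)^2 + (y-mu_y)^2) / (2 sigma^2))
              * cos(2 pi (x cos theta + y sin theta) / wavelength + phase)
    """
    x, y = grid_coordinates(shape, deg_per_pixel)
    envelope = np.exp(-(((x - params.mu_x) ** 2 + (y - params.mu_y) ** 2)
                        / (2.0 * params.sigma**2)))
    carrier = np.cos(2.0 * np.pi * (x * np.cos(params.theta) + y * np.sin(params.theta))
                     / params.wavelength + params.phase)
    return envelope * carrier


@dataclass
class ModelNeuron:
    """Differentiable image -> nonnegative-response contract.

    ``respond`` must be deterministic given the image; ``grad`` returns the
    gradient of the response with respect to the pixels (same shape as the
    image). ``rf_center`` is the receptive-field center in (row, col) pixels.
    """

    respond: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    rf_center: tuple[float, float] = (0.0, 0.0)
    label: str = ""
    params: GaborParams | None = None
    #: optional vectorized responder (list of images -> array); synthesis
    #: loops fall back to per-image calls when absent
    batch: Callable | None = None

    def respond_batch(self, images) -> np.ndarray:
        if self.batch is not None:
            return np.asarray(self.batch(images), dtype=float)
        return np.array([self.respond(as_array(im)) for im in images])


def simple_cell_response(image, params: GaborParams, shape=None,
                         deg_per_pixel=DEFAULT_DEG_PER_PIXEL) -> float:
    """Rectified linear response: max(0, <image, gabor>)."""
    arr = as_array(image)
    filt = gabor_image(params, arr.shape, deg_per_pixel)
    return float(max(0.0, np.sum(arr * filt)))


def complex_cell_response(image, params: GaborParams, shape=None,
                          deg_per_pixel=DEFAULT_DEG_PER_PIXEL) -> float:
    """Energy-model response: sqrt(a^2 + b^2) over a quadrature filter pair."""
    arr = as_array(image)
    f1 = gabor_image(params, arr.shape, deg_per_pixel)
    f2 = gabor_image(params.shifted(np.pi / 2.0), arr.shape, deg_per_pixel)
    a = np.sum(arr * f1)
    b = np.sum(arr * f2)
    return float(np.hypot(a, b))


def _center_pixels(params: GaborParams, shape, deg_per_pixel):
    rows, cols = shape
    return ((rows - 1) / 2.0 + params.mu_y / deg_per_pixel,
            (cols - 1) / 2.0 + params.mu_x / deg_per_pixel)


def make_simple_cell(params: GaborParams, shape=DEFAULT_SHAPE,
                     deg_per_pixel=DEFAULT_DEG_PER_PIXEL,
                     label: str = "simple") -> ModelNeuron:
    """A noiseless simple cell as a ModelNeuron with analytic gradient."""
    filt = gabor_image(params, shape, deg_per_pixel)

    def respond(image):
        return float(max(0.0, np.sum(as_array(image) * filt)))

    def grad(image):
        # Below threshold the rectifier's true gradient vanishes; return the
        # gradient of the underlying linear drive instead so gradient ascent
        # can escape the dead zone (ascending the drive is the unique
        # direction that can ever re-activate the cell).
        return filt.copy()

    return ModelNeuron(respond, grad, _center_pixels(params, shape, deg_per_pixel),
                       label, params)


def make_complex_cell(params: GaborParams, shape=DEFAULT_SHAPE,
                      deg_per_pixel=DEFAULT_DEG_PER_PIXEL,
                      label: str = "complex") -> ModelNeuron:
    """A noiseless energy-model complex cell with analytic gradient."""
    f1 = gabor_image(params, shape, deg_per_pixel)
    f2 = gabor_image(params.shifted(np.pi / 2.0), shape, deg_per_pixel)

    def respond(image):
        arr = as_array(image)
        return float(np.hypot(np.sum(arr * f1), np.sum(arr * f2)))

    def grad(image):
        arr = as_array(image)
        a = np.sum(arr * f1)
        b = np.sum(arr * f2)
        r = np.hypot(a, b)
        if r == 0:
            return np.zeros_like(f1)
        return (a * f1 + b * f2) / r

    return ModelNeuron(respond, grad, _center_pixels(params, shape, deg_per_pixel),
                       label, params)


def sample_gabor_population(n_cells: int, seed: int,
                            sigma_range=SIGMA_RANGE) -> list[GaborParams]:
    """Draw Gabor parameters for a simulated cell population.

    theta ~ U[0, pi), phase ~ U[0, 2 pi), sigma ~ U over ``sigma_range``
    degrees and wavelength ~ U[sigma, 2 sigma] degrees/cycle, which enforces
    the constraint that the period not exceed twice the envelope s.d. (so the
    Gaussian window holds at least about one full cycle). Centers are at the
    grid origin.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_cells):
        sigma = rng.uniform(*sigma_range)
        out.append(GaborParams(
            mu_x=0.0, mu_y=0.0, sigma=sigma,
            theta=rng.uniform(0.0, np.pi),
            wavelength=rng.uniform(sigma, 2.0 * sigma),
            phase=rng.uniform(0.0, 2.0 * np.pi),
        ))
    return out


def simulate_cells(n_cells: int, kind: str, seed: int, shape=DEFAULT_SHAPE,
                   deg_per_pixel=DEFAULT_DEG_PER_PIXEL) -> list[ModelNeuron]:
    """Sample a population of noiseless simple or complex cells."""
    if kind not in ("simple", "complex"):
        raise ValueError("kind must be 'simple' or 'complex'")
    maker = make_simple_cell if kind == "simple" else make_complex_cell
    population = sample_gabor_population(n_cells, seed)
    return [maker(p, shape, deg_per_pixel, label=f"{kind}-{i}")
            for i, p in enumerate(population)]


def sample_poisson_responses(model: ModelNeuron, images, gain: float = 10.0,
                             seed: int = 0) -> np.ndarray:
    """Sample Poisson spike counts with mean ``gain * respond(image)``.

    The default gain of 10 puts the mean count of a strongly driven cell in
    the tens, a regime where the Poisson noise is informative but not
    overwhelming.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    rng = np.random.default_rng(seed)
    means = gain * model.respond_batch(images)
    return rng.poisson(means)
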