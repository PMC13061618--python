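"""Grayscale stimulus grids and the standardization used throughout synthesis.

All stimuli live on a fixed-size 2D grid (default 36 rows x 64 columns) in a
unitless, z-score-like intensity space. Synthetic stimuli are repeatedly
projected onto a fixed first- and second-moment budget -- mean 0 and
root-mean-square (RMS) contrast 0.25 -- so that they stay within the intensity
statistics that predictive models of visual cortex are trained on. Clipping to
a symmetric intensity range emulates the finite dynamic range of a display and
is always applied *after* the moment matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

DEFAULT_SHAPE = (36, 64)
DEFAULT_DEG_PER_PIXEL = 2.0
STD_MEAN = 0.0
STD_RMS = 0.25
#: symmetric clip bound in standardized units; wide enough that <~1% of pixels
#: of a standardized naturalistic (1/f) image clip
DEFAULT_CLIP = (-1.0, 1.0)


@dataclass
class ImageGrid:
    """A 2D grayscale stimulus with its pixel-to-degree conversion.

    Parameters
    ----------
    values : ndarray of shape (rows, cols)
        Standardized (unitless) intensities; row 0 is the top of the image.
    deg_per_pixel : float
        Visual angle subtended by one pixel, in degrees.
    """

    values: np.ndarray
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ImageGrid values must be a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.values.copy(), self.deg_per_pixel, dict(self.meta))


def as_array(image) -> np.ndarray:
    """Coerce an ImageGrid or array-like to a float 2D array."""
    if isinstance(image, ImageGrid):
        return image.values
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    return arr


def grid_coordinates(shape=DEFAULT_SHAPE, deg_per_pixel=DEFAULT_DEG_PER_PIXEL):
    """Pixel-center coordinates in degrees, origin at the grid center.

    Returns (x, y) meshgrids with x increasing along columns and y along rows.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("grid shape must be positive")
    y = (np.arange(rows) - (rows - 1) / 2.0) * deg_per_pixel
    x = (np.arange(cols) - (cols - 1) / 2.0) * deg_per_pixel
    return np.meshgrid(x, y)


def standardize(
    image,
    mean_target: float = STD_MEAN,
    rms_target: float = STD_RMS,
    clip: tuple[float, float] | None = DEFAULT_CLIP,
):
    """Project an image onto a fixed mean and RMS contrast, then clip.

    RMS contrast is the standard deviation of pixel intensities (population
    denominator). Clipping is applied last, so the post-clip moments can
    deviate slightly for heavy-tailed inputs. Raises on zero-variance input,
    for which the contrast target is unreachable.
    """
    arr = as_array(image)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot standardize a non-finite image")
    centered = arr - arr.mean()
    rms = np.sqrt(np.mean(centered**2))
    if rms == 0:
        raise ValueError("cannot standardize a zero-variance image")
    out = centered * (rms_target / rms) + mean_target
    if clip is not None:
        out = np.clip(out, clip[0], clip[1])
    if isinstance(image, ImageGrid):
        return ImageGrid(out, image.deg_per_pixel, dict(image.meta))
    return out


def is_standardized(image, mean_target=STD_MEAN, rms_target=STD_RMS,
                    mean_tol=1e-6, rms_tol=1e-3) -> bool:
    arr = as_array(image)
    rms = arr.std()
    return abs(arr.mean() - mean_target) <= mean_tol and abs(rms - rms_target) <= rms_tol


def masked_distance(a, b, mask) -> float:
    """Euclidean distance between two images inside a weighted mask.

    Each pixel difference is weighted by the mask value before the L2 norm is
    taken, i.e. ``||m * (a - b)||_2``. With a binary mask this reduces to the
    plain Euclidean distance restricted to the mask support.
    """
    a = as_array(a)
    b = as_array(b)
    m = as_array(mask)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("images and mask must share one grid")
    diff = m * (a - b)
    return float(np.sqrt(np.sum(diff**2)))


def pairwise_masked_distances(images, mask) -> np.ndarray:
    """Condensed vector of masked distances over all unordered pairs."""
    stack = np.stack([as_array(im) for im in images])
    m = as_array(mask)
    flat = (stack * m).reshape(len(stack), -1)
    sq = np.sum(flat**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    iu = np.triu_indices(len(stack), k=1)
    return np.sqrt(np.maximum(d2[iu], 0.0))


# ---------------------------------------------------------------------------
# I/O: 16-bit grayscale PNG with a JSON sidecar holding the affine transform
# back to standardized units, plus plain CSV.

def save_png(image: ImageGrid | np.ndarray, path, deg_per_pixel=DEFAULT_DEG_PER_PIXEL):
    path = Path(path)
    arr = as_array(image)
    if isinstance(image, ImageGrid):
        deg_per_pixel = image.deg_per_pixel
    lo, hi = float(arr.min()), float(arr.max())
    scale = (hi - lo) if hi > lo else 1.0
    quant = np.round((arr - lo) / scale * 65535).astype(np.uint16)
    Image.fromarray(quant).save(path)
    sidecar = {
        "lo": lo,
        "hi": hi,
        "deg_per_pixel": deg_per_pixel,
        "mean": float(arr.mean()),
        "rms": float(arr.std()),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_png(path) -> ImageGrid:
    path = Path(path)
    quant = np.asarray(Image.open(path), dtype=float)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    lo, hi = sidecar["lo"], sidecar["hi"]
    denom = 65535.0 if quant.max() > 255 else 255.0
    arr = quant / denom * (hi - lo) + lo
    return ImageGrid(arr, sidecar.get("deg_per_pixel", DEFAULT_DEG_PER_PIXEL))


def save_csv(image, path):
    np.savetxt(path, as_array(image), delimiter=",")


def load_csv(path, deg_per_pixel=DEFAULT_DEG_PER_PIXEL) -> ImageGrid:
    return ImageGrid(np.loadtxt(path, delimiter=","), deg_per_pixel)
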