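"""Gabor front-end: grayscale raster image -> stimulus director field.

The pipeline mirrors classical V1 edge extraction: the image is binarized,
convolved with an even-symmetric (cosine-phase) Gabor filter at ``n_angles``
evenly spaced orientations, and at every pixel the angle with the maximal
response becomes the local orientation while the response itself (clipped at
zero) becomes the field magnitude.  The result is encoded as a director
field and can be fed straight into the dynamics.

Filters are evaluated from the analytic expression

    G_theta(x, y) = exp(-(x^2 + y^2) / (2 s^2)) * cos(2 pi u / lambda),
    u = -x sin(theta) + y cos(theta)   (coordinate perpendicular to theta),

with the mean subtracted so each filter is DC-free (a uniform image yields a
zero field; image borders are handled by reflection).  Filters at multiples
of pi/2 are built by rotating the canonical filter on the grid, so the pi/2
filter equals the 90-degree-rotated canonical filter exactly.  Argmax ties
are broken toward the lowest angle index (stable and documented).
"""

from __future__ import annotations

from dataclasses import dataclass

import math
import numpy as np
from scipy.ndimage import convolve as _nd_convolve

from .field import DirectorField

__all__ = [
    "GaborConfig",
    "GaborBank",
    "gabor_filter",
    "build_gabor_bank",
    "image_to_field",
    "load_grayscale",
]


@dataclass(frozen=True)
class GaborConfig:
    n_angles: int = 12
    wavelength: float = 6.0  # carrier wavelength, pixels
    envelope_sd: float = 3.0  # Gaussian envelope sd, pixels
    n_stds: float = 3.0  # half-extent of the filter grid, in envelope sds

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        if self.wavelength <= 0 or self.envelope_sd <= 0:
            raise ValueError("wavelength and envelope_sd must be > 0")


@dataclass
class GaborBank:
    config: GaborConfig
    filters: np.ndarray  # (n_angles, K, K), zero-mean
    angles: np.ndarray


def gabor_filter(config: GaborConfig, theta: float) -> np.ndarray:
    """One even-symmetric, zero-mean Gabor filter detecting orientation ``theta``.

    The carrier varies along the direction *perpendicular* to theta, so the
    filter responds maximally to a line oriented at theta.  Exact multiples
    of pi/2 are built by rotating the canonical (theta = 0) filter on the
    grid, so those rotations are grid-exact.
    """
    theta = theta % math.pi
    for k in (0, 1):
        if abs(theta - k * math.pi / 2) < 1e-12:
            canonical = _canonical_filter(config)
            return np.rot90(canonical, k=-k) if k else canonical
    M = max(1, math.ceil(config.n_stds * config.envelope_sd))
    coords = np.arange(-M, M + 1, dtype=float)
    x, y = np.meshgrid(coords, coords, indexing="xy")
    env = np.exp(-(x**2 + y**2) / (2 * config.envelope_sd**2))
    c, s = math.cos(theta), math.sin(theta)
    # perpendicular coordinate: the filter's stripes run along theta
    carrier = np.cos(2 * math.pi * (-s * x + c * y) / config.wavelength)
    g = env * carrier
    return g - g.mean()


def _canonical_filter(config: GaborConfig) -> np.ndarray:
    M = max(1, math.ceil(config.n_stds * config.envelope_sd))
    coords = np.arange(-M, M + 1, dtype=float)
    x, y = np.meshgrid(coords, coords, indexing="xy")
    env = np.exp(-(x**2 + y**2) / (2 * config.envelope_sd**2))
    g = env * np.cos(2 * math.pi * y / config.wavelength)
    return g - g.mean()


def build_gabor_bank(config: GaborConfig = GaborConfig()) -> GaborBank:
    """Even-symmetric, DC-free Gabor filters at n evenly spaced angles."""
    angles = np.array([k * math.pi / config.n_angles for k in range(config.n_angles)])
    filters = np.stack([gabor_filter(config, th) for th in angles])
    return GaborBank(config, filters, angles)


def load_grayscale(path) -> np.ndarray:
    """Read a PNG/PGM image as a float array in [0, 1]; must be single-channel."""
    from PIL import Image

    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16", "1", "F"):
        raise ValueError(
            f"image mode {img.mode!r} is multi-channel; convert to grayscale first"
        )
    arr = np.asarray(img, dtype=float)
    if arr.max() > 0:
        arr = arr / arr.max()
    return arr


def image_to_field(
    image: np.ndarray,
    bank: GaborBank | None = None,
    binarize_threshold: float = 0.5,
    normalize: bool = False,
) -> DirectorField:
    """Oriented-energy estimate of an image as a director field.

    ``binarize_threshold`` is a fraction of the maximum intensity; the image
    is thresholded to {0, 1} before filtering.  Per pixel, the orientation is
    the argmax filter angle (ties -> lowest index) and the magnitude the
    winning response, clipped at zero.  ``normalize=True`` rescales
    magnitudes to a maximum of 1 for use as a stimulus.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image; convert to grayscale first")
    if not (0 <= binarize_threshold <= 1):
        raise ValueError("binarize_threshold must be in [0, 1]")
    bank = bank or build_gabor_bank()
    binary = (image > binarize_threshold * image.max()).astype(float)
    responses = np.stack([_nd_convolve(binary, flt, mode="reflect") for flt in bank.filters])
    best = np.argmax(responses, axis=0)  # first maximal index wins ties
    mag = np.take_along_axis(responses, best[None], axis=0)[0]
    mag = np.clip(mag, 0.0, None)
    if normalize and mag.max() > 0:
        mag = mag / mag.max()
    values = mag * np.exp(2j * bank.angles[best])
    values[mag == 0] = 0.0
    return DirectorField(values)
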