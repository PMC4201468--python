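"""Coarse-grained director field on a periodic square lattice.

The neural state of a small cortical patch is summarized by two numbers: the
mean firing rate rho >= 0 and the dominant edge orientation theta of the
stimuli the patch responds to.  Orientation is a *director* -- an axis, not an
arrow -- so theta and theta + pi are the same physical state, and two equal
orthogonal edges cancel (cross-orientation suppression) rather than average.
Both facts are captured by storing the single complex number

    psi = rho * exp(2j * theta)

per lattice site: the doubled angle makes the encoding parity-invariant and
makes orthogonal contributions antiparallel in the complex plane.

Conventions used everywhere in this package:

* lattice sites are 0-based ``(row, col)`` integer pairs on an L x L grid with
  periodic wrap in both axes;
* the site <-> complex-plane map is ``z = col + 1j * row``;
* orientations are measured counterclockwise from the positive real
  (horizontal) axis and reduced modulo pi;
* sites with zero magnitude carry an *undefined* orientation (NaN in
  :class:`OrientationMap`), never an implicit horizontal bias.

Orientations are canonicalized modulo pi before the complex exponential is
formed, so theta and theta + pi produce the same stored value up to the
last-ulp rounding of the reduction itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from typing import Mapping

import numpy as np

__all__ = ["DirectorField", "OrientationMap", "active_mask"]


def _reduce_mod_pi(theta: np.ndarray) -> np.ndarray:
    out = np.mod(theta, np.pi)
    # np.mod may return pi itself for inputs a hair below a multiple of pi
    out = np.where(out >= np.pi, 0.0, out)
    return out


@dataclass
class OrientationMap:
    """Per-site (rate, orientation) view of a director field.

    ``orientation`` is in [0, pi) and is NaN wherever ``rate == 0``.
    """

    rate: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.rate.shape != self.orientation.shape:
            raise ValueError("rate and orientation must share a shape")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")

    @property
    def undefined(self) -> np.ndarray:
        """Boolean mask of sites whose orientation is undefined (zero rate)."""
        return self.rate == 0


@dataclass
class DirectorField:
    """Complex-valued neural field psi on an L x L periodic lattice.

    ``abs(values)`` is the coarse-grained firing rate, ``angle(values) / 2``
    the dominant orientation.  ``meta`` carries provenance (dt, time index,
    seed) for serialization; it never affects numerics.
    """

    values: np.ndarray
    meta: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("director field must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("director field values must be finite")

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def zeros(cls, L: int, meta: Mapping | None = None) -> "DirectorField":
        return cls(np.zeros((L, L), dtype=complex), dict(meta or {}))

    @classmethod
    def from_orientation_map(cls, m: OrientationMap, meta: Mapping | None = None) -> "DirectorField":
        """Encode (rate, orientation) pairs as ``rate * exp(2j * orientation)``.

        Orientations at zero-rate sites (NaN allowed there) are ignored.
        """
        if np.any(m.rate < 0):
            raise ValueError("rates must be non-negative")
        theta = _reduce_mod_pi(np.where(m.rate > 0, m.orientation, 0.0))
        values = m.rate * np.exp(2j * theta)
        values[m.rate == 0] = 0.0
        return cls(values, dict(meta or {}))

    # ------------------------------------------------------------------ #
    # views
    # ------------------------------------------------------------------ #
    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def orientation_map(self) -> OrientationMap:
        """Decode to (rate, orientation); inverse of :meth:`from_orientation_map`.

        Zero-magnitude sites get orientation NaN (undefined), flagged through
        :attr:`OrientationMap.undefined`.
        """
        rho = np.abs(self.values)
        theta = _reduce_mod_pi(np.angle(self.values) / 2.0)
        theta = np.where(rho > 0, theta, np.nan)
        return OrientationMap(rho, theta)

    # ------------------------------------------------------------------ #
    # thresholding
    # ------------------------------------------------------------------ #
    def active_mask(self, cutoff: float, mode: str = "absolute") -> np.ndarray:
        """Sites considered *active*: magnitude strictly above a threshold.

        ``mode='absolute'`` uses the cutoff directly; ``mode='relative'``
        interprets ``cutoff`` in [0, 1] as a fraction of the current maximum
        magnitude (an all-zero field then yields an empty mask).
        """
        return active_mask(self, cutoff, mode)

    def copy(self) -> "DirectorField":
        return DirectorField(self.values.copy(), dict(self.meta))


def active_mask(f: DirectorField, cutoff: float, mode: str = "absolute") -> np.ndarray:
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    mag = f.magnitude
    if mode == "absolute":
        threshold = cutoff
    elif mode == "relative":
        if cutoff > 1:
            raise ValueError("relative cutoff must be <= 1 (fraction of max magnitude)")
        threshold = cutoff * mag.max(initial=0.0)
    else:
        raise ValueError(f"unknown cutoff mode: {mode!r}")
    return mag > threshold
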