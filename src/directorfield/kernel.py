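"""Co-circular "bow-tie" excitatory interaction kernel.

Two oriented edge elements are *co-circular* when both are tangent to one
common circle.  For a source edge at the origin oriented along the real axis,
the circle through the origin tangent to the real axis and passing through a
displacement z has

    tangent orientation at z :  arg(z)            (mod pi, doubled -> 2*arg z,
                                                   director phase 4*arg z)
    radius                   :  |z|^2 / (2 |Im z|)  (infinite on the axis).

The excitatory kernel points each target site toward its co-circular
orientation and damps the weight by (i) a Gaussian of range sigma in the
displacement and (ii) a curvature gate suppressing circles tighter than
R_min.  The whole functional form lives in :func:`kernel_weight` so it can be
swapped in one place:

    K(z) = exp(i * 4 * arg z) * exp(-|z|^2 / sigma^2)
                              * exp(-(R_min / R_c(z))^2),        K(0) = 0,

with R_c(z) the co-circle radius above.  On the real axis the curvature gate
is 1 (straight continuation); toward the imaginary axis it collapses, giving
the kernel its bow-tie shape.  K is even, K(-z) = K(z): the phase gains
4 * pi under point reflection and both damping factors are even.

A source whose own orientation is theta excites with the rotated kernel

    K_theta(z) = exp(2j * theta) * K(z * exp(-1j * theta)),

evaluated analytically at the exact rotated coordinates (no lattice
resampling, which would re-introduce square-lattice anisotropy).  A
nearest-lattice-point compatibility mode is available in the dynamics engine.
:class:`KernelBank` precomputes the rotated kernel for a set of evenly spaced
source-orientation bins covering [0, pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field

import numpy as np

__all__ = [
    "KernelParams",
    "KernelBank",
    "cocircular_director_phase",
    "cocircle_radius",
    "kernel_weight",
    "build_base_kernel",
    "rotate_kernel",
    "build_kernel_bank",
    "orientation_bin",
]


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the co-circular kernel.

    sigma : spatial range of excitation (lattice units), > 0.
    R_min : smallest co-circle radius with substantial excitation
            (lattice units), >= 0; 0 disables the curvature gate.
    half_width : integer half-extent M of the (2M+1) x (2M+1) kernel lattice;
            defaults to ceil(3 * sigma), the effective range of the Gaussian.
    n_angle_bins : number of source-orientation bins of the rotated bank.
    """

    sigma: float
    R_min: float
    half_width: int | None = None
    n_angle_bins: int = 64

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.R_min < 0:
            raise ValueError("R_min must be >= 0")
        if self.half_width is not None and self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.n_angle_bins < 4:
            raise ValueError("n_angle_bins must be >= 4")

    @property
    def M(self) -> int:
        """Kernel lattice half-extent actually used."""
        return self.half_width if self.half_width is not None else max(1, math.ceil(3 * self.sigma))

    @property
    def bin_width(self) -> float:
        return np.pi / self.n_angle_bins


def cocircular_director_phase(z) -> np.ndarray | float:
    """Director phase (twice the orientation) of the co-circular edge at z.

    The co-circular tangent orientation at z is arg(z) mod pi, hence the
    director phase is 4 * arg(z), returned in [0, 2*pi).
    """
    z = np.asarray(z, dtype=complex)
    if np.any(z == 0):
        raise ValueError("co-circular phase is undefined at z = 0")
    phase = np.mod(4.0 * np.angle(z), 2.0 * np.pi)
    return phase if phase.ndim else float(phase)


def cocircle_radius(z) -> np.ndarray | float:
    """Radius |z|^2 / (2 |Im z|) of the co-circle through 0 and z.

    Infinite on the real axis (straight-line continuation).
    """
    z = np.asarray(z, dtype=complex)
    if np.any(z == 0):
        raise ValueError("co-circle radius is undefined at z = 0")
    y = np.abs(z.imag)
    with np.errstate(divide="ignore"):
        r = np.where(y > 0, (z.real**2 + z.imag**2) / (2.0 * y), np.inf)
    return r if r.ndim else float(r)


def kernel_weight(z, sigma: float, R_min: float) -> np.ndarray:
    """Analytic co-circular kernel K(z); the single place its form is defined.

    Vectorized over z; K(0) = 0 (a site never excites itself).
    """
    z = np.asarray(z, dtype=complex)
    r2 = z.real**2 + z.imag**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phase = np.exp(4j * np.arctan2(z.imag, z.real))
        gauss = np.exp(-r2 / sigma**2)
        # (R_min / R_c)^2 = 4 R_min^2 Im(z)^2 / |z|^4
        curv = np.exp(-4.0 * R_min**2 * z.imag**2 / np.where(r2 > 0, r2**2, 1.0))
        w = phase * gauss * curv
    return np.where(r2 > 0, w, 0.0 + 0.0j)


def _offset_grid(M: int) -> np.ndarray:
    """Complex displacement grid z = dcol + 1j * drow, shape (2M+1, 2M+1)."""
    d = np.arange(-M, M + 1)
    dcol, drow = np.meshgrid(d, d, indexing="xy")
    return dcol + 1j * drow


@dataclass
class KernelBank:
    """Precomputed rotated kernels, one per source-orientation bin.

    ``rotated[k]`` is the kernel for source orientation k * pi / n_angle_bins,
    evaluated analytically at exact rotated coordinates; ``rotated[0]`` is the
    base kernel (source parallel to the real axis).
    """

    params: KernelParams
    rotated: np.ndarray  # (n_bins, 2M+1, 2M+1) complex
    offsets: np.ndarray = _dc_field(repr=False, default=None)  # complex grid

    def __post_init__(self) -> None:
        if self.offsets is None:
            self.offsets = _offset_grid(self.params.M)

    @property
    def base(self) -> np.ndarray:
        return self.rotated[0]

    @property
    def bin_width(self) -> float:
        return self.params.bin_width


def build_base_kernel(params: KernelParams) -> np.ndarray:
    """The canonical kernel (source orientation 0) on its (2M+1)^2 lattice."""
    return kernel_weight(_offset_grid(params.M), params.sigma, params.R_min)


def rotate_kernel(bank: KernelBank | KernelParams, theta: float) -> np.ndarray:
    """Kernel for a source of orientation theta, by analytic re-evaluation.

    K_theta(z) = exp(2j*theta) * K(z * exp(-1j*theta)); theta acts mod pi
    (director parity), and multiples of pi/2 are snapped so rotation by pi
    returns the base kernel exactly.
    """
    params = bank.params if isinstance(bank, KernelBank) else bank
    theta = float(theta) % np.pi
    # snap exact quarter turns so parity/90-degree identities hold bitwise
    for k in range(2):
        if abs(theta - k * np.pi / 2) < 1e-15:
            theta = k * np.pi / 2
    z = _offset_grid(params.M)
    if theta == 0.0:
        return kernel_weight(z, params.sigma, params.R_min)
    c, s = np.cos(theta), np.sin(theta)
    if theta == np.pi / 2:
        c, s = 0.0, 1.0
    rot = complex(c, -s)  # exp(-1j*theta)
    phase = complex(c, s) ** 2  # exp(2j*theta)
    return phase * kernel_weight(z * rot, params.sigma, params.R_min)


def build_kernel_bank(params: KernelParams) -> KernelBank:
    """Precompute the rotated kernel for every source-orientation bin."""
    M = params.M
    n = params.n_angle_bins
    rotated = np.empty((n, 2 * M + 1, 2 * M + 1), dtype=complex)
    for k in range(n):
        rotated[k] = rotate_kernel(params, k * params.bin_width)
    return KernelBank(params, rotated)


def orientation_bin(theta, n_angle_bins: int) -> np.ndarray:
    """Nearest source-orientation bin index for orientation theta (mod pi)."""
    theta = np.mod(np.asarray(theta, dtype=float), np.pi)
    idx = np.rint(theta / (np.pi / n_angle_bins)).astype(np.int64)
    return np.mod(idx, n_angle_bins)
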