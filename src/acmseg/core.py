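"""Shared level-set machinery.

Regularized Heaviside/Dirac pair, finite-difference differential
operators, curvature, the distance-regularization force, binary-step
initialization of the level-set function, and mask extraction.

Conventions (used uniformly by every model in this package):

* ``phi > 0`` denotes *inside* the contour; the region fitted by the
  inside statistics (e1, h1, g11, g12).
* First/second derivatives by central differences, Laplacian by the
  5-point stencil, replicate (Neumann) boundary handling.
* ``|grad phi|`` is floored at 1e-10 wherever it divides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

GRAD_FLOOR = 1e-10


@dataclass
class ImageGrid:
    """A 2-D grayscale image on the normalized [0, 1] intensity scale.

    ``intensity_levels`` records the native dynamic range of the source
    (255 for 8-bit, 65535 for 16-bit); it sets the squared scale factor
    applied to the data terms of the evolution equations.
    """

    values: np.ndarray
    intensity_levels: int = 255

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.values.shape[0] < 3 or self.values.shape[1] < 3:
            raise ValueError("image must be at least 3x3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("image values must lie in [0, 1]; normalize first")

    @property
    def shape(self):
        return self.values.shape

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def heaviside_eps(phi, epsilon: float):
    """Regularized Heaviside 0.5*(1 + (2/pi)*arctan(phi/epsilon))."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(phi, dtype=np.float64) / epsilon))


def dirac_eps(phi, epsilon: float):
    """Regularized Dirac delta epsilon / (pi * (phi**2 + epsilon**2)).

    Exactly the phi-derivative of :func:`heaviside_eps`; even in phi and
    maximal (1/(pi*epsilon)) at phi = 0.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    phi = np.asarray(phi, dtype=np.float64)
    return epsilon / (np.pi * (phi * phi + epsilon * epsilon))


def _dx(a: np.ndarray) -> np.ndarray:
    """Central difference along axis 1 with replicated borders."""
    p = np.pad(a, ((0, 0), (1, 1)), mode="edge")
    return 0.5 * (p[:, 2:] - p[:, :-2])


def _dy(a: np.ndarray) -> np.ndarray:
    """Central difference along axis 0 with replicated borders."""
    p = np.pad(a, ((1, 1), (0, 0)), mode="edge")
    return 0.5 * (p[2:, :] - p[:-2, :])


def gradient(a: np.ndarray):
    return _dy(a), _dx(a)


def gradient_magnitude(a: np.ndarray) -> np.ndarray:
    gy, gx = gradient(a)
    return np.sqrt(gy * gy + gx * gx)


def laplacian(a: np.ndarray) -> np.ndarray:
    """5-point Laplacian with replicate boundaries."""
    p = np.pad(a, 1, mode="edge")
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * a


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|), the mean curvature of the level lines.

    The gradient magnitude is floored at ``GRAD_FLOOR`` so flat fields
    return an exactly-zero curvature.
    """
    phi = np.asarray(phi, dtype=np.float64)
    gy, gx = gradient(phi)
    mag = np.sqrt(gy * gy + gx * gx)
    mag = np.maximum(mag, GRAD_FLOOR)
    return _dy(gy / mag) + _dx(gx / mag)


def distance_regularization(phi: np.ndarray) -> np.ndarray:
    """Gradient-descent force of the penalty 0.5*(|grad phi| - 1)^2.

    Equals ``laplacian(phi) - curvature(phi)``; it relaxes phi toward a
    signed distance function without explicit reinitialization.
    """
    phi = np.asarray(phi, dtype=np.float64)
    return laplacian(phi) - curvature(phi)


def initialize_phi(shape, region0: np.ndarray, rho: float) -> np.ndarray:
    """Piecewise-constant binary-step initialization.

    +rho strictly inside ``region0``, 0 on its inner boundary ring
    (pixels of region0 with a 4-connected neighbour outside), and -rho
    outside. Positive phi marks the inside of the contour.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    region0 = np.asarray(region0, dtype=bool)
    if region0.shape != tuple(shape):
        raise ValueError("region0 shape does not match the grid")
    if not region0.any() or region0.all():
        raise ValueError("initial region must be nonempty and not cover the whole grid")
    interior = ndimage.binary_erosion(
        region0, structure=ndimage.generate_binary_structure(2, 1), border_value=1
    )
    boundary = region0 & ~interior
    phi = np.full(region0.shape, -float(rho))
    phi[interior] = float(rho)
    phi[boundary] = 0.0
    return phi


def default_init_region(shape, fraction: float = 0.4) -> np.ndarray:
    """Centered rectangle covering ``fraction`` of each dimension."""
    h, w = shape
    rh = max(3, int(round(h * fraction)))
    rw = max(3, int(round(w * fraction)))
    r0 = (h - rh) // 2
    c0 = (w - rw) // 2
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r0 + rh, c0 : c0 + rw] = True
    return mask


def phi_to_mask(phi: np.ndarray) -> np.ndarray:
    """Binary inside-mask. Pixels with phi exactly 0 count as outside."""
    return np.asarray(phi) > 0
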