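"""The three baseline region-based contour energies.

* Chan-Vese: inside/outside approximated by the global constants e1, e2.
* Local binary fitting (LBF): Gaussian-windowed local mean fields
  h1(x), h2(x), which track smooth intensity inhomogeneity.
* Global division: each side of the contour is split around its own mean
  into a brighter and a darker sub-population (g11, g12 inside; g21, g22
  outside), which copes with heavy noise and multi-level objects.

Each model provides a ``*_means`` statistics update, a discretized
energy (used for the descent trace and as the finite-difference
correctness oracle of the forces), a data-force field, and one
explicit-Euler evolution step

    phi <- phi + dt * ( dirac(phi) * (data + s^2 * nu * curvature)
                        + mu * (laplacian(phi) - curvature(phi)) )

where the data terms carry the squared native intensity range
s^2 = intensity_scale**2 (see :mod:`acmseg.params`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    curvature,
    dirac_eps,
    distance_regularization,
    gradient_magnitude,
    heaviside_eps,
)
from .params import ModelParams

DENOM_FLOOR = 1e-10
MASS_FLOOR = 1e-12


class DegenerateContourError(RuntimeError):
    """Raised when one side of the contour has (numerically) vanished."""


@dataclass
class FittingState:
    """Fitted intensity statistics of the current partition.

    e1/e2 are the global means inside/outside; h1/h2 the local mean
    fields; g11 >= g12 the brighter/darker means inside and g21 >= g22
    the brighter/darker means outside. All on the [0, 1] scale. Fields
    not used by a given model are None.
    """

    e1: Optional[float] = None
    e2: Optional[float] = None
    h1: Optional[np.ndarray] = None
    h2: Optional[np.ndarray] = None
    g11: Optional[float] = None
    g12: Optional[float] = None
    g21: Optional[float] = None
    g22: Optional[float] = None


def gaussian_blur(a: np.ndarray, sigma: float) -> np.ndarray:
    """Convolution with a sampled Gaussian truncated at 4*sigma.

    Zero padding: the windowed integrals run over the image domain only,
    so near the border the kernel mass shrinks. Quantities of the form
    G*(w I) / G*w self-normalize; absolute windowed sums must account
    for the mass field (:func:`gaussian_mass`).
    """
    return ndimage.gaussian_filter(np.asarray(a, dtype=np.float64), sigma,
                                   mode="constant", cval=0.0, truncate=4.0)


_MASS_CACHE: dict = {}


def gaussian_mass(shape, sigma: float) -> np.ndarray:
    """In-domain kernel mass G*1 (1 in the interior, < 1 near borders)."""
    key = (tuple(shape), float(sigma))
    if key not in _MASS_CACHE:
        _MASS_CACHE[key] = gaussian_blur(np.ones(shape), sigma)
    return _MASS_CACHE[key]


# ---------------------------------------------------------------- Chan-Vese

def cv_means(image: np.ndarray, phi: np.ndarray, epsilon: float) -> Tuple[float, float]:
    """Heaviside-weighted global means inside (e1) and outside (e2)."""
    h = heaviside_eps(phi, epsilon)
    m1 = h.sum()
    m2 = (1.0 - h).sum()
    if m1 < MASS_FLOOR or m2 < MASS_FLOOR:
        raise DegenerateContourError("a region has collapsed; cannot fit means")
    e1 = float((image * h).sum() / m1)
    e2 = float((image * (1.0 - h)).sum() / m2)
    return e1, e2


def cv_data_force(image: np.ndarray, e1: float, e2: float, params: ModelParams) -> np.ndarray:
    s2 = params.scale2
    return s2 * (-params.lambda1 * (image - e1) ** 2 + params.lambda2 * (image - e2) ** 2)


def cv_energy(image: np.ndarray, phi: np.ndarray, e1: float, e2: float,
              params: ModelParams, data_only: bool = False) -> float:
    h = heaviside_eps(phi, params.epsilon)
    s2 = params.scale2
    e = s2 * (params.lambda1 * ((image - e1) ** 2 * h).sum()
              + params.lambda2 * ((image - e2) ** 2 * (1.0 - h)).sum())
    if not data_only:
        e += s2 * params.nu * (dirac_eps(phi, params.epsilon) * gradient_magnitude(phi)).sum()
    return float(e)


def cv_evolve_step(image: np.ndarray, phi: np.ndarray, params: ModelParams) -> np.ndarray:
    """One explicit-Euler Chan-Vese update."""
    e1, e2 = cv_means(image, phi, params.epsilon)
    delta = dirac_eps(phi, params.epsilon)
    force = delta * (cv_data_force(image, e1, e2, params)
                     + params.scale2 * params.nu * curvature(phi))
    if params.mu > 0:
        force = force + params.mu * distance_regularization(phi)
    return phi + params.dt * force


# ------------------------------------------------------ local binary fitting

def lbf_means(image: np.ndarray, phi: np.ndarray, sigma: float,
              epsilon: float) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-windowed local means h1 (inside) and h2 (outside).

    h_i = G_sigma*(w_i I) / G_sigma*w_i with w1 = H_eps(phi) and
    w2 = 1 - w1; denominators floored at 1e-10.
    """
    w1 = heaviside_eps(phi, epsilon)
    num1 = gaussian_blur(w1 * image, sigma)
    den1 = gaussian_blur(w1, sigma)
    num_all = gaussian_blur(image, sigma)
    mass = gaussian_mass(image.shape, sigma)
    h1 = num1 / np.maximum(den1, DENOM_FLOOR)
    h2 = (num_all - num1) / np.maximum(mass - den1, DENOM_FLOOR)
    return h1, h2


def _lbf_pointwise_residuals(image: np.ndarray, h1: np.ndarray, h2: np.ndarray,
                             sigma: float) -> Tuple[np.ndarray, np.ndarray]:
    """F_i(y) = sum_x G(x-y) (I(y) - h_i(x))^2 via the three-convolution
    expansion I^2 (G*1) - 2 I (G*h_i) + G*(h_i^2)."""
    i2 = image * image * gaussian_mass(image.shape, sigma)
    f1 = i2 - 2.0 * image * gaussian_blur(h1, sigma) + gaussian_blur(h1 * h1, sigma)
    f2 = i2 - 2.0 * image * gaussian_blur(h2, sigma) + gaussian_blur(h2 * h2, sigma)
    return f1, f2


def lbf_data_force(image: np.ndarray, h1: np.ndarray, h2: np.ndarray,
                   params: ModelParams) -> np.ndarray:
    f1, f2 = _lbf_pointwise_residuals(image, h1, h2, params.sigma)
    return params.scale2 * (-params.lambda1 * f1 + params.lambda2 * f2)


def lbf_energy(image: np.ndarray, phi: np.ndarray, h1: np.ndarray, h2: np.ndarray,
               params: ModelParams, data_only: bool = False) -> float:
    w1 = heaviside_eps(phi, params.epsilon)
    f1, f2 = _lbf_pointwise_residuals(image, h1, h2, params.sigma)
    s2 = params.scale2
    e = s2 * (params.lambda1 * (f1 * w1).sum() + params.lambda2 * (f2 * (1.0 - w1)).sum())
    if not data_only:
        e += s2 * params.nu * (dirac_eps(phi, params.epsilon) * gradient_magnitude(phi)).sum()
        e += params.mu * 0.5 * ((gradient_magnitude(phi) - 1.0) ** 2).sum()
    return float(e)


def lbf_evolve_step(image: np.ndarray, phi: np.ndarray, params: ModelParams) -> np.ndarray:
    """One explicit-Euler local-binary-fitting update."""
    h1, h2 = lbf_means(image, phi, params.sigma, params.epsilon)
    delta = dirac_eps(phi, params.epsilon)
    force = delta * (lbf_data_force(image, h1, h2, params)
                     + params.scale2 * params.nu * curvature(phi))
    force = force + params.mu * distance_regularization(phi)
    return phi + params.dt * force


# -------------------------------------------------------- global division

def intensity_split(image: np.ndarray, threshold: float) -> np.ndarray:
    """Indicator of the brighter sub-population, H(I - threshold).

    A hard indicator: it partitions pixels by intensity, not by contour
    membership, and is held frozen during each phi update, so the
    evolution force needs no smoothness in it. (A regularized split has
    heavy arctan tails that leak large cross-population residuals and
    destabilize the region.)
    """
    return (image > threshold).astype(np.float64)


def min_means(image: np.ndarray, phi: np.ndarray, epsilon: float):
    """Four-way intensity split around the side means.

    Inside the contour, pixels are partitioned by the indicator
    H(I - e1) into a brighter population with mean g11 and a darker one
    with mean g12; likewise outside around e2 giving g21, g22. An empty
    sub-population falls back to its parent mean so a constant region
    yields zero data force.
    """
    e1, e2 = cv_means(image, phi, epsilon)
    w_in = heaviside_eps(phi, epsilon)
    w_out = 1.0 - w_in
    hi1 = intensity_split(image, e1)
    hi2 = intensity_split(image, e2)

    def _split_mean(weights: np.ndarray, fallback: float) -> float:
        mass = weights.sum()
        if mass < MASS_FLOOR:
            return fallback
        return float((image * weights).sum() / mass)

    g11 = _split_mean(hi1 * w_in, e1)
    g12 = _split_mean((1.0 - hi1) * w_in, e1)
    g21 = _split_mean(hi2 * w_out, e2)
    g22 = _split_mean((1.0 - hi2) * w_out, e2)
    return g11, g12, g21, g22, e1, e2


def min_data_force(image: np.ndarray, g11: float, g12: float, g21: float, g22: float,
                   e1: float, e2: float, params: ModelParams) -> np.ndarray:
    hi1 = intensity_split(image, e1)
    hi2 = intensity_split(image, e2)
    inside = hi1 * (image - g11) ** 2 + (1.0 - hi1) * (image - g12) ** 2
    outside = hi2 * (image - g21) ** 2 + (1.0 - hi2) * (image - g22) ** 2
    return params.scale2 * (-params.lambda1 * inside + params.lambda2 * outside)


def min_energy(image: np.ndarray, phi: np.ndarray, g11: float, g12: float,
               g21: float, g22: float, e1: float, e2: float,
               params: ModelParams, data_only: bool = False) -> float:
    w_in = heaviside_eps(phi, params.epsilon)
    hi1 = intensity_split(image, e1)
    hi2 = intensity_split(image, e2)
    inside = hi1 * (image - g11) ** 2 + (1.0 - hi1) * (image - g12) ** 2
    outside = hi2 * (image - g21) ** 2 + (1.0 - hi2) * (image - g22) ** 2
    s2 = params.scale2
    e = s2 * (params.lambda1 * (inside * w_in).sum()
              + params.lambda2 * (outside * (1.0 - w_in)).sum())
    if not data_only:
        e += s2 * params.nu * (dirac_eps(phi, params.epsilon) * gradient_magnitude(phi)).sum()
        e += params.mu * 0.5 * ((gradient_magnitude(phi) - 1.0) ** 2).sum()
    return float(e)


def min_evolve_step(image: np.ndarray, phi: np.ndarray, params: ModelParams) -> np.ndarray:
    """One explicit-Euler global-division update."""
    g11, g12, g21, g22, e1, e2 = min_means(image, phi, params.epsilon)
    delta = dirac_eps(phi, params.epsilon)
    force = delta * (min_data_force(image, g11, g12, g21, g22, e1, e2, params)
                     + params.scale2 * params.nu * curvature(phi))
    force = force + params.mu * distance_regularization(phi)
    return phi + params.dt * force
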