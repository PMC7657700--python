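"""Adaptive-weight hybrid local/global region model.

The hybrid energy blends the local binary fitting (LBF) terms with the
global-division terms through a pixelwise adaptive weight F in [0, 1]
("global fitting energy support"):

    E = sum (1 - F) * [LBF data terms] + F * [global-division data terms]
        + nu * contour length + mu * distance-regularization penalty

The weight is driven by local image contrast: with I_T the local
intensity range in a T x T window (on the [0, 1] scale) and Avg(I_T) its
image mean (the global contrast level),

    F = clamp_[0,1]( p * (h1 + h2) / alpha * Avg(I_T) * (1 - I_T) )

so the global pathway gains weight on images with high overall contrast
variation (strong inhomogeneity or noise) but is switched off near
object boundaries, where I_T -> 1 and the local terms must dominate.
A perfectly flat image (Avg(I_T) = 0) degenerates to the pure local
model. Statistics (h1, h2, e, g) and F are frozen within each descent
step (alternating minimization), so the evolution force is exactly the
negative gradient of the discretized energy at fixed statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .core import (
    ImageGrid,
    curvature,
    default_init_region,
    dirac_eps,
    distance_regularization,
    gradient_magnitude,
    heaviside_eps,
    initialize_phi,
    phi_to_mask,
)
from .models import (
    FittingState,
    intensity_split,
    cv_energy,
    cv_evolve_step,
    lbf_data_force,
    lbf_energy,
    lbf_evolve_step,
    lbf_means,
    min_data_force,
    min_energy,
    min_evolve_step,
    min_means,
    _lbf_pointwise_residuals,
)
from .params import ModelParams

#: consecutive sub-tolerance iterations required to declare convergence
CONVERGENCE_RUN = 5


@dataclass
class ContrastMap:
    """Local contrast I_T, its image mean, and the adaptive weight."""

    i_t: np.ndarray
    avg_i_t: float
    weight: np.ndarray            # clamped to [0, 1]
    weight_preclamp: np.ndarray   # raw value before clamping


@dataclass
class SegmentationResult:
    """Final mask plus the per-iteration diagnostics of the evolution."""

    mask: np.ndarray
    phi_final: np.ndarray
    energy_trace: List[float]
    changed_fraction_trace: List[float]
    iterations_used: int
    converged: bool
    model: str = "hybrid"


def local_contrast(image: np.ndarray, window: int) -> np.ndarray:
    """Local intensity range (max - min) in a window x window
    neighbourhood, replicate-padded. Zero on flat regions, 1 across a
    full-range step edge."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(h, w):
        raise ValueError("window exceeds the image extent")
    mx = ndimage.maximum_filter(image, size=window, mode="nearest")
    mn = ndimage.minimum_filter(image, size=window, mode="nearest")
    return mx - mn


def gfes_weight(h1: np.ndarray, h2: np.ndarray, i_t: np.ndarray,
                p: float, alpha: float, clamp: bool = True) -> np.ndarray:
    """Adaptive global-energy weight field.

    ``p*(h1+h2)/alpha * Avg(I_T) * (1 - I_T)``, clamped to [0, 1] unless
    ``clamp`` is False. Returns an all-zero field when Avg(I_T) = 0
    (flat image: the global pathway is unnecessary).
    """
    avg = float(np.mean(i_t))
    raw = (p * (h1 + h2) / alpha) * avg * (1.0 - i_t)
    if not clamp:
        return raw
    return np.clip(raw, 0.0, 1.0)


def contrast_map(image: np.ndarray, phi: np.ndarray, params: ModelParams) -> ContrastMap:
    """Assemble the contrast/weight state for the current phi."""
    i_t = local_contrast(image, params.window)
    h1, h2 = lbf_means(image, phi, params.sigma, params.epsilon)
    pre = gfes_weight(h1, h2, i_t, params.p, params.alpha, clamp=False)
    return ContrastMap(i_t=i_t, avg_i_t=float(np.mean(i_t)),
                       weight=np.clip(pre, 0.0, 1.0), weight_preclamp=pre)


def hybrid_energy(image: np.ndarray, phi: np.ndarray, state: FittingState,
                  weight: np.ndarray, params: ModelParams,
                  data_only: bool = False) -> float:
    """Discretized hybrid energy at frozen statistics and weight."""
    w_in = heaviside_eps(phi, params.epsilon)
    f1, f2 = _lbf_pointwise_residuals(image, state.h1, state.h2, params.sigma)
    local = params.lambda1 * f1 * w_in + params.lambda2 * f2 * (1.0 - w_in)

    hi1 = intensity_split(image, state.e1)
    hi2 = intensity_split(image, state.e2)
    inside = hi1 * (image - state.g11) ** 2 + (1.0 - hi1) * (image - state.g12) ** 2
    outside = hi2 * (image - state.g21) ** 2 + (1.0 - hi2) * (image - state.g22) ** 2
    glob = params.lambda1 * inside * w_in + params.lambda2 * outside * (1.0 - w_in)

    s2 = params.scale2
    e = s2 * float(((1.0 - weight) * local + weight * glob).sum())
    if not data_only:
        gm = gradient_magnitude(phi)
        e += s2 * params.nu * float((dirac_eps(phi, params.epsilon) * gm).sum())
        e += params.mu * 0.5 * float(((gm - 1.0) ** 2).sum())
    return float(e)


def _hybrid_state(image: np.ndarray, phi: np.ndarray, params: ModelParams) -> FittingState:
    h1, h2 = lbf_means(image, phi, params.sigma, params.epsilon)
    g11, g12, g21, g22, e1, e2 = min_means(image, phi, params.epsilon)
    return FittingState(e1=e1, e2=e2, h1=h1, h2=h2,
                        g11=g11, g12=g12, g21=g21, g22=g22)


def hybrid_force(image: np.ndarray, phi: np.ndarray, state: FittingState,
                 weight: np.ndarray, params: ModelParams) -> np.ndarray:
    """Descent force of the hybrid energy at frozen statistics."""
    data = ((1.0 - weight) * lbf_data_force(image, state.h1, state.h2, params)
            + weight * min_data_force(image, state.g11, state.g12,
                                      state.g21, state.g22,
                                      state.e1, state.e2, params))
    delta = dirac_eps(phi, params.epsilon)
    force = delta * (data + params.scale2 * params.nu * curvature(phi))
    return force + params.mu * distance_regularization(phi)


def hybrid_evolve_step(image: np.ndarray, phi: np.ndarray, params: ModelParams,
                       i_t: Optional[np.ndarray] = None,
                       weight_override: Optional[np.ndarray] = None,
                       ) -> Tuple[np.ndarray, float]:
    """One alternating-minimization step of the hybrid model.

    Refits h1/h2, e/g statistics and the adaptive weight for the current
    phi, then applies one explicit-Euler update. Returns the new field
    and the (pre-step) energy. ``weight_override`` substitutes a fixed
    weight field (0 reproduces the pure local model, 1 the pure global
    one); ``i_t`` may carry the precomputed local-contrast field, which
    depends only on the image.
    """
    state = _hybrid_state(image, phi, params)
    if weight_override is not None:
        weight = np.broadcast_to(np.asarray(weight_override, dtype=np.float64),
                                 phi.shape)
    else:
        if i_t is None:
            i_t = local_contrast(image, params.window)
        weight = gfes_weight(state.h1, state.h2, i_t, params.p, params.alpha)
    energy = hybrid_energy(image, phi, state, weight, params)
    new_phi = phi + params.dt * hybrid_force(image, phi, state, weight, params)
    return new_phi, energy


# ------------------------------------------------------------ driver

_STEPPERS = {
    "cv": cv_evolve_step,
    "lbf": lbf_evolve_step,
    "min": min_evolve_step,
}


def _model_energy(model: str, image: np.ndarray, phi: np.ndarray,
                  params: ModelParams) -> float:
    from .models import cv_means  # local import keeps module load light
    if model == "cv":
        e1, e2 = cv_means(image, phi, params.epsilon)
        return cv_energy(image, phi, e1, e2, params)
    if model == "lbf":
        h1, h2 = lbf_means(image, phi, params.sigma, params.epsilon)
        return lbf_energy(image, phi, h1, h2, params)
    if model == "min":
        g11, g12, g21, g22, e1, e2 = min_means(image, phi, params.epsilon)
        return min_energy(image, phi, g11, g12, g21, g22, e1, e2, params)
    raise ValueError(f"unknown model {model!r}")


def segment(image: Union[np.ndarray, ImageGrid], params: Optional[ModelParams] = None,
            init_region: Optional[np.ndarray] = None,
            model: str = "hybrid") -> SegmentationResult:
    """Segment a [0, 1] grayscale image with one of cv/lbf/min/hybrid.

    Evolution starts from a binary-step level-set function over
    ``init_region`` (default: centered rectangle covering 40% of each
    dimension) and stops when the relative changed-pixel fraction of the
    binary mask stays below ``params.tol`` for 5 consecutive iterations,
    or at ``params.max_iter`` (then ``converged`` is False).
    """
    if isinstance(image, ImageGrid):
        image = image.values
    image = np.asarray(image, dtype=np.float64)
    if params is None:
        from .params import default_params
        params = default_params(model)
    if init_region is None:
        init_region = default_init_region(image.shape)
    phi = initialize_phi(image.shape, init_region, params.rho)

    i_t = local_contrast(image, params.window) if model == "hybrid" else None
    mask = phi_to_mask(phi)
    n_pix = mask.size
    energy_trace: List[float] = []
    changed_trace: List[float] = []
    quiet = 0
    converged = False
    iterations = 0

    for _ in range(params.max_iter):
        if model == "hybrid":
            phi, energy = hybrid_evolve_step(image, phi, params, i_t=i_t)
        else:
            energy = _model_energy(model, image, phi, params)
            phi = _STEPPERS[model](image, phi, params)
        iterations += 1
        new_mask = phi_to_mask(phi)
        changed = float(np.count_nonzero(new_mask ^ mask)) / n_pix
        mask = new_mask
        energy_trace.append(float(energy))
        changed_trace.append(changed)
        quiet = quiet + 1 if changed < params.tol else 0
        if quiet >= CONVERGENCE_RUN:
            converged = True
            break

    return SegmentationResult(mask=mask, phi_final=phi, energy_trace=energy_trace,
                              changed_fraction_trace=changed_trace,
                              iterations_used=iterations, converged=converged,
                              model=model)
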