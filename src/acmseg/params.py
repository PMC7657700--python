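"""Model parameters shared by all region-based contour models.

All intensities inside the library live on the normalized [0, 1] scale.
``lambda1``, ``lambda2`` and ``nu`` are expressed on that scale; the
evolution equations internally multiply the data and length terms by
``intensity_scale**2`` so that the classical 8-bit parameter values
(time step 0.1, nu = 0.01 on the unit scale, i.e. 0.01*255*255 in 8-bit
units) reproduce the usual convergence behaviour of these models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass
class ModelParams:
    """Tunable parameters of the level-set evolution.

    Attributes
    ----------
    lambda1, lambda2:
        Weights of the inside/outside data-fitting terms.
    mu:
        Weight of the distance-regularization penalty
        ``mu * 0.5 * (|grad phi| - 1)^2`` (keeps phi close to a signed
        distance function; removes the need for reinitialization).
    nu:
        Length-term weight on the normalized intensity scale (the 8-bit
        convention value divided by 255**2).
    epsilon:
        Width of the regularized Heaviside/Dirac pair.
    dt:
        Explicit-Euler time step.
    sigma:
        Standard deviation (pixels) of the Gaussian window used by the
        local fitting terms.
    rho:
        Magnitude of the piecewise-constant initial level-set function.
    p:
        Scale of the adaptive global-weight function, in [0, 1].
    alpha:
        Denominator scale of the adaptive global-weight function.
    window:
        Odd side length T (pixels) of the local-contrast window.
    max_iter, tol:
        Iteration cap and convergence tolerance (relative changed-pixel
        fraction of the binary mask, sustained over 5 iterations).
    intensity_scale:
        Native intensity range of the source data (255 for 8-bit). Data
        and length terms are scaled by its square.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    mu: float = 1.0
    nu: float = 0.01
    epsilon: float = 1.0
    dt: float = 0.1
    sigma: float = 5.0
    rho: float = 2.0
    p: float = 0.5
    alpha: float = 0.3
    window: int = 21
    max_iter: int = 3000
    tol: float = 2e-5
    intensity_scale: float = 255.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.mu < 0 or self.nu < 0:
            raise ValueError("mu and nu must be non-negative")

    @property
    def scale2(self) -> float:
        """Squared native intensity range; multiplies data/length terms."""
        return float(self.intensity_scale) ** 2

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


#: Per-model default parameters. Values follow the usual published
#: settings for each model: the hybrid model uses sigma=5, dt=0.1,
#: mu=1, nu=0.01 (unit scale); the Chan-Vese model carries no distance
#: regularization and a small length weight; LBF and the global-division
#: model use sigma=3 with nu=0.001 (unit scale).
MODEL_DEFAULTS = {
    "cv": dict(sigma=3.0, mu=0.0, nu=0.1 / 255.0**2),
    "lbf": dict(sigma=3.0, mu=1.0, nu=0.001),
    "min": dict(sigma=3.0, mu=1.0, nu=0.001),
    "hybrid": dict(sigma=5.0, mu=1.0, nu=0.01),
}


def default_params(model: str = "hybrid", **overrides) -> ModelParams:
    """Default :class:`ModelParams` for one of cv/lbf/min/hybrid."""
    if model not in MODEL_DEFAULTS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODEL_DEFAULTS)}")
    kwargs = dict(MODEL_DEFAULTS[model])
    kwargs.update(overrides)
    return ModelParams(**kwargs)
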