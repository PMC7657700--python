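"""Deterministic synthetic phantoms with exact ground-truth masks.

Each phantom is a two-region (or layered) shape rendered at base
foreground/background intensities, optionally degraded by

* a multiplicative bias field (linear ramp, Gaussian ramp, or sinusoid)
  normalized to unit mean — the standard model of smooth shading in
  MRI/X-ray acquisition. At amplitude ``a`` the field spans a
  max/min ratio of 1/(1-a), so a = 2/3 produces 3:1 shading;
* additive Gaussian noise or salt impulse noise,

followed by clipping to [0, 1]. Generation is fully seeded and
bit-reproducible. The ``standard_suite`` is the fixed phantom set used
throughout the tests: it covers a clean homogeneous disk, a strongly
biased disk, a two-level salt-noised blob, a two-level object, a
linear-ramp rectangle, a two-blob scene, a ring, and a step edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .core import ImageGrid


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic test image."""

    shape: str = "disk"                 # disk | rectangle | two_blob | ring | multilevel | step
    size: Tuple[int, int] = (128, 128)
    fg: float = 0.7
    bg: float = 0.25
    bias: str = "none"                  # none | linear | gaussian | sinusoid
    bias_amplitude: float = 0.0         # max/min bias ratio = 1/(1-a)
    bias_center: Tuple[float, float] = (0.25, 0.25)   # fractional, for gaussian
    bias_width: float = 0.6             # fractional of the image diagonal
    bias_center2: Optional[Tuple[float, float]] = None  # optional 2nd Gaussian lobe
    bias_width2: float = 0.1
    noise: str = "none"                 # none | gaussian | salt
    noise_level: float = 0.0            # std for gaussian; flip fraction for salt
    inner_fg: Optional[float] = None    # second level for the multilevel shape
    radius_frac: float = 0.28           # disk radius as a fraction of min(h, w)
    inner_radius_frac: float = 0.12     # inner-level radius (multilevel shape)
    bias_norm: str = "max"              # "max": field in [1-a, 1]; "mean": unit mean
    edge_blur: float = 0.0              # optional 1-px-scale Gaussian edge softening
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fg == self.bg:
            raise ValueError("foreground and background intensities must differ")
        if not (0.0 <= self.bias_amplitude < 1.0):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if min(self.size) < 8:
            raise ValueError("phantom too small")


def _coords(size):
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    return yy.astype(np.float64), xx.astype(np.float64)


def _disk(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _base_shape(spec: PhantomSpec):
    """Return (clean image, truth mask) before bias/noise."""
    h, w = spec.size
    yy, xx = _coords(spec.size)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = spec.radius_frac * min(h, w)
    img = np.full(spec.size, spec.bg, dtype=np.float64)

    if spec.shape == "disk":
        truth = _disk(yy, xx, cy, cx, r)
        img[truth] = spec.fg
    elif spec.shape == "rectangle":
        truth = np.zeros(spec.size, dtype=bool)
        truth[int(0.25 * h): int(0.75 * h), int(0.3 * w): int(0.7 * w)] = True
        img[truth] = spec.fg
    elif spec.shape == "two_blob":
        m1 = _disk(yy, xx, 0.35 * h, 0.32 * w, 0.16 * min(h, w))
        m2 = _disk(yy, xx, 0.65 * h, 0.68 * w, 0.20 * min(h, w))
        truth = m1 | m2
        img[truth] = spec.fg
    elif spec.shape == "ring":
        outer = _disk(yy, xx, cy, cx, 0.34 * min(h, w))
        inner = _disk(yy, xx, cy, cx, 0.18 * min(h, w))
        truth = outer & ~inner
        img[truth] = spec.fg
    elif spec.shape == "multilevel":
        truth = _disk(yy, xx, cy, cx, r)
        inner = _disk(yy, xx, cy - 0.1 * h, cx, spec.inner_radius_frac * min(h, w))
        img[truth] = spec.fg
        img[truth & inner] = spec.inner_fg if spec.inner_fg is not None else min(
            1.0, spec.fg + 0.25)
    elif spec.shape == "step":
        truth = xx >= w / 2.0
        img[truth] = spec.fg
    else:
        raise ValueError(f"unknown phantom shape {spec.shape!r}")

    if not truth.any() or truth.all():
        raise ValueError("degenerate phantom: empty or full truth mask")
    return img, truth


def bias_field(spec: PhantomSpec) -> np.ndarray:
    """Strictly positive multiplicative shading field.

    With ``bias_norm="max"`` the field spans [1-a, 1] (never brightens,
    so base intensities are never clipped); with ``bias_norm="mean"`` it
    is rescaled to unit mean (brightness-preserving, the convention of
    bias-correction methods), which suits amplitude sweeps that must not
    confound inhomogeneity with overall darkening.
    """
    h, w = spec.size
    yy, xx = _coords(spec.size)
    a = spec.bias_amplitude
    if spec.bias == "none" or a == 0.0:
        return np.ones(spec.size)
    if spec.bias == "linear":
        g = xx / max(w - 1, 1)
    elif spec.bias == "gaussian":
        cy, cx = spec.bias_center[0] * (h - 1), spec.bias_center[1] * (w - 1)
        width = spec.bias_width * np.hypot(h, w)
        g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * width ** 2))
        if spec.bias_center2 is not None:
            cy2, cx2 = spec.bias_center2[0] * (h - 1), spec.bias_center2[1] * (w - 1)
            width2 = spec.bias_width2 * np.hypot(h, w)
            g2 = np.exp(-((yy - cy2) ** 2 + (xx - cx2) ** 2) / (2.0 * width2 ** 2))
            g = np.clip(g + g2, 0.0, 1.0)
        else:
            g = (g - g.min()) / (g.max() - g.min())
    elif spec.bias == "sinusoid":
        g = 0.5 * (1.0 + np.sin(2.0 * np.pi * xx / w) * np.cos(2.0 * np.pi * yy / h))
    else:
        raise ValueError(f"unknown bias kind {spec.bias!r}")
    raw = (1.0 - a) + a * g            # in [1-a, 1]; ratio 1/(1-a)
    if spec.bias_norm == "mean":
        return raw / raw.mean()
    if spec.bias_norm != "max":
        raise ValueError(f"unknown bias_norm {spec.bias_norm!r}")
    return raw


def generate(spec: PhantomSpec) -> Tuple[ImageGrid, np.ndarray]:
    """Render the phantom: clip01(shape * bias + noise), exact truth mask."""
    img, truth = _base_shape(spec)
    img = img * bias_field(spec)
    if spec.edge_blur > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, spec.edge_blur, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    if spec.noise == "gaussian" and spec.noise_level > 0:
        img = img + rng.normal(0.0, spec.noise_level, size=spec.size)
    elif spec.noise == "salt" and spec.noise_level > 0:
        flips = rng.random(spec.size) < spec.noise_level
        img = np.where(flips, rng.random(spec.size), img)
    elif spec.noise not in ("none", "gaussian", "salt"):
        raise ValueError(f"unknown noise kind {spec.noise!r}")
    img = np.clip(img, 0.0, 1.0)
    return ImageGrid(img), truth


#: the bias phantom used by the inhomogeneity comparisons: a disk whose
#: illumination peaks at its center and falls off ~3:1 toward the rim
#: (multiplicative Gaussian ramp), plus a dim second shading lobe in the
#: background whose brightened pixels overlap the darkened object rim.
#: Global thresholds (Chan-Vese) misclassify both the rim and the lobe;
#: windowed local statistics recover the true boundary.
BIAS_DISK = PhantomSpec(shape="disk", size=(128, 128), fg=0.5, bg=0.21,
                        radius_frac=0.35, bias="gaussian", bias_amplitude=0.70,
                        bias_center=(0.5, 0.5), bias_width=0.0994,
                        bias_center2=(100 / 127, 100 / 127), bias_width2=0.0884,
                        seed=11)


#: two-level object under heavy salt noise: the dim shell sits below a
#: global two-mean threshold (so a single inside-mean model drops it),
#: while the four-way intensity division absorbs both object levels and
#: the impulse noise.
SALT_BLOB = PhantomSpec(shape="multilevel", size=(128, 128), fg=0.35,
                        inner_fg=0.9, bg=0.15, radius_frac=0.28,
                        inner_radius_frac=0.20, noise="salt",
                        noise_level=0.10, seed=3)


#: brightness-preserving family for inhomogeneity sweeps: same disk and
#: base intensities at every amplitude, wide unit-mean Gaussian shading,
#: so only the inhomogeneity level varies along the sweep.
SWEEP_DISK = PhantomSpec(shape="disk", size=(128, 128), fg=0.5, bg=0.21,
                         radius_frac=0.32, bias="gaussian", bias_norm="mean",
                         bias_center=(0.25, 0.25), bias_width=0.45, seed=11)


def bias_sweep_family(amplitudes) -> List[Tuple[float, ImageGrid, np.ndarray]]:
    """Phantoms differing only in bias-field amplitude."""
    from dataclasses import replace
    out = []
    for a in amplitudes:
        image, truth = generate(replace(SWEEP_DISK, bias_amplitude=float(a)))
        out.append((float(a), image, truth))
    return out


def standard_suite() -> List[Tuple[str, ImageGrid, np.ndarray]]:
    """Fixed, versioned phantom set used by the tests and benchmarks."""
    specs = [
        ("disk_clean", PhantomSpec(shape="disk", fg=0.7, bg=0.25, seed=1)),
        ("disk_bias", BIAS_DISK),
        ("blob_salt", SALT_BLOB),
        ("multilevel", PhantomSpec(shape="multilevel", fg=0.55, bg=0.2,
                                   inner_fg=0.8, seed=4)),
        ("rect_ramp", PhantomSpec(shape="rectangle", fg=0.6, bg=0.25,
                                  bias="linear", bias_amplitude=0.5, seed=5)),
        ("two_blob", PhantomSpec(shape="two_blob", fg=0.7, bg=0.25, seed=6)),
        ("ring", PhantomSpec(shape="ring", fg=0.7, bg=0.25, seed=7)),
        ("step_edge", PhantomSpec(shape="step", fg=0.7, bg=0.3, seed=8)),
    ]
    out = []
    for name, spec in specs:
        image, truth = generate(spec)
        out.append((name, image, truth))
    return out
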