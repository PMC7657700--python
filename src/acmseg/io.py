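"""Image and mask I/O plus YAML run configuration.

Images are normalized on load to the [0, 1] working scale; the source
bit depth is recorded as ``intensity_levels`` so the evolution equations
can restore the native data-term magnitudes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import yaml

from .core import ImageGrid
from .params import MODEL_DEFAULTS, ModelParams, default_params

#: ITU-R BT.601 luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path) -> ImageGrid:
    """Read a PNG/TIFF/PGM image as a normalized grayscale ImageGrid."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise IOError(f"empty image file: {path}")
    if arr.ndim == 3:
        gray = arr[..., :3].astype(np.float64) @ _LUMA  # drop alpha, take luminance
    else:
        gray = arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        levels = int(np.iinfo(arr.dtype).max)
        gray = gray / levels
    else:
        levels = 255
        mx = gray.max()
        if mx > 1.0:
            gray = gray / mx
    return ImageGrid(np.clip(gray, 0.0, 1.0), intensity_levels=levels)


def load_mask(path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel counts as inside)."""
    grid = load_image(path)
    return grid.values > 0.5


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as a 0/255 single-channel PNG."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def save_image(image: ImageGrid, path) -> None:
    """Write a [0, 1] image as 8-bit grayscale PNG."""
    vals = np.clip(np.asarray(image.values if isinstance(image, ImageGrid) else image),
                   0.0, 1.0)
    iio.imwrite(Path(path), np.round(vals * 255).astype(np.uint8))


def save_trace(result, path) -> None:
    """Write the per-iteration diagnostics as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "energy", "changed_pixel_fraction"])
        for i, (e, c) in enumerate(zip(result.energy_trace,
                                       result.changed_fraction_trace), start=1):
            writer.writerow([i, repr(e), repr(c)])


# ------------------------------------------------------------- run config

_PARAM_KEYS = {f.name for f in dc_fields(ModelParams)}
_CONFIG_KEYS = _PARAM_KEYS | {"model", "input", "output", "init", "seed", "verbose"}


@dataclass
class RunConfig:
    """One segmentation run: model choice, parameters, paths."""

    model: str = "hybrid"
    params: ModelParams = None  # type: ignore[assignment]
    input: Optional[str] = None
    output: Optional[str] = None
    init: Optional[str] = None
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODEL_DEFAULTS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.params is None:
            self.params = default_params(self.model)


def parse_config(source) -> RunConfig:
    """Parse a YAML mapping (path or dict) into a RunConfig.

    Unknown keys are rejected. The ``nu`` key is given in the customary
    8-bit printed convention (e.g. 0.01*255*255 = 650.25) and is
    internally divided by 255**2 onto the normalized scale, so published
    parameter tables can be entered verbatim.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    model = data.get("model", "hybrid")
    param_kwargs = {k: v for k, v in data.items() if k in _PARAM_KEYS}
    if "nu" in param_kwargs:
        param_kwargs["nu"] = float(param_kwargs["nu"]) / 255.0**2
    params = default_params(model, **param_kwargs)
    return RunConfig(model=model, params=params,
                     input=data.get("input"), output=data.get("output"),
                     init=data.get("init"), seed=int(data.get("seed", 0)),
                     verbose=bool(data.get("verbose", False)))


def serialize_config(cfg: RunConfig) -> dict:
    """Round-trippable dict form of a RunConfig (nu back in 8-bit units)."""
    out = {"model": cfg.model, "seed": cfg.seed, "verbose": cfg.verbose}
    for key in ("input", "output", "init"):
        val = getattr(cfg, key)
        if val is not None:
            out[key] = val
    for f in dc_fields(ModelParams):
        val = getattr(cfg.params, f.name)
        out[f.name] = val * 255.0**2 if f.name == "nu" else val
    return out
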