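"""Segmentation scoring against ground truth.

The headline metric is pixel accuracy (TP+TN)/(TP+TN+FP+FN) over the
full frame; Dice and Jaccard are provided as overlap-focused
auxiliaries (frame accuracy is background-inflated on small objects).
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import ImageGrid
from .hybrid import SegmentationResult, segment
from .params import ModelParams, default_params


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total <= 0:
        raise ValueError("empty masks: accuracy undefined")
    return (counts.tp + counts.tn) / counts.total


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    c = confusion(pred, truth)
    denom = c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    c = confusion(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def mask_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return accuracy(confusion(pred, truth))


def compare_models(image, truth: np.ndarray,
                   models: Sequence[str] = ("cv", "lbf", "min", "hybrid"),
                   params: Optional[Dict[str, ModelParams]] = None,
                   init_region: Optional[np.ndarray] = None) -> List[dict]:
    """Run several models on identical input and initialization.

    Returns one row per requested model with accuracy, Dice, Jaccard,
    iteration count, final energy and wall-clock time (informational).
    Per-model failures are captured in the row, not raised.
    """
    rows: List[dict] = []
    for name in models:
        row: dict = {"model": name}
        mp = (params or {}).get(name) or default_params(name)
        t0 = time.perf_counter()
        try:
            result = segment(image, mp, init_region=init_region, model=name)
        except Exception as exc:  # noqa: BLE001 - reported per row
            row.update(error=str(exc), accuracy=np.nan)
            rows.append(row)
            continue
        row.update(
            accuracy=mask_accuracy(result.mask, truth),
            dice=dice(result.mask, truth),
            jaccard=jaccard(result.mask, truth),
            iterations=result.iterations_used,
            converged=result.converged,
            final_energy=result.energy_trace[-1] if result.energy_trace else np.nan,
            cpu_time=time.perf_counter() - t0,
        )
        rows.append(row)
    return rows
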