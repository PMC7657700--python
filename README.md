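# acmseg

Region-based active-contour segmentation of 2-D grayscale images with
intensity inhomogeneity — the smooth shading (bias fields) typical of
MRI, X-ray/mammography and dermoscopy that makes one tissue class span a
wide intensity range and defeats global thresholds.

The package implements four level-set models in one framework:

* **Chan–Vese** (`cv`): each side of the contour approximated by a
  single constant e₁/e₂;
* **Local binary fitting** (`lbf`): Gaussian-windowed local mean fields
  h₁(x)/h₂(x), robust to smooth shading but initialization-sensitive;
* **Global division** (`min`): each side split at its own mean into
  brighter/darker sub-populations (g₁₁, g₁₂ / g₂₁, g₂₂), robust to
  impulse noise and multi-level objects;
* **Hybrid** (`hybrid`): a pixelwise blend of the local and global
  energies, gated by an adaptive weight driven by local image contrast,

      F = clamp₀¹[ p(h₁+h₂)/α · Avg(I_T) · (1 − I_T) ],

  where I_T is the intensity range in a T×T window. The weight grows
  with the image's inhomogeneity level and vanishes at boundaries
  (I_T → 1), so the local terms place the contour while the global terms
  stabilize the smooth interior.

All models evolve φ by explicit Euler on
`δ_ε(φ)(data + ν·κ) + μ(∇²φ − κ)` with the regularized Heaviside/Dirac
pair `H_ε(φ) = ½(1 + (2/π)arctan(φ/ε))`, a length term, and the
distance-regularization penalty `∫½(|∇φ|−1)²` that removes
reinitialization. A seeded phantom generator (shapes × multiplicative
shading × noise, with exact ground truth) and an evaluation module
(confusion counts, accuracy = (TP+TN)/(TP+TN+FP+FN), Dice, Jaccard)
complete the toolkit. See `docs/methods.md` for the numerical details.

## Worked example

Compare all four models on the built-in bias-field phantom — a disk
whose illumination falls ~3:1 from center to rim over a background with
a second dim shading lobe, so the darkened rim overlaps the brightened
background:

```python
from acmseg import compare_models
from acmseg.phantoms import BIAS_DISK, generate

image, truth = generate(BIAS_DISK)
rows = compare_models(image, truth, models=("cv", "lbf", "min", "hybrid"))
for r in rows:
    print(f"{r['model']:8s} {r['accuracy']:8.4f} {r['dice']:6.4f} "
          f"{r['iterations']:6d} {str(r['converged']):>9s}")
```

prints

```
cv         0.8855 0.8303     28      True
lbf        0.3061 0.3074   1422      True
min        0.6823 0.4894     28      True
hybrid     0.9996 0.9994   1807      True
```

The two-mean model thresholds globally and mislabels the dim rim and the
bright background lobe (acc 0.89); pure local fitting wanders from the
default centered initialization on this image (0.31); the global
division mislabels the shaded rim (0.68); the hybrid recovers the disk
almost exactly (0.9996 accuracy, Dice 0.999).

Command-line equivalents:

```
acmseg phantom --spec suite --out phantoms/
acmseg run --model hybrid --input phantoms/disk_bias.png --out mask.png --verbose
acmseg eval --pred mask.png --truth phantoms/disk_bias_mask.png
acmseg bench --models cv,lbf,min,hybrid --out bench.csv
```

`acmseg run` accepts a YAML config (`--config`) whose `nu` is given in
the customary 8-bit printed convention (e.g. `nu: 650.25` for
0.01·255·255); unknown keys are rejected.

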