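# igwoderm

Dermoscopic melanoma analysis built around an improved grey wolf optimizer
(IGWO): entropy-based lesion segmentation, DullRazor-style preprocessing, a
compact CNN classifier with an imbalance-aware training protocol, and
IGWO-driven hyperparameter search — all runnable end to end on seeded
synthetic dermoscopy-like images, with no external data.

## Who this is for

Researchers and students studying swarm-intelligence metaheuristics in
medical image analysis: how a grey wolf optimizer variant behaves as the
search engine behind multilevel thresholding and CNN hyperparameter tuning,
and how a melanoma classification pipeline should be evaluated under strong
class imbalance (patient-grouped splits, balanced accuracy, G-mean, MCC,
Cohen's κ).

## The methods

**Grey wolf optimizer.** A pack of N agents keeps its three best solutions
(α, β, δ). Each iteration every agent x moves to the mean of three
elite-guided pulls,

    D_e = |C·x_e − x|,   x'_e = x_e − A·D_e,   x(t+1) = (x'_α + x'_β + x'_δ)/3,

with A = 2a·r₁ − a, C = 2·r₂, r₁, r₂ ~ U[0,1) drawn per agent per dimension
and shared by the three pulls, and a = 2(1 − t/T) decaying linearly.

**Improved GWO.** Each iteration the worst ⌊rN⌋ omega wolves (default
r = 0.3) are eliminated. Each is regenerated as an exact elite copy with
probability p = 0.7 (elite drawn with rank weights 3:2:1), otherwise as a
Gaussian resample x_α + σ·g with σ = 1/(t+1). Per-agent greedy memory keeps
the better of old and new position after every move.

**Kapur segmentation.** Thresholds TH = [th₁ … th_{m−1}] maximize the sum of
within-class Shannon entropies of the intensity histogram; the optimizer
searches the integer thresholds (25 seeded repeats, per-position mean).
The binary mask is refined by hole filling, opening, closing (3×3 element)
and largest-component selection.

**Classifier.** A numpy CNN — three 3×3 conv blocks (same padding, ReLU,
2×2 max-pool) with filters (f₁, f₂, f₃), dense-128, dropout d, softmax —
trained with class-weighted cross-entropy (w_c = n/(2n_c)), RMSprop
(lr 10⁻³, ρ 0.9, ε 10⁻⁷), early stopping on validation loss. The
hyperparameters (f₁, f₂, f₃) ∈ [16, 256]³ and d ∈ [0.2, 0.8] are tuned by
IGWO against validation loss.

## Worked example

```python
import numpy as np
from dataclasses import replace
from igwoderm import (MALIGNANT_PARAMS, SegmentationConfig, make_lesion_image,
                      segment_lesion, run_pipeline)
from igwoderm.pipeline import resolve_config, iou
from igwoderm.preprocess import DermoscopyPreprocessor
from igwoderm.synthetic import add_hair
from igwoderm.segmentation import find_thresholds, gray_histogram, kapur_objective

# one hairy malignant-like lesion through preprocessing and segmentation
rng = np.random.default_rng(7)
img, truth = make_lesion_image(replace(MALIGNANT_PARAMS, size=96), rng)
hairy, _ = add_hair(img, count=4, width=2, rng=rng)
clean = DermoscopyPreprocessor().transform_one(hairy)
th = find_thresholds(clean, m=2, seed=7, repeats=5)
J = kapur_objective(gray_histogram(clean), th)
mask = segment_lesion(clean, SegmentationConfig(seed=7))
print(f"threshold: {th.th[0]}  entropy J: {J:.4f}  IoU vs truth: {iou(mask, truth):.3f}")

# the full desk-scale pipeline: synth -> split -> train -> evaluate
cfg = resolve_config({"seed": 0, "synth": {"n_images": 250, "n_patients": 50},
                      "segment": {"enabled": False}, "train": {"epochs": 10}})
m = run_pipeline(cfg)["metrics"]
print("test accuracy: %.3f  AUC: %.3f  MCC: %.3f"
      % (m["accuracy"], m["auc"], m["mcc"]))
```

prints

```
threshold: 194  entropy J: 6.2255  IoU vs truth: 0.932
test accuracy: 1.000  AUC: 1.000  MCC: 1.000
```

The single-image lines say the entropy criterion put the lesion/skin
threshold at grey level 194 (total within-class entropy 6.23) and the final
mask overlaps the generator's ground truth at IoU 0.93. The pipeline lines
are held-out test metrics of the CNN on 250 synthetic images with 10%
malignant prevalence and patient-grouped 70/15/15 splits — the synthetic
classes are built to be separable, so a correctly wired pipeline should
saturate them.

There is also a CLI (`igwoderm synth | preprocess | segment | train | hpo |
evaluate | run`); `igwoderm run --out-dir runs/demo` executes the whole
desk-profile pipeline with artifacts and a reproducibility manifest.

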