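# emdimage

Quasi-2D empirical mode decomposition (EMD) for feature enhancement of
RGB medical images, with the surrounding pipeline: dataset preparation
for directory-per-class image collections, ground-truth-bearing
synthetic fixtures, hard-label multi-class evaluation metrics, and a
small training harness with Grad-CAM support.

## The problem and the method

Classifiers for endoscopic (and other color medical) imagery must pick
up subtle local texture under large, slowly varying illumination
bias. EMD addresses this adaptively, with no preset basis: a signal
x(t) is decomposed by iterative *sifting* into intrinsic mode functions
(IMFs) plus a residue,

    x(t) = Σᵢ cᵢ(t) + rₙ(t),

where each IMF cᵢ has extrema and zero-crossing counts differing by at
most one and a (near-)zero mean envelope, and c₁ is the fastest
oscillation. The quasi-2D variant flattens an H × W × 3 image row-major
(channel fastest), decomposes the 1D scan, and reshapes each IMF back
to image shape. The last IMFs collect low-frequency structure along the
scan — background and illumination drift — so subtracting the last k
IMF images from the original,

    enhanced = image − Σ (last k IMF images),

suppresses the background while preserving local texture and contrast.
The named configurations NO, IM-IMF-1, IM-IMF-1-2, IM-IMF-1-2-3
subtract k = 0, 1, 2, 3 IMFs. The package implements the decomposition
from scratch (extrema detection, spline envelopes with mirrored ends,
Cauchy + IMF-test sift stopping), exposes it functionally and as a
scikit-learn transformer (`EMDEnhancer`), and ships the evaluation
stack used to judge enhanced-vs-raw pipelines: one-vs-rest
precision/recall/F1, hard-label one-hot ROC with AUC = (1 + TPR −
FPR)/2, cross-entropy, and percentile-bootstrap confidence intervals.
See `docs/methods.md` for assumptions, tolerances, and limitations.

## Worked example

Decompose a synthetic 32 × 32 image with a known slow scan-order
background (amplitude 50), fast texture, a Gaussian "lesion" blob, and
noise; then subtract slow IMFs and watch the background energy
(squared projection onto the normalized ground-truth background) drop:

```python
import numpy as np
from emdimage import (SyntheticImageSpec, LesionSpec, make_synthetic_image,
                      decompose_image, enhance, EnhancementConfig)

spec = SyntheticImageSpec(height=32, width=32, background_amp=50.0,
                          texture_amp=10.0, texture_period=12.0,
                          lesion=LesionSpec(center=(16, 16), radius=5.0, amplitude=40.0),
                          noise_sd=2.0, seed=3)
image, truth = make_synthetic_image(spec)

dec = decompose_image(image)
print(f"IMFs extracted: {dec.n}, sift counts: {dec.sift_counts}")

recon_err = np.sqrt(np.mean((dec.reconstruct() - image) ** 2)) / np.sqrt(np.mean(image**2))
print(f"reconstruction error (relative RMS): {recon_err:.2e}")

bg = truth["background"].ravel() - truth["background"].mean()
bg /= np.linalg.norm(bg)
for k in (0, 1, 2):
    cfg = EnhancementConfig.from_name(["NO", "IM-IMF-1", "IM-IMF-1-2"][k])
    out = enhance(image, dec, cfg)
    energy = np.dot(out.ravel(), bg) ** 2
    print(f"{cfg.name:>10}: background energy {energy:12.1f}")
```

Output:

```
IMFs extracted: 6, sift counts: [59, 10, 83, 30, 12, 1]
reconstruction error (relative RMS): 1.22e-16
        NO: background energy    3829496.7
  IM-IMF-1: background energy        274.5
IM-IMF-1-2: background energy         87.4
```

Six IMFs cover the scan from sample-scale noise (c₁) down to the slow
background (c₆); the reconstruction identity holds to rounding. NO
leaves the image untouched, and already IM-IMF-1 removes > 99.99% of
the background-correlated energy here because the background landed in
the last IMF, while the texture and lesion stay in the earlier IMFs.

## Command line

```sh
emdimage fixtures make-dataset data/ --classes 8 --per-class 5 --seed 0
emdimage decompose data/class_0/img_0000.png --out imfs/
emdimage enhance data/ enhanced/ --config IM-IMF-1-2 --export clip_8bit
emdimage split RAW_KVASIR/ --seed 0 --out split.csv     # 3360/1440/3200 at 8x1000
emdimage prepare RAW_KVASIR/ prepared/ --crop --resize 64
emdimage evaluate --truth truth.csv --pred pred.csv --report report.json
emdimage run-experiment data/ --enhancement IM-IMF-1 --backend softmax --epochs 15
```

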