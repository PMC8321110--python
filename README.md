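# mwi3d — synthetic microwave breast imaging with learned enhancement

Quantitative microwave breast imaging reconstructs the complex relative
permittivity ε(r) = ε′ − jε″ of breast tissue from multi-static scattered
microwave fields, exploiting the large dielectric contrast between tumors
(ε ≈ 56.3 − 30j), fibroglandular tissue (20 − 21.6j) and fat (3 − 0.6j).
The reconstructions produced by iterative inverse-scattering solvers
carry characteristic artifacts and undershoot the true tumor
permittivity, which hurts voxel-level tumor detection.  `mwi3d` is a
self-contained pipeline for studying a learned fix for this problem:

1. **Phantoms** — randomized three-tissue breast phantoms (ellipsoidal
   fat layer and fibroglandular interior; one or two tumors grown by
   random voxel accretion to a sampled maximum diameter of 1.1–1.5 cm).
2. **Forward simulation** — a scalar volume-integral-equation
   (Lippmann–Schwinger) solver in open air with 24 point probes, each
   transmitting once and received by the other 23 (552 complex channels
   per frequency, five frequencies at 1.1–1.5 GHz), plus 5% complex
   Gaussian measurement noise.  Forward data is generated on a grid
   twice as fine as the inversion grid, so the inversion never sees its
   own discretization.
3. **Inversion** — Contrast Source Inversion (CSI): alternating
   Polak–Ribière conjugate-gradient updates of per-transmitter contrast
   sources w_j and the closed-form update of the contrast
   χ = (ε − ε_n)/ε_n, against an inhomogeneous prior background ε_n
   (fat + fibroglandular, tumors unknown), minimizing
   F = Σ‖d_j − G_S w_j‖²/Σ‖d_j‖² + Σ‖χE_j − w_j‖²/Σ‖χE_j^n‖².
4. **Enhancement** — a real-weighted U-Net mapping the 10-channel stack
   (Re and Im of the CSI images at the five frequencies) to the true
   real permittivity, trained with pixel-wise mean squared error
   L = (1/LMN)ΣΣΣ(I^GT − I^CNN)², Adam, batches of 10, Glorot
   initialization, and k-fold cross validation so every phantom is
   predicted by a model that never saw it.
5. **Evaluation** — detection by thresholding at 85% of the maximum
   reconstructed value and multi-frequency mask intersection;
   quantitative comparison via voxel-pooled ROC/AUC, the DMTD curve
   (distance from each ROC operating point to the ideal corner
   FPR = 0, TPR = 1 as a function of threshold), and reconstruction
   error.

Two profiles are built in: `full` (3-D 64³ volumes, 500 CSI iterations,
depth-4/32-filter U-Net, 200 epochs, 600 phantoms) mirrors the reference
study conditions and is intended for long batch runs; `scaled` (a 2-D TM
slice of the same geometry: 32² inversion grid, 64² forward grid, 100
CSI iterations, depth-2/8-filter U-Net, 20 epochs, 60 phantoms) runs a
complete study in a few minutes on one CPU and is what the tests use.

## Worked example

Generate eight phantoms, simulate and invert them at all five
frequencies, and measure per-frequency detection quality:

```python
import numpy as np
from mwi3d import (RunConfig, make_fixture_suite, roc_analysis, loss_mse,
                   threshold_detect, intersect_masks)
from mwi3d.phantoms import TUMOR

suite = make_fixture_suite(RunConfig(profile="scaled", seed=1, n_phantoms=8))
labels = [t.labels == TUMOR for t in suite["tissues"]]
region = suite["region"]          # breast interior (air excluded)
n = len(labels)
print(f"{n} phantoms, {int(region.sum())} breast voxels each")
for fi, f in enumerate(suite["frequencies"]):
    scores = [st[fi].real for st in suite["stacks"]]
    auc = roc_analysis(scores, labels, [region] * n).auc
    mse = loss_mse(np.stack(scores), suite["y"][:, 0])
    print(f"CSI {f/1e9:.1f} GHz: pooled tumor AUC = {auc:.3f}, "
          f"squared error = {mse:.2f}")
st = suite["stacks"][0]
masks = [threshold_detect(st[fi].real, 0.85, region) for fi in range(5)]
inter = intersect_masks(masks)
print(f"phantom 0: tumor voxels = {int(labels[0].sum())}, "
      f"85% intersection detects {inter.count} voxels, "
      f"{int((inter.values & labels[0]).sum())} inside the true tumor")
```

Output:

```
8 phantoms, 724 breast voxels each
CSI 1.1 GHz: pooled tumor AUC = 0.947, squared error = 10.96
CSI 1.2 GHz: pooled tumor AUC = 0.925, squared error = 11.90
CSI 1.3 GHz: pooled tumor AUC = 0.907, squared error = 12.02
CSI 1.4 GHz: pooled tumor AUC = 0.879, squared error = 12.29
CSI 1.5 GHz: pooled tumor AUC = 0.871, squared error = 12.99
phantom 0: tumor voxels = 7, 85% intersection detects 5 voxels, 3 inside the true tumor
```

The AUC is the probability that a random tumor voxel's reconstructed
Re(ε) exceeds a random non-tumor voxel's (voxels pooled over phantoms
within the breast interior); it degrades with frequency as the lossy
fibroglandular tissue attenuates the tumor's scattering signature.  The
squared error is the pixel-wise mean over Re(ε) against the true
phantom.  Training the U-Net on a 60-phantom suite
(`mwi3d run --scenario baseline --out runs/base`) lowers the error to
≈ 7.9 and raises the pooled AUC to ≈ 0.96, beating the best
single-frequency CSI on both counts.

A command-line interface exposes the stages individually
(`mwi3d generate|simulate|invert|train|evaluate|run`); robustness
scenarios (`offband_freqs`, `small_fibro`, `prior_error_10`,
`no_tumor_prior_error_5`, `highband_freqs`) regenerate test data under
the documented perturbations and reuse the baseline-trained network.

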