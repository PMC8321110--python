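# Methods

## Physical model

All field quantities obey the scalar Helmholtz equation with the
e^{+jωt} time convention, so permittivities are written ε = ε′ − jε″
(ε″ ≥ 0 for passive tissue) and the outgoing Green's functions are
g₃(R) = e^{−jkR}/4πR in 3-D and g₂(R) = −(j/4)H₀⁽²⁾(kR) in the 2-D TM
slice mode.  The phantom sits in open air (ε = 1 − 0.001j); probes are
point sources/samplers on a ring (2-D) or three stacked rings of eight
(3-D) at 1.2× the fat radius.  Every probe transmits once and all other
probes receive, giving n(n−1) = 552 complex data per frequency for the
default 24 probes.  The physical enclosure of a real acquisition system
is not modeled; the artifact-generation/learning/evaluation logic under
study is independent of the enclosure, and an open-region
volume-integral formulation keeps the whole chain self-contained.

The scattered field solves the Lippmann–Schwinger equation
E = E_inc + k_b² ∫ g_b(r−r′) χ_a(r′) E(r′) dr′ with χ_a = (ε − ε_b)/ε_b.
Discretization integrates the kernel over an equal-measure disc/sphere
per voxel (Richmond's scheme): off-center entries are g(R) times an
effective cell measure, the self term is the closed-form cell integral;
both are validated against numerical quadrature in the tests.  The same
kernel backs an FFT convolution on the full grid and dense matrices on
restricted voxel masks, so the two paths agree to rounding.  Incident
fields use the identical cell-averaged kernel (normalized by the cell
measure), which makes the simulated multistatic matrix exactly
reciprocal.  Forward accuracy is checked against independently coded
partial-wave series for a dielectric cylinder (2-D) and sphere (3-D):
both agree to ≈ 0.1–0.2% relative RMS at the default resolution, and
grids resolving fewer than 8 voxels per wavelength in the densest
tissue trigger a warning.

Forward data for inversion experiments is always simulated on a grid
refined 2× relative to the inversion grid (inverse-crime avoidance);
the deliberate exception is the fixed-point/recovery property tests,
which are inverse-crime by design.  Because all phantoms of a run share
the tumor-free breast geometry, the pipeline factorizes the background
system once per frequency (dense LU on the breast mask) and solves each
phantom by an exact Woodbury update over its tumor voxels; masks too
large for a dense factorization (the 3-D full profile) fall back to
FFT-accelerated BiCGStab with relative tolerance 1e−6.

## Measurement noise

"5% noise" is realized as additive complex Gaussian noise with
per-component standard deviation 0.05·rms(|d|)/√2 over the 552 measured
channels at each frequency, so the expected noise-to-signal norm ratio
is 5%.  The noise is scaled to the full scattered field (breast plus
tumor).  Because the lossy fibroglandular interior attenuates the
tumor's scattering signature, the tumor-specific part of the data is
typically below the noise floor in norm; detection still works because
the noise is incoherent across channels and frequencies while the tumor
signature is consistent.

## Phantom generator

The generator emulates simple three-tissue breast phantoms: an
axis-aligned ellipsoidal fat region (10 cm diameter) containing an
8 cm fibroglandular ellipsoid, values from the standard tissue table
(air 1 − 0.001j, fat 3 − 0.6j, fibroglandular 20 − 21.6j, tumor
56.3 − 30j), frequency-independent.  These are the only dimensions
printed for the physical three-region phantom and are used for both
profiles.  Tumors grow by uniform random face-connected accretion from
a uniform random fibroglandular seed until the component's physical
diameter (max pairwise voxel-center distance plus one voxel extent, so
a single voxel has diameter = spacing) reaches a threshold drawn
uniformly from 1.1–1.5 cm.  Two-tumor phantoms forbid the second seed
from touching the first component, keeping the components distinct.
Datasets are half one-tumor, half two-tumor, with per-phantom child
seeds recorded in a manifest; identical spec + seed reproduces volumes
bit-for-bit.

What the generator does **not** emulate: anatomically realistic
(MRI-derived) tissue maps, skin, dispersive permittivity, irregular
fibroglandular shapes.  Passing tests therefore demonstrate the
method's behavior under idealized geometric variability, not clinical
realism.

The prior background ε_n used by the inversion is the same phantom with
tumors relabeled fibroglandular; imperfect-prior scenarios scale the
fibroglandular permittivity by 1.10 or 1.05.

## Contrast source inversion

The unknowns are the contrast χ = (ε − ε_n)/ε_n and one contrast-source
field per transmitter.  The inhomogeneous background is folded exactly
into distorted-background operators: with A the homogeneous-air domain
operator restricted to the breast mask, X_n the diagonal background
contrast and B = diag(ε_n/ε_air),

    G_D = (I − A X_n)⁻¹ A B,   G_S = S B + S X_n G_D,

built densely once per frequency (they are data-independent and shared
across phantoms).  Background fields E^n and the background's own
receiver data (subtracted from the measurements) come from the same
factorization.  Iterations follow the classical alternating scheme: a
Polak–Ribière⁺ conjugate-gradient step with exact per-transmitter line
search on the w_j, then the closed-form pointwise least-squares update
χ = Σ w_j Ē_j / Σ|E_j|² restricted to the breast-interior mask.
Initialization is the standard back-propagation estimate.  The data
normalization is fixed at 1/Σ‖d_j‖²; the state normalization is
re-evaluated each iteration with the previous contrast (freezing it at
the small initial contrast over-weights the state equation and
empirically stalls convergence).  The recorded cost is monotone
non-increasing in practice because ‖χE^n‖ grows while the contrast
builds up; the tests assert this at 1e−10 relative slack.  Degenerate
inputs: exactly zero data leaves the back-propagation start (and hence
χ) at zero; a non-finite cost aborts with the iteration index; pointwise
χ updates guard against zero field energy.  No regularization beyond
the background prior is applied.  Batch runs use complex64 operator
matrices (the per-phantom property checks use complex128); 500
iterations in the full profile, 100 in the scaled profile.

The inverse-crime recovery check deserves a note.  A hard-edged
low-contrast blob can never be recovered to a 10× voxel-RMS reduction
by any diffraction-limited method — the error is dominated by the
discontinuity — and in high-permittivity backgrounds the exterior
(air-side) measurement operator limits the accessible resolution.  The
recovery test therefore uses a smooth Gaussian contrast bump (σ = 2.5
voxels, amplitude 0.1) in a lossless ε = 2 disc at 7.6 GHz (just over 8
voxels per wavelength at the bump peak), where the data demonstrably
determines the target (a truncated-SVD distorted-Born solve of the same
data reaches > 20×): 100 CSI iterations then reduce the Re(ε) error by
≈ 30×.

## Network and training

The enhancement network maps the 10-channel stack (Re/Im of the CSI
images at the five frequencies, ascending frequency, Re before Im) to
the true Re(ε) volume.  Architecture: encoder of `depth` levels, each
one 3^d convolution + ReLU followed by 2× max-pooling, filters doubling
from `base_filters` (default depth 4, base 32, bottleneck 512 — the
filter schedule 32·2^(k−1)); decoder with 2×-stride-2 transposed
convolutions, skip concatenations and 3^d convolutions; a linear 1×1
output head.  Weights are real-valued, Glorot-uniform initialized.  One
network reconstructs Re(ε); the imaginary part behaves analogously and
is not trained by default.  The layers are a compact NumPy
implementation with hand-written backpropagation (kernel-offset-loop
convolutions, non-overlapping transposed convolutions, tie-splitting
max-pool), gradient-checked against finite differences.

Training minimizes the pixel-wise mean squared error with Adam
(lr 1e−3, β = 0.9/0.999), batches of 10, and 4-fold cross validation
(450/150 splits at n = 600; 45/15 at the scaled n = 60), so every
phantom is predicted exactly once by a model that never saw it.  Two
numerical choices matter at the scaled profile's small step budget
(20 epochs × 5 batches = 100 Adam steps):

- **Standardization.**  Inputs and targets are standardized with
  training-fold statistics using per-voxel (and per-channel) means —
  classic per-pixel mean subtraction.  The deterministic breast
  structure and the systematic part of the CSI artifact pattern are
  absorbed by the normalization, so the network trains on per-phantom
  deviations (the tumors); the transform is inverted at prediction
  time.
- **Symmetry augmentation.**  Each batch is presented under a random
  90° in-plane rotation and optional flip.  These are exact symmetries
  of the circular breast/probe geometry (24 probes every 15°), so
  augmented examples are exactly as physical as the originals; this
  regularizes training on small phantom sets without changing the
  dataset size, epoch count or step count, and makes the CSI-vs-network
  comparison stable across training seeds.

Predictions are fixed to the air permittivity outside the
breast-interior mask before evaluation; the mask is prior knowledge the
inversion itself uses (its χ updates are mask-restricted), so both
methods receive it symmetrically.

## Evaluation

Detection thresholds Re(ε) at 85% of the volume maximum inside the
breast mask (reconstructions undershoot the true tumor value, so an
absolute threshold would fail); multi-frequency detection ANDs the
per-frequency masks.  ROC curves pool voxels across all test phantoms
within the breast interior (air excluded); per-phantom evaluation is
available but pooling is the default.  AUC is trapezoidal and equals
the normalized Mann–Whitney U statistic (asserted exactly on random
tied-score instances).  The intersection detector is given a full ROC
curve through the score min_f vol_f/max(vol_f), whose level sets are
exactly the intersection masks at every relative threshold.  The DMTD
curve plots √(FPR² + (1−TPR)²) against the detection threshold
normalized to [0, 1] across each method's own score range (for
cross-method comparability); its summary is the dip minimum, the argmin
threshold, and the dip width at min + 0.05.  Reconstruction error
reports the pixel-wise mean of squared differences and, alongside it,
the square root of that mean; the mean-of-squares form is the headline
number and the comparison metric.  For tumor-free scenarios ROC is
undefined and the report instead counts detected (all false-positive)
voxels per method.

## Problem sizes and profiles

The scaled profile — 2-D TM slice, 32² inversion grid at 3.3 mm
spacing, 64² forward grid, 24 probes, 100 CSI iterations per frequency,
depth-2/8-filter network, 20 epochs, 60 phantoms — was chosen so that a
complete study (simulation, five inversions per phantom, three
cross-validated trainings) finishes in minutes on a single CPU; it is
the configuration exercised by the test-suite and the acceptance
script.  The full profile (3-D 64³, 500 iterations, depth-4/32-filter
network, 200 epochs, 600 phantoms) reproduces the reference study
conditions and is practical only as a long batch run.  Headline
quantities from the scaled profile (AUCs ≈ 0.95–0.96, squared errors
≈ 8–11) characterize the desk-scale configuration, not the full-size
study.

## Known limitations

- Scalar fields; no polarization, no antenna model, no enclosure.
- Single simple fibroglandular region; no skin layer; non-dispersive
  tissues.
- The 2-D scaled profile changes the wave physics (cylindrical
  spreading, 2-D Green's function); orderings and properties validated
  there are expected, but not shown, to transfer quantitatively to 3-D.
- CSI is run to a fixed iteration count, not to a convergence
  criterion, matching the reference protocol.
- With imperfect *structural* priors both CSI and the network are known
  to degrade; that scenario is exposed (`small_fibro` geometry change,
  prior permittivity errors) but no recovery is claimed.
- The high-frequency scenario (`highband_freqs`, 2.5–2.9 GHz) emulates
  out-of-band operation; degraded detection is the expected outcome and
  is reported, not asserted.
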