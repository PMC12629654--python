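# Methods

`eatseg` implements a fully automated two-stage pipeline for epicardial
adipose tissue (EAT) volumetry on non-contrast cardiac CT, together with
the synthetic phantoms and agreement statistics needed to test it end to
end without clinical data.

## The measurement problem

EAT is the fat enclosed by the pericardial sac. On CT, adipose tissue is
identified by attenuation alone — the conventional window at 120 kV is
−190 to −30 HU — but thresholding a whole scan also picks up paracardial
fat outside the sac, mediastinal fat, and subcutaneous fat. The clinically
meaningful quantity therefore requires a pericardium segmentation first;
fat voxels are counted only inside it. Stage one produces that
segmentation with a 3D UNet++; stage two applies the HU window inside the
mask **on the native-resolution image** and reports
`V = n_voxels · sx·sy·sz / 1000` cm³, with a per-slice (inferior-first)
volume profile.

## Canonical geometry

All volumes are reoriented at load time to RAS+ so that axis 2 runs
inferior→superior and slice index 0 is the most inferior slice. Every
statement about "inferior slices" (the redundant class, the
inferior-share statistic) is defined against this convention. DICOM
ingestion is deliberately narrow (single axial series, monotone slice
positions, no gantry-tilt correction); anything else should be converted
to NIfTI first.

## Preprocessing

The training representation is a fixed cube built deterministically:

1. isotropic resampling to 1.6 mm (trilinear for images, nearest for
   masks), output shape `round(n·s/t)` per axis (round half away from
   zero, minimum 1);
2. centred pad/crop to 128³ (images padded with the clip floor −800 HU ≈
   air/lung, the dominant border tissue; labels padded with 0); per axis
   the low/high counts differ by at most one and pad and crop are mutually
   exclusive;
3. HU clipping to [−800, 1200] and linear normalisation to [0, 1].

The order resample → pad/crop → clip/normalise is fixed and recorded in a
`GridTransform` that `invert_to_native` uses to map predictions back
(un-pad, zero-fill the cropped margin, nearest-neighbour resample to the
native shape). Normalising before vs after padding changes nothing
numerically here because the pad value equals the clip floor; the order is
nonetheless fixed and documented so transforms stay auditable.

**Redundant class.** Pericardium segmentation is hardest in the apical
(inferior) region, where the sac boundary is faint — and that region
matters most, because the most inferior 15–20% of EAT-containing slices
hold over 20% of total EAT volume. Supervision therefore uses three
categories: background (0), pericardium (1), and a "redundant" class (2)
for fat-density voxels (−198 to −80 HU) *outside* the pericardium in the
inferior 20% of axial slices (`ceil(0.2·nz)` slices of the whole scan,
counted from the most inferior). The extra class penalises boundary
leakage into adjacent fat and sharpens the apex boundary. Pericardium
wins ties, so the primary target is never altered; labels are generated
on the resampled grid so all supervision shares one geometry.

## Network

The segmentation model is a 3D UNet++: an encoder column X(i,0) with 2×
max-pool downsampling, and nested decoder nodes X(i,j) that concatenate
all same-level predecessors with a 2³-stride-2 transposed-convolution
upsampling of X(i+1,j−1). Each node is two (3³ conv → instance norm →
LeakyReLU(0.1)) stages; a 1×1×1 head with an independent sigmoid per
class sits on X(0, L−1); deep supervision is not used. The reference
configuration is five levels, encoder channels [32, 32, 64, 128, 256]
(final upsampling feature size 32) on 128³ cubes.

The three class channels are trained as independent binary targets with
per-voxel binary cross-entropy summed over channels (they are disjoint by
construction, so the multi-label reading is consistent); the optimiser is
RMSProp (smoothing 0.99, eps 1e−8) at a fixed learning rate, batch size 1,
no scheduler. At inference the pericardium channel is thresholded at 0.5
(configurable), optionally reduced to the largest 26-connected component,
and mapped back to the native grid; the redundant channel is discarded.

The whole network — forward and backward — is a self-contained numpy
implementation: direct 3³ convolutions as JIT-compiled kernels, explicit
gradient kernels for weights and inputs, hand-written instance-norm and
pooling backward passes, verified against float64 central differences in
the test suite. Training is deterministic for a fixed seed on a given
machine (single-threaded kernels); bitwise reproducibility across CPU
generations is not claimed.

### Desk-scale ("toy") training recipe

CPU-scale tests use four levels, channels [2, 4, 8, 16], 64³ cubes at
2.4 mm. Two optimisation knobs are rescaled for this regime, and only
these:

* **learning rate 1e-3** (default 1e-4). A fixed-lr RMSProp step moves
  each coordinate by ≈ lr regardless of gradient scale, so total
  displacement after training is ≈ lr × steps. At clinical scale an epoch
  is ~10³ scans; at 20 phantoms × ≤50 epochs it is 10³ steps in total, and
  1e-4 × 10³ = 0.1 cannot reorganise weights initialised at ~0.2 scale
  (He). Empirically the default rate leaves held-out Dice at ≈ 0 after 30
  toy epochs, while 1e-3 reaches Dice > 0.9 by epoch ~20.
* **class-prior head-bias initialisation** (`foreground_prior = 0.1`):
  head biases start at the prior log-odds instead of 0, so the short step
  budget is spent on boundary discrimination rather than on learning
  class frequencies. Weights remain randomly initialised.

## Contour interpolation

Manual annotation practice marks the pericardium on every 5th axial slice
(denser near the apex). `interpolate_dense` completes the mask by
shape-based interpolation: each annotated slice becomes a signed 2D
Euclidean distance field (positive inside; empty/full slices use a large
finite constant), fields of the two bracketing annotated slices are
blended linearly along z, and the result is thresholded at ≥ 0. Annotated
slices are copied through exactly; slices outside the annotated extent
stay empty. For nested convex shapes this has closed-form behaviour
(concentric disks interpolate their radii linearly), which the tests
exploit. Equivalence with any particular interactive tool's smoothing is
not claimed.

## Synthetic phantoms

The phantom emulates exactly the features that exercise the pipeline's
failure modes, and no more (no vessels, no motion, no beam hardening):

* lung/air background (−800 HU), soft-tissue mediastinum (40 HU);
* an ellipsoidal pericardial sac (axes ≈ 50×45×55 mm) bounded by a thin
  (2 mm) fibrous line at 30 HU whose contrast fades toward the apex;
* inside the sac, a myocardial/blood core (inner scale λ = 0.75 of the
  sac) and an epicardial fat sub-shell at −100 HU occupying a fraction
  f(ζ) of the shell cross-section that ramps linearly from 0.30 at/above
  the equator to 0.95 at the inferior pole — making the apical cap
  fat-dominant, which reproduces the inferior-heavy EAT distribution
  (inferior-share(0.2) ≈ 0.29 > 0.2 for the defaults);
* optional paracardial fat (a ≈ 33 cm³ sphere at the same HU, outside the
  sac) that makes naive global thresholding overestimate EAT by ≳ 40%,
  and an optional calcified focus (300 HU);
* additive Gaussian HU noise (default SD 10), applied only after all
  truth quantities are computed. At this noise level no material's HU can
  cross the adipose window (≥ 6 SD margins), so noise perturbs only
  partial-volume boundary voxels.

**Analytic truth.** In normalised sac coordinates the fat region is
ρ ∈ [ρ_f(ζ), 1] with ρ_f² = 1 − f(ζ)(1−λ²), so the true volume is the 1D
integral `V = πabc ∫ min(1−ζ², f(ζ)(1−λ²)) dζ`, evaluated by fine
trapezoidal quadrature — an oracle independent of the voxel renderer.
Rendering uses supersampled occupancy: each voxel is subdivided into s³
sample points, voxel HU is the mean (a partial-volume model) and truth
masks use occupancy ≥ 0.5. The default s = 3 is deliberately odd: even
factors never sample the voxel centre and the ≥ 0.5 tie inflates rendered
masks (+2.4% volume at 0.8 mm for s = 2 vs +0.06% for s = 3). Rendered
minus analytic volume converges to zero as spacing shrinks
(6.0% → 3.0% → 1.5% at 2.0/1.0/0.5 mm), the expected first-order
partial-volume behaviour.

Datasets are drawn with per-case jitter (heart scale 0.82–1.15, fat
fractions, noise, centre offsets), spanning roughly 40–250 cm³ of EAT to
mirror a clinical spread with mean ≈ 130 cm³.

What passing on phantoms does **not** show: robustness to real-world
boundary texture, coronary calcification inside fat, motion/streak
artifacts, HU calibration drift across kV settings, or anatomical
variation beyond ellipsoidal geometry. One specific gap: the phantom's
extra-pericardial fat sits at equator level, so few fat-density voxels
fall in the inferior slice band and the redundant class receives little
supervision signal here — its boundary-sharpening effect is therefore
exercised mechanically but not stressed the way abdominal fat stresses it
in real scans. The phantom demonstrates the pipeline's correctness and
learnability, not clinical performance.

## Agreement statistics

`metrics` implements the method-comparison suite: Dice (both-empty = 1 by
convention), relative volume error `100·|V_pred − V_ref|/V_ref`, Pearson
r, Bland–Altman bias with 95% limits of agreement `bias ± 1.96·sd(d)`
(sample sd; differences are predicted − reference, so underestimation
gives a negative bias), and ICC(2,1) — two-way random effects, absolute
agreement, single measure — with the standard F-distribution confidence
interval. The ICC form is the conventional choice for two readers
measuring the same absolute quantity; the implementation is cross-checked
against an independent statistics package in the tests.

## Numerical choices and degenerate inputs

* EAT window bounds are inclusive on both ends; "between −190 and −30" is
  ambiguous and the inclusive reading matches the common convention.
* `inferior_share` counts EAT-containing slices (not all scan slices) and
  errors on zero total volume rather than returning 0.
* Resampling uses the pixel-as-cell (align-corners-false) convention on
  both forward and inverse paths; inverse nearest mapping is exact-shape
  by construction.
* Dice/extraction refuse mismatched grids instead of broadcasting.
* Training raises a divergence error naming the epoch on a non-finite
  loss; lr = 0 provably freezes the loss trace.

## Problem sizes used in the shipped benchmarks

Phantom rendering for the learned-pipeline benchmarks uses 96×96×84 grids
at 2.0 mm (training/evaluation) and 0.8 mm grids for threshold-stage
volume recovery; the end-to-end benchmark trains on 20 phantoms for 50
epochs and evaluates 5 held-out phantoms, which together with the 20 noisy
recovery phantoms keeps a full acceptance run in the tens of minutes on a
single CPU core. These sizes are package choices balancing statistical
margin against convenience; nothing in the implementation is specific to
them.

## Known limitations

* No gantry-tilt or multi-frame DICOM support; no PACS connectivity.
* The HU window is fixed (no kV-dependent adaptation) and no fat
  radiomics beyond volume are computed.
* The clinical-scale configuration (five levels, 128³, lr 1e-4) is
  implemented and tested for mechanics but not trained to convergence
  here; no claim is made of reproducing any externally trained model's weights.
* Loss traces are machine-local: identical seeds reproduce bitwise on one
  machine but may differ across BLAS/SIMD generations.
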