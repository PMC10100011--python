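# Methods

This note records the models, parameters and design choices behind
`carotiq`, in the order the pipeline runs them.

## Data model and grids

Volumes live on axis-aligned voxel lattices indexed `(z, y, x)` with
per-axis spacing in mm; the analysis grid uses 3.0 × 1.37 × 1.37 mm
(slice × row × column), the voxel size at which the segmentation network
operates. World coordinates are RAS-aligned; by package convention the
array `x` axis increases toward the patient's left, so the carotid on the
`+x` half is labelled *left*. PET and CT are resampled onto one common
analysis grid before any pipeline stage (trilinear for scalar volumes,
nearest-neighbour for masks); out-of-field voxels are filled with −1000 HU
(CT) or 0 (PET). Only orthogonal, axis-aligned NIfTI affines are accepted:
oblique and nonrigidly-registered acquisitions are out of scope.

Whether SUV statistics should be computed on the PET native grid or a
common grid is a genuinely open choice; this package defines all
statistics on the common analysis grid so that CT-defined VOIs and PET
values index the same lattice.

## Phantom generator

The generator emulates the statistical structure of a noncontrast-CT +
NaF-PET neck study, not anatomy. Defaults (all overridable in
`PhantomSpec`):

| parameter | default | meaning |
| --- | --- | --- |
| grid | (60, 128, 128) @ 3.0 × 1.37 × 1.37 mm | ~18 cm of neck |
| carotid_radius_mm | 3.0 | common-carotid lumen+wall tube radius |
| carotid_curvature_amplitude_mm | 3.0 | sinusoidal centerline excursion |
| carotid_suv_mean / sd | 1.0 / 0.15 | per-case tissue SUV draw (truncated ±3σ) |
| background_suv | 0.5 | soft-tissue blood-pool level |
| bone_suv / bone_hu | 5.0 / 700 | vertebral column uptake and density |
| soft_tissue_hu / vessel_hu | 40 / 45 | noncontrast CT gives vessels almost no contrast |
| psf_fwhm_mm | 6.0 | scanner resolution, applied to the bone activity |
| noise_sd_suv / ct_noise_sd_hu | 0.1 / 10 | additive Gaussian noise |
| include_jugular_distractor | off | vessel-density tubes without NaF avidity |

Carotid radius 3 mm and curvature 3 mm were chosen once as typical
common-carotid calibre and course; the distractor flag is off by default
(an opt-in harder condition). The per-case tissue SUV is a single draw per
side around SUVmean ≈ 1, matching cohort-level summaries of carotid NaF
uptake in healthy/angina populations; no published voxel-level
distribution exists, so a Gaussian tissue model is a declared assumption.

A voxel is carotid iff its center lies within the tube radius of the
centerline polyline (Euclidean, world mm). The bone's *excess* activity is
blurred with the Gaussian PSF before noise, producing the spill-over halo
the leakage-removal stage exists for; carotid and background activity are
left unblurred so that the carotid tissue value is exact. (Blurring the
whole activity map would also be defensible, but at 3 mm radius versus
6 mm FWHM it would destroy the generator's own calibration — the mean SUV
over truth voxels would drop ~25% below the nominal tissue value.)

What the phantoms do **not** emulate: real anatomy (bifurcations, vessel
tapering), attenuation/scatter physics, respiratory motion, contrast CT,
inter-scanner SUV calibration error. Tests passing on phantoms therefore
demonstrate the pipeline's mechanics and statistics, not clinical accuracy.

The simulated "second observer" (`perturb_mask`) applies world-metric
dilation then erosion and flips 5% of boundary voxels; it produces the
paired segmentations the agreement study needs without human input.

## Segmentation network

Classic 3-D U-Net layout: two valid 3×3×3 convolutions + ReLU per level,
2×2×2 max-pooling, three poolings (four resolutions), 2×2×2
up-convolutions, center-cropped skip concatenations, 1×1×1 classification
head with softmax over {background, carotid left, carotid right}. Valid
convolutions shrink the patch by 88 voxels per axis — 100³ in, 12³ out —
and admissible input extents are ≥ 92 and ≡ 4 (mod 8). The net consumes
the CT channel only; PET enters downstream (leakage removal,
quantification).

Whole-volume inference tiles the CT with disjoint output responsibilities
(edge tiles shift inward; the volume is edge-replication padded by the
44-voxel margin). Argmax ties break toward background. Because the same
fully-convolutional weights accept any admissible extent, small volumes
are segmented in one enlarged tile.

The implementation is plain numpy (im2col convolutions chunked to bound
scratch memory, explicit backprop, float32). Channel widths default small
(`base_channels`) — the published-scale network's widths are unknown and
desk-scale training does not need them. Training: categorical
cross-entropy over each patch's output region, optionally class-weighted
(default weights (1, 12, 12)); Nesterov-accelerated Adam (Nadam:
β₁ = 0.9, β₂ = 0.999), global gradient-norm clipping (default 2.0);
patches sampled per epoch with a configurable fraction centered on carotid
voxels; a train/validation case split; everything driven by one seed.
Patch sampling strategy, epochs, learning rate, weights and widths are
this package's declared defaults, not inferences about any original
training setup.

An optional input variant (`NetSpec.coord_channels`) appends normalized
(z, y, x) coordinate ramps to the CT channel as an explicit position
prior; it is off by default — in desk-scale trials it did not outperform
the plain CT input — but kept because left/right labeling on
near-symmetric anatomy is otherwise learnable only through asymmetric
context features.

Three training choices deserve justification. *Class weighting*: the
carotids occupy well under 1% of a neck volume, and at desk scale the
plain voxel-mean loss collapses to a confident background predictor — the
loss falls while the carotid classes never win an argmax. Weighting the
carotid classes moves the loss's optimum so that even modest posterior
evidence (roughly P(carotid|x) ≳ 1/(1+w)) crosses the argmax boundary;
(1, 1, 1) restores the plain loss. *Patch shape*: desk-scale runs default
to 100×132×132 input patches (output 12×44×44). Wider in-plane windows
deliver an order of magnitude more supervised voxels per second of CPU
convolution and keep the vertebral landmark inside most windows; the
100³→12³ geometry remains the published-scale reference and is what the
geometry checks exercise. *Curriculum*
(:func:`carotiq.unet.desk_scale_curriculum`): a strongly weighted warmup
(weights (1, 12, 12), lr 4·10⁻³) followed by two short low-learning-rate
refinements at weights (1, 5, 5) and (1, 3, 3). The warmup's operating
point deliberately over-segments (it crosses argmax at weak evidence);
the refinements anneal the loss back toward the balanced posterior and
tighten the masks without losing the vessels. One seeded curriculum on
8 training + 2 validation phantoms runs in roughly twenty minutes on one
CPU.

The deterministic `reference_segmenter` is a rule-based alternative route:
CT vessel band (42.5–60 HU) ∩ per-side adaptive SUV threshold (midpoint of
the body-median SUV and the in-band 99th-percentile SUV on that side),
morphological closing, largest 26-connected component per mid-sagittal
side. On noise-free phantoms the band isolates vessels exactly and the
adaptive threshold tracks each case's tissue-SUV draw, which is what makes
it usable as an independent oracle in tests; on realistic CT noise a 5 HU
band is meaningless, so it is a phantom-world tool, not a clinical one.

## Postprocessing

*Largest almost-connected component* (per carotid class, applied
independently): 26-connected components are grouped by the transitive
closure of "minimum voxel-center distance ≤ 20 mm" and the group with the
most voxels is kept; ties go to the group containing the lexicographically
smallest voxel. Distances are between voxel centers in world mm.

*SUV leakage removal* (single pass): with μ, σ the mean and population SD
of PET SUV over the VOI *before* any removal, candidate voxels exceed
μ + 2σ; a candidate is removed iff its nearest activation maximum lies in
the bone mask. An *activation maximum* is a 26-neighbourhood local PET
maximum; plateaus count when they strictly dominate their outer boundary
and are represented by their lexicographically smallest voxel; maxima
closer than 5 mm are reduced to the strongest (nearest-tie: higher SUV,
then lexicographic). Whether the original procedure iterated the removal
or used a sample SD is unknowable from the description; one pass with the
population SD is declared here.

The bone mask is a stand-in for a dedicated tool: HU ≥ 200, 1-voxel
closing, drop components < 0.5 ml. 200 HU separates the phantom's 700 HU
bone from 45 HU vessels with wide margin.

## Agreement statistics

Differences d = a − b per subject; bias d̄, sample SD s (n−1); 95% LoA
d̄ ± 1.96 s (z fixed at 1.96, not a t quantile — the convention the
reproduced summary tables follow). Bias CI is t-based. Exact LoA
confidence limits use the noncentral-t pivot: for the upper LoA μ + zσ,
intervals of the form d̄ + k·s/√n have exact coverage when the k-range
covers the corresponding probability of T' ~ t'_{n−1}(z√n). Two exact
variants are implemented; both have nominal coverage and differ in how the
miss probability is split:

* `tails="symmetric"` (default): equal halfwidth h above and below the
  LoA, with h solved so P((z−h)√n ≤ T' ≤ (z+h)√n) = 0.95;
* `tails="equal"`: equal-tailed quantiles k = t'⁻¹(0.025), t'⁻¹(0.975).

The symmetric variant is the default because symmetric-about-the-LoA
limits are how exact Bland–Altman confidence bounds are conventionally
tabulated and reported; the equal-tailed variant is kept for comparison.
Coverage of both is checked by simulation in the test suite.

Dice is 2|A∩B|/(|A|+|B|); two empty masks score 1 (agreement on absence)
with an explicit flag. Populations of per-case Dice values are compared
with a two-sided Welch t-test — the field's reports rarely name their
test; Welch is the least-assumption default. Percent volume deviation is
the mean of 100·|a−b|/((a+b)/2). Degenerate paired t-tests (zero-variance
differences) return t = 0, p = 1 when the mean is also zero, and a flagged
machine-floor p otherwise.

## Numerical choices

* SUVmean of a VOI is clipped to SUVmax (summation order can push the mean
  of a constant VOI one ulp above its max).
* Distance comparisons in postprocessing carry a 10⁻⁹ slack so that "gap
  exactly 20 mm" counts as connected on both the fast path and the
  brute-force oracle.
* The geometry walker raises naming the first failing axis rather than
  silently rounding.
* All random draws flow from explicit `numpy.random.Generator` seeds; no
  global state.

## Problem sizes in tests and the acceptance script

Training demonstrations use 8 training + 2 validation phantoms on the
default 60×128×128 grid with a 4-channel-base network — large enough for
the loss to fall and validation Dice to become meaningful, small enough
for a single-CPU run. Coverage simulations use 5000 replicates at n = 25.
The randomized postprocessing oracle comparison uses 50 instances on
≤ 32³ grids. These sizes are the package's desk-scale defaults.

## Known limitations

* The numpy network trains at desk scale only; no GPU path, no
  augmentation beyond patch sampling.
* The reference segmenter assumes phantom-like tissue values.
* The bone stand-in thresholds CT; it is not a general bone segmenter.
* Phantom realism limits: see above — results on phantoms bound the
  pipeline's correctness, not its clinical performance.
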