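# Methods

## The pipeline

Photon absorption remote sensing (PARS) microscopy excites a specimen with
pulsed lasers (here 266 nm targeting DNA/RNA and 532 nm targeting
hemoglobin, the 532 nm pulse ~500 ns after the 266 nm one) and records,
per pixel, the radiative emission, the time-resolved non-radiative (NR)
probe-beam modulations, and the pre-excitation scattering baseline.
`pars_stain` turns such recordings into virtual H&E stains in four stages:

1. **Conventional channels** (`signals`): for each excitation window, the
   NR integral (baseline-subtracted modulation energy); the radiative
   amplitude in the 266 nm window; the scattering baseline. Channels are
   percentile-saturated, rescaled to [0, 1] and color-reversed before
   entering the model.
2. **Time-domain features** (`kstar`): K*-means learns K characteristic
   signal shapes from a random subset of NR traces; applying the
   pseudo-inverse of the feature matrix to every trace yields K feature
   amplitude images m_f1..m_fK.
3. **Colorization** (`mcgan`): a multi-channel cycleGAN maps an N-channel
   stack of selected channels to RGB H&E. The RGB target's blue channel is
   duplicated up to N for training; the surplus N−3 generated channels are
   discarded at read-out. Whole images are colorized patch-wise with ~50%
   overlap and feathered stitching.
4. **Selection** (`studies`): the K-study picks the number of features by
   held-out SSIM (radiative channel always included for a fair
   comparison); the C-study trains one model per non-empty subset of the
   channel array (2^N − 1 models) and ranks subsets by SSIM, PSNR and
   RMSE, all computed after an identical Gaussian pre-blur of prediction
   and ground truth.

## K*-means details

Signals are treated as rays in R^n: the distance between two signals is
the sine of the angle between them (zero for scaled or inverted copies,
one for orthogonal shapes), and a centroid is the principal component of
its member signals unioned with their negations. Two consequences drive
the implementation:

* **Amplitude weighting.** The centroid PCA uses raw (unnormalized)
  members, so each signal's influence scales with its squared norm. This
  is what makes the update robust to weak noisy pixels; normalizing
  members first would hand background noise the same vote as strong
  tissue signal and measurably corrupts centroids. The trade-off: the sum
  of squared assignment distances (the angular inertia) is no longer
  guaranteed to fall at every step. It falls overall in every observed
  run; single-step upticks stay below ~1% and are logged. The per-fit
  trajectory is kept in `FeatureSet.inertia_history`.
* **Energy-weighted seeding with restarts.** Pure farthest-point seeding
  fails in the presence of signal-free pixels: their noise directions are
  nearly orthogonal to everything, so they hijack the far-point picks and
  Lloyd iterations cannot recover (the stranded centroids only ever
  attract noise). Seeds are therefore picked by maximizing
  (normalized norm)² × (angular distance to previous seeds)², with the
  first seed sampled proportional to squared norm. Four restarts are run
  (sub-seeded deterministically from the user seed) and the lowest-inertia
  solution wins.

Other numerical choices: convergence when the largest centroid movement
falls below 1e−4 (angular distance), at most 100 iterations; empty
clusters are re-seeded from the worst-fit signal; centroids are oriented
so their largest-magnitude element is positive (the PCA sign is
arbitrary); pixels with signal norm below 1e−3 × the median norm are
excluded from learning and get zero amplitudes at unmixing time; the
pseudo-inverse truncates singular values below 1e−10 × the largest, and a
rank-deficient feature matrix is reported with the offending near-collinear
centroid pair. Features are learned on the full post-excitation trace
(both peaks); learning uses a seeded uniform 10% pixel subset by default.

## The colorization model

Generators are encoder–decoder UNets with skip connections; all
convolutions use kernel 4 and stride 2 (`downsampling_depth` levels) with
instance normalization and LeakyReLU(0.2) down / ReLU up, and a tanh head.
Discriminators are PatchGANs: stride-2 kernel-4 layers plus a final
stride-1 layer emitting a patch score map. The objective is least-squares
adversarial loss + cycle consistency (weight 10) + identity loss (weight
5), optimized with Adam(β1 = 0.5, β2 = 0.999) at lr 2e-4, constant for the
first half of training then stepped linearly toward zero every
`lr_decay_interval` epochs. A replay buffer of 50 generated images feeds
the discriminator updates. Early stopping triggers when the 5-epoch moving
average of the generator loss fails to improve by 0.1% for 10 consecutive
epochs. Registered A/B patches are fed as corresponding items (batch 1 by
default).

An optional `supervised_weight` adds a paired L1 term between each
generator output and its registered counterpart. It is off by default (the
objective is then the standard cycleGAN one); the scaled-down studies
below enable it, because at desk scale (tiny nets, ≤10 epochs) the purely
adversarial color assignment is dominated by seed-to-seed optimization
noise — observed held-out SSIM on identical data ranged 0.27–0.80 across
seeds — and the study would then measure GAN luck rather than channel
informativeness. The paired term is the direct expression of training on
registered pairs, which is how the model is intended to be used.

Networks, Adam and the conv/transposed-conv/instance-norm kernels with
their gradients are implemented in-package on numpy (`pars_stain._nn`), a
deliberately small CPU engine; gradients are verified against central
differences in the test suite.

Subsets with fewer than three channels (possible in the C-study) are
padded by duplicating the last input channel up to three, mirroring the
target-side duplication: the RGB target fixes the network width at ≥ 3.

Stitching uses separable triangular (tent) weights peaking at the patch
center, floored at 1e−3 so border pixels covered by a single patch remain
defined; weights are normalized per pixel, so constants are conserved
exactly and seams stay continuous.

## Evaluation

RMSE is computed on the 0–255 intensity scale over all RGB channels;
PSNR = 20·log10(255/RMSE), flagged infinite when RMSE = 0; SSIM uses the
standard constants on the luminance-converted pair with 7×7 windows. Both
images are blurred with the same Gaussian (default σ = 2 px, recorded in
every report) before any metric, which suppresses the effect of small
registration errors in real data. LPIPS is an optional hook: a caller may
supply a perceptual backbone callable; it never ships with the package and
is excluded from ranking unless explicitly enabled. C-study rows are
ranked per metric (1 = best) and ordered by the mean of per-metric ranks,
ties broken by SSIM rank then subset name. Evaluation happens on stitched
whole test images, not per patch, and on held-out fields of view.

## The phantom generator

`synth` generates everything the pipeline consumes, so no external data is
needed. A field of view is a dense connective-tissue section (85–90%
fill, matching tissue sections that are mostly tissue) with seeded nuclear
disks and, for the skin-like preset, small red-blood-cell disks; nuclei
and RBCs occlude the stroma beneath them. Class masks are blurred
(σ = 0.4 px) into soft mixing weights — so unmixing is non-trivial at
edges — modulated by a smooth ±10% amplitude field, and capped at a
per-pixel sum of 1.

Per pixel, the NR trace is `baseline + Σ_c weight_c · shape_c + N(0, σ²)`
per sample (default σ = 0.02 against unit-norm shapes, i.e. roughly 50:1
peak signal-to-noise for a fully weighted pixel). Class shapes are damped
sinusoids sharing a common 266 nm response plus a class-specific term:
extracted time-domain features are correlated in practice, and this
correlation is load-bearing — it is precisely what makes *redundant*
clusters harmful (splitting a class yields near-collinear centroids whose
pseudo-inverse amplifies noise into the feature maps), which is the
behavior the K-study exploits. The skin preset has three signal classes
(nucleus, RBC with its hemoglobin-like 532 nm peak, connective; pairwise
angular distances ≈ 0.6–0.9); the brain preset has two, more strongly
correlated classes (distance ≈ 0.38, no RBCs). The radiative raster
responds with a short pulse in the 266 nm window only, scaled by
class-specific amplitudes (connective 1.0, RBC 0.35, nucleus 0.15). The
pseudo-H&E ground truth is the deterministic per-pixel blend of class
colors (purple nuclei, red RBCs, pink stroma, white background).

The first excitation is placed at 96 ns rather than 0 so a pre-excitation
segment exists for the baseline and scattering estimates; traces are
n = 256 samples at 4 ns/sample, covering both peaks.

What the phantom does **not** emulate: optical physics (fluence,
Grüneisen, scattering), registration error between modalities (pairs are
aligned by construction), scanner artifacts, stain variability, and the
morphological richness of real tissue. Passing tests on phantoms
demonstrates that the algorithms recover planted structure under the
stated noise model — not that the learned colorizations transfer to real
tissue.

## Scaled-down study conditions

The selection studies run end-to-end on a single CPU at reduced scale:
128×128 fields of view, 64-pixel patches (~49 training patches at ~75%
overlap), UNet depth 2 with 8 base filters, 2-layer discriminators,
10 epochs, paired L1 weight 10, K examined over {2, 3, 4} (bracketing both
presets' true class counts; the full-scale protocol examines 2–6). A
single desk-scale run's held-out SSIM is noticeably seed-dependent, so
each K is scored by the mean SSIM of three sub-seeded feature-learning /
training replicates (`n_replicates=3` in `run_k_study`); the averaged
selection recovers K = 3 on the skin-like phantom and K = 2 on the
brain-like phantom. The same conditions are used by
`scripts/acceptance.py`.

## Known limitations

* The numpy engine is single-threaded per operation and intended for
  desk-scale experiments; the full-scale protocol (256-pixel patches,
  depth 6, 200 epochs) is expressed in the defaults but not practical
  without a GPU framework.
* Real-data ingest (HDF5 rasters, TIFF channels) is implemented, but no
  registration is provided: inputs must be co-registered upstream.
* The paper-scale absolute metric values depend on unreleased tissue data
  and are out of scope; phantom SSIM/PSNR/RMSE values characterize the
  pipeline, not the instrument.
* With `supervised_weight = 0` at desk scale, adversarial training is
  high-variance; expect unstable colors on tiny runs.
* On the brain-like phantom the K-study margin between K = 2 and K = 3 is
  small (~0.02 replicate-mean SSIM): in a purely linear mixing model an
  information-complete K above the true class count is penalized only
  through pseudo-inverse noise amplification, a weaker effect than the
  redundancy penalties real data exhibits.
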