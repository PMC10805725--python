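# pars-stain

Virtual H&E staining of photon absorption remote sensing (PARS) microscopy
data: time-domain feature extraction with a scale/sign-invariant K-means
variant, and multi-channel cycleGAN colorization with exhaustive channel
selection.

PARS records, at every pixel, a time-resolved non-radiative (NR) signal —
probe-beam intensity modulations following pulsed excitation at 266 nm
(DNA/RNA) and, ~500 ns later, 532 nm (hemoglobin) — together with the
radiative emission amplitude and the pre-excitation scattering baseline.
Conventionally each trace is reduced to a single number (the integrated
modulation energy), discarding the shape of the signal. This package
implements the alternative: treat each trace s ∈ R^n as a ray whose
*angle* encodes the absorber, cluster the rays with **K\*-means** — the
distance between signals x, y is sin∠(x, y), and a cluster centroid is
the principal component of the cluster unioned with its negation — and
unmix every trace against the learned feature matrix
F = [f₁ | … | f_K] by its Moore–Penrose pseudo-inverse, a = F⁺s, giving K
feature images m_f1..m_fK. Selected channels (NR₅₃₂, NR₂₆₆, R₂₆₆, m_f…)
feed a **multi-channel cycleGAN**: UNet generators and PatchGAN
discriminators whose input width N may exceed 3; the RGB H&E target is
expanded by duplicating its blue channel and the surplus N−3 generated
channels are discarded. Two selection protocols complete the pipeline:
the **K-study** (pick K by held-out SSIM, K ∈ 2…6) and the **C-study**
(train one model per non-empty channel subset — 2^N−1 models — and rank
by SSIM, PSNR and RMSE computed after an identical Gaussian pre-blur).

Real PARS rasters are not publicly distributable, so the package ships a
seeded phantom generator (`pars_stain.synth`) producing co-registered NR
and radiative rasters, ground-truth mixing weights and pseudo-H&E images
with the statistical structure the pipeline assumes; every stage is
exercisable — and tested — end-to-end without any download.

## Worked example

```python
import numpy as np
from pars_stain import kstar, mcgan, signals, studies, synth

# a skin-like phantom pair: train and held-out test fields of view
train = synth.generate_phantom(synth.skin_phantom_spec(128, 128, seed=0))
test = synth.generate_phantom(synth.skin_phantom_spec(128, 128, seed=100))

# learn 3 time-domain features from a 10% pixel subset, inspect recovery
w = signals.post_excitation_window(train.nr)
fs = kstar.learn_features(train.nr, w, K=3, subset_fraction=0.1, seed=0)
print(f"converged={fs.converged} after {fs.n_iter} iterations, "
      f"inertia={fs.inertia:.1f}")

# scaled-down K-study: R channel + m_f1..K, tiny GAN, 10 epochs
cfg = mcgan.MCGANConfig(patch_size=64, max_epochs=10, downsampling_depth=2,
                        ngf=8, ndf=8, n_disc_layers=2, seed=0,
                        supervised_weight=10.0)
report = studies.run_k_study(train, test, cfg, k_range=[2, 3, 4],
                             target_train_patches=49)
for r in report.results:
    print(f"{r.label}: SSIM {r.report.ssim:.4f}")
print("best K =", report.best_K)
```

Output from the run above:

```
converged=True after 3 iterations, inertia=328.2
K=3: SSIM 0.9587
K=4: SSIM 0.8858
K=2: SSIM 0.8009
best K = 3
```

The phantom plants 3 signal classes, and the study recovers K = 3: with
K = 2 a class pair shares a feature (colors get confused, SSIM drops
to 0.80), while K = 4 splits a class into two nearly collinear centroids
whose pseudo-inverse amplifies noise into the feature maps (SSIM 0.89).

The same protocol on the brain-like phantom (two, more strongly
correlated classes; `synth.brain_phantom_spec`) selects K = 2, mirroring
the skin-3/brain-2 pattern the selection procedure is designed to expose.

## Command line

```sh
pars-stain synth --preset skin --size 128 --seed 0 --out fov/
pars-stain extract --raster fov/fov_NR.h5 --out channels/
pars-stain features --raster fov/fov_NR.h5 --k 3 --subset 0.1 --seed 7 --out feats/
pars-stain kstudy --preset brain --kmin 2 --kmax 4 --out kstudy.csv
pars-stain cstudy --preset skin --channels R_266,m_f1 --out cstudy.csv
pars-stain colorize --model ckpt --stack channels/fov_NR_NR_266.tif ... --out he.png
```

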