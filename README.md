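# siribruise

Detection of early subsurface bruises in fruit by **structured-illumination
reflectance imaging (SIRI)**: a sinusoidal light pattern of spatial
frequency *f* is projected onto the sample and imaged at three phase
offsets (−2π/3, 0, +2π/3).  Per-pixel three-phase demodulation of the
pattern triplet *I₁, I₂, I₃*

    I_DC = (I₁ + I₂ + I₃) / 3
    I_AC = (√2 / 3) · √((I₁−I₂)² + (I₁−I₃)² + (I₂−I₃)²)

separates a planar component (DC, the ordinary uniform-illumination image)
from the modulated amplitude (AC), whose depth of interrogation shrinks as
*f* grows — so a shallow bruise shows up as an AC deficit while remaining
invisible in DC.  The ratio image **RT = I_AC / I_DC** cancels illumination
nonuniformity from surface curvature and reflectance, and is the preferred
detection image.

The package is a complete, tested analysis chain for this problem,
aimed at researchers in optical fruit-quality inspection and biological
image analysis:

- `synthetic_scene` — ground-truthed fruit phantoms (elliptical fruit,
  vignetting, subsurface bruise of graded severity S0–S3, sensor noise,
  8-bit quantization) rendered into pattern triplets;
- `demodulate` — three-phase demodulation, masked Gaussian denoising, RT;
- `segment` — fruit masking from DC, Otsu bruise/sound partition on RT;
- `contrast` — contrast index CI = between-class / total pixel variance,
  and the frequency sweep that picks the operating frequency (mild-first
  rule over 50–500 cycles/m);
- `texture` — 56 GLCM Haralick features (14 statistics × 4 directions,
  distance 1) on masked images;
- `selection` — random-frog feature selection scored by cross-validated
  PLS-DA, tallied over 30 data partitions, top-10 subset;
- `classify` — from-scratch LS-SVM (RBF kernel, KKT linear system),
  PLS-DA (NIPALS, LOO-CV latent variables) and KNN, evaluated by TP/TN/ACC
  over 30 stratified 7:3 splits;
- `pipeline` / `cli` — end-to-end orchestration with per-stage caching,
  YAML configuration and a `siribruise` command-line group.

## Worked example

```python
import numpy as np
from siribruise import (
    IlluminationSpec, NoiseSpec, make_phantom, render_triplet,
    tpd_demodulate, demodulate_triplet, fruit_mask_from_dc,
    split_bruise_sound, contrast_index,
)

scene = make_phantom("S2", seed=11)                       # moderate bruise
trip = render_triplet(scene, IlluminationSpec(150.0),     # 150 cycles/m
                      NoiseSpec(gaussian_sigma=1.0, quantize=True, rng_seed=12))
dc, _ = tpd_demodulate(trip)
fruit = fruit_mask_from_dc(dc)                            # global DC threshold
demod = demodulate_triplet(trip, mask=fruit)              # DC / AC / RT
seg = split_bruise_sound(demod.rt_image, fruit)           # Otsu on RT
res = contrast_index(demod.rt_image, seg)
truth = scene.bruise_profile > 0.5
dice = 2 * (seg.bruise_mask & truth).sum() / (seg.bruise_mask.sum() + truth.sum())
print(f"CI = {res.ci:.3f}, bruise pixels = {res.n_bruise}, Dice vs truth = {dice:.3f}")
```

prints

```
CI = 0.941, bruise pixels = 2478, Dice vs truth = 0.995
```

i.e. the bruise/sound split explains 94.1% of the RT intensity variance
inside the fruit, and the recovered bruise mask overlaps the phantom's
ground-truth disk with Dice 0.99.  The same chain scaled up — frequency
sweep, feature extraction, random-frog selection, repeated-split
LS-SVM — is driven by `siribruise.pipeline.run_all` or the CLI:

```sh
siribruise simulate --n-per-class 30 --frequency 150 --seed 1 --out-dir run/images
siribruise ci-sweep --replicates 3 --seed 1 --out run/ci_table.csv
siribruise features --manifest run/images/manifest.csv --out run/features.csv
siribruise select --features-csv run/features.csv --source RT --out run/tally.csv
siribruise evaluate --features-csv run/features.csv --model lssvm --source RT \
    --subset-csv run/tally.csv --reps 30 --seed 1
```

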