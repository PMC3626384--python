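# heliovent

Semiautomatic segmentation of ventilated airspaces in hyperpolarized-gas
(HP ³He) lung MRI, with ventilated-lung-volume (VLV) quantification and
method-agreement statistics.

Ventilation MRI shows where inhaled gas actually reaches the lung:
obstructed lungs (asthma, COPD, cystic fibrosis) show pockets of signal
depletion — ventilation defects.  Turning such images into a reproducible
number requires separating true gas signal from background noise, grading
ventilation intensity, and excising the trachea and main-stem bronchi,
which carry gas without exchanging it.  `heliovent` implements that
three-step pipeline:

1. **Statistical noise subtraction** — background noise sampled from an
   automated 25 × 50 box at the bottom of each slice is fitted with an
   adjusted Rayleigh curve r(f) = (αf + δ)·exp(−(αf + δ)²/2σ²)/σ², and an
   optimal threshold τₙ minimising
   ε_τ = Σ_{f<τ}(r − h)(f) + Σ_{f≥τ} r(f) yields an initial binary mask.
2. **Ventilation clustering** — fuzzy C-means (C = 4, m = 2) on masked
   intensities partitions pixels into negligible / low / intermediate /
   high ventilation; the negligible class returns to the background.
3. **Airway removal** — seeded region growing (running-mean difference
   |g(z) − mean(A)|, user seed + bounding box), connectivity labeling, a
   50-pixel area filter, binary subtraction and disk-element morphology
   restricted to a centroid template box remove the conducting airways.

The quantification layer computes VLV (pixels × voxel volume), Dice
overlap 2|A∩B|/(|A|+|B|), Bland–Altman 95% limits of agreement, Pearson /
OLS regression against spirometry (FEV₁, FVC) and t-tests.  A synthetic
phantom generator with ground truth makes the whole pipeline testable
without clinical data, and `heliovent.cohort` ships the ten-subject
reference tables the statistics layer is validated against.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from heliovent import end_to_end_fixture, run_pipeline_arrays, dice

phantom, seeds = end_to_end_fixture("realistic")   # 10 slices, 256x256
result = run_pipeline_arrays(phantom.image, seeds)

print(f"thresholds: {[f.tau for f in result.fits]}")
print(f"cluster centers: {[round(float(c), 1) for c in result.cluster_model.centers]}")
print(f"VLV = {result.vlv.total_l:.3f} L   (truth {dice(result.final, phantom.truth):.4f} Dice)")
```

prints

```
thresholds: [36, 43, 48, 38, 35, 38, 42, 38, 41, 40]
cluster centers: [46.0, 90.1, 150.0, 210.0]
VLV = 3.606 L   (truth 0.9993 Dice)
```

Per-slice thresholds land just above the sampled Rayleigh background
(σ = 10 here), the four cluster centres recover the phantom's intensity
classes (45/90/150/210), and the final mask — thresholded, refined, airways
removed — agrees with the generating ground truth to Dice 0.999, giving a
ventilated volume of 3.6 L at the 1.8 mm × 1.8 mm × 13 mm voxel geometry.

The same pipeline runs from the shell:

```sh
heliovent phantom --preset realistic --out /tmp/ph
heliovent run --input /tmp/ph/image.nii.gz --seeds /tmp/ph/seeds.json --out /tmp/run
heliovent metrics --mask-a /tmp/run/mask_final.nii.gz --mask-b /tmp/ph/truth_lung.nii.gz
```

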