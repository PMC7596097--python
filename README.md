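# papillae

Automated counting of fungiform papillae (FP) on stained anterior-tongue
images: U-Net-style segmentation trained with a weighted IoU loss,
morphological post-processing with an adaptive filiform filter, counting
inside the calibrated anatomical regions used by manual protocols
(ED1–ED3), and a bootstrap/permutation framework for comparing counts
between subject groups. A calibrated synthetic stained-tongue simulator
with exact ground truth makes the whole pipeline testable end-to-end.

**Who it is for.** Researchers in sensory science and oral physiology who
use FP density as a marker of taste responsiveness and want a counting
procedure that is automated, calibrated in millimetres, and statistically
careful — plus anyone needing a compact, fully reproducible CPU
segmentation pipeline with known ground truth.

## The method

Papillae and tongue are segmented by an encoder–decoder network (VGG-style
convolutional encoder without dense layers, U-Net decoder with batch norm
and dropout 0.5) optimised with a weighted Jaccard distance

```
L = 1 − |y ∩ ŷ| / (|y| + |ŷ·w| − |y ∩ ŷ|)
```

where the weight map w boosts pixels within 15 px of at least two papillae
tenfold (papillae model) or lip pixels fivefold (tongue model), so the
errors that corrupt counts — merged neighbours, tongue/lip confusion — are
penalised hardest. Raw segmentations are cleaned by 3 erosions + 2
dilations, gated by the tongue mask, filtered by an adaptive area rule
(drop objects smaller than ⅕ of the mean area of the largest 25 %), and
counted as 8-connected components. Counts are reported for three standard
regions anchored to the tongue tip and midline — ED1 (three 6 mm circles),
ED2 (two 6 mm circles at 0.5 cm from tip and midline), ED3 (a 1 cm²
square bisected by the midline) — and for the whole tongue (TOT), each
with a density per cm². Group differences are tested with a bootstrapped
permutation test whose decision uses the full p-value distribution
(retain the null when > 40 % of round p-values exceed 0.10).

See `docs/methods.md` for the full account.

## Worked example

```python
from papillae import (easy_spec, generate_sample, Calibration,
                      count_papillae, count_all_regions)

sample = generate_sample(easy_spec(seed=1))       # synthetic stained tongue
cal = Calibration(sample.spec.px_per_mm)

# ground-truth-mask mode: the deterministic half of the pipeline
mask, objects = count_papillae(sample.papillae_mask, sample.tongue_mask, cal)
rec = count_all_regions(objects, sample.tongue_mask, cal, subject_id="demo")
print(rec.ED1, rec.ED2, rec.ED3, rec.TOT)
print(sample.true_counts.ED1, sample.true_counts.ED2,
      sample.true_counts.ED3, sample.true_counts.TOT)
```

prints

```
10 9 14 50
10 9 14 50
```

— the measured regional counts (ED1, ED2, ED3, whole tongue) exactly
recover the generator's ground truth: 10 papillae centred in the three
anterior circles, 9 in the two lateral circles, 14 in the 1 cm² tip
square, 50 on the tongue overall.

Training the reduced network and segmenting from pixels:

```python
from papillae import (build_model, reduced_config, train,
                      sliding_window_predict, f1_auc_kappa, extract_patches)
from papillae.losses import papillae_loss_weights

samples = [generate_sample(easy_spec(seed=100 + i)) for i in range(10)]
dataset = []
for s in samples:
    w = papillae_loss_weights(s.papillae_mask)
    dataset.extend(extract_patches(s.image, s.papillae_mask, w,
                                   tongue_mask=s.tongue_mask,
                                   patch_size=(128, 192)))
model = train(build_model(reduced_config(epochs=8, seed=0)), dataset)

held_out = generate_sample(easy_spec(seed=900))
prob = sliding_window_predict(model, held_out.image)
f1, auc, kappa = f1_auc_kappa(prob, held_out.papillae_mask,
                              support=held_out.tongue_mask)
print(f"F1={f1:.3f} AUC={auc:.3f} kappa={kappa:.3f}")
```

prints (≈ 3 minutes on one CPU)

```
F1=0.956 AUC=1.000 kappa=0.954
```

— held-out pixelwise segmentation quality of the scaled-down network on
the easy synthetic preset.

There is also a CLI (`papillae simulate|train|segment|count|regions|
evaluate|stats|pipeline`); `papillae pipeline --n-subjects 5 --out run/
--seed 0` runs the whole chain in ground-truth-mask mode and writes
per-subject masks, object tables, a counts CSV and a JSON report.

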