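# petmip

Multimodal classification of lymphoma subtypes from ¹⁸F-FDG PET
maximum-intensity-projection (MIP) images and routine clinical variables,
with a trainable **Scanner-Conditioned Normalization (SCN)** layer that
harmonizes feature embeddings across PET scanner manufacturers.

## Who this is for

Multi-center PET studies suffer from scanner batch effects: vendor-specific
point-spread functions, gains and noise shift image statistics enough that a
classifier trained at some sites degrades at others. `petmip` implements a
full desk-scale replica of a harmonized image+clinical classifier for binary
lymphoma subtype tasks (e.g. Hodgkin vs non-Hodgkin surrogates), together
with a synthetic multi-scanner phantom so every stage — SUV conversion, MIP
projection, harmonized training, evaluation statistics, Grad-CAM
explanations — is testable end to end without any patient data.

## The model

Each case contributes an anterior and a lateral MIP of the body-weight SUV
volume,

SUV = activity(Bq/mL) × weight(g) / [dose₀(Bq) · 2^(−Δt/T½)],

with the injected dose decay-corrected over the uptake interval Δt
(T½ = 6586.2 s for ¹⁸F). Each MIP is

resized to a square, min-max normalized per image. A shared-weight CNN maps
each view to a pooled embedding **x**, which SCN standardizes instance-wise
and recalibrates with manufacturer-indexed learnable parameters:

x̂ = (x − μₓ) / √(σₓ² + ε),  y = x̂ ⊙ γₛ + βₛ,  ε = 10⁻⁶,

where *s* is the scanner-manufacturer index; γₛ, βₛ are learned jointly with
the network. The two view embeddings are concatenated with a three-layer
clinical encoder's output (age, Ann Arbor stage, Deauville score, blood
counts, NLR/PLR, LDH, binary history flags — z-scored with training-set
statistics only) and a classifier head emits one logit. Training uses
class-weighted binary cross-entropy, AdamW, early stopping with best-epoch
restore, and reduce-on-plateau learning-rate scheduling. Evaluation reports
AUC, MCC, sensitivity and specificity with percentile-bootstrap 95% CIs
(B = 1000), an unpaired DeLong test between independent cohorts, and a paired
bootstrap AUC-difference test for models scored on the same cases.

There is no GPU dependency: the network, SCN layer and Grad-CAM are a small
numpy implementation with hand-derived, finite-difference-verified gradients.

## Worked example

```python
import numpy as np
from petmip import (PhantomConfig, SplitSpec, generate_cohort,
                    LymphomaMipModel, TrainConfig)

cases = generate_cohort(PhantomConfig(), 300, SplitSpec(), seed=42)
model = LymphomaMipModel(cases, image_size=64)
results = model.fit(TrainConfig(seed=0))
print(results.summary(B=500, seed=0))
cmp = results.compare_cohorts()
print(f"DeLong internal vs external: z={cmp['z']:+.3f}, p={cmp['p']:.3f}")
```

prints

```
Multimodal PET-MIP + clinical classifier
  backbone=test_small_cnn  views=both  scn=on  clinical=on
  best epoch 11 / stopped 16

  cohort             n     AUC          95% CI    MCC   Sens   Spec
  internal_test     45   0.922  (0.841,0.983)  0.508  0.750  0.838
  external_test     75   0.852  (0.724,0.940)  0.281  0.636  0.734

DeLong internal vs external: z=+1.013, p=0.311
```

The cohort is 300 synthetic patients over four scanner vendors; vendor 3 is
held out entirely as the external test site. The internal/external AUC gap
reflects the residual domain shift after SCN harmonization (the external
vendor was never seen in training, so SCN falls back to the mean of the
learned per-vendor recalibration rows); the DeLong test shows the gap is not
significant at this sample size.

A command-line workflow mirrors the library:

```bash
petmip simulate out/cohort --n-cases 100 --seed 1
petmip train out/cohort out/model --image-size 64
petmip evaluate out/model/predictions.csv --out out/reports.json
petmip run-all out/experiment --seed 1        # full ablation experiment
```

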